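"""Performance metrics and model-interrogation experiments.

Beyond the standard confusion-matrix metrics and ROC/PR curves, this
module implements the interrogation procedures used to probe what the
splicing model has learned:

* leave-one-out importance — retrain without one channel, measure the mean
  decrease in F1 and ROC AUC;
* add-one-in feature gain — start from a DNA-only model and add one
  channel (or one pair) at a time;
* cross-cell transfer — apply fitted weights unchanged to another dataset;
* reversal test — evaluate a forward-trained model on inputs whose
  epigenomic channels are fed 3'->5', probing direction dependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .features import DNA_CHANNELS, SpliceDataset
from .model import ModelConfig, SpliceRNN, SpliceRNNResults, split_indices


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Threshold metrics plus ROC / PR curves and their areas.

    ``roc_auc`` and ``pr_auc`` are None when the labels contain a single
    class (the curves are undefined there); threshold metrics are still
    reported.
    """

    confusion: ConfusionCounts
    precision: float
    recall: float
    accuracy: float
    f1: float
    roc_auc: float | None
    pr_auc: float | None
    roc_curve: pd.DataFrame  # columns fpr, tpr, threshold
    pr_curve: pd.DataFrame  # columns recall, precision

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
        }


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Precision/recall/accuracy/F1 at a threshold, plus ROC and PR curves.

    ROC AUC uses the trapezoid rule over the full threshold sweep (tied
    scores grouped); PR AUC is the step-wise average-precision sum.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same shape")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    calls = (s >= threshold).astype(int)
    tp = int(np.sum((calls == 1) & (y == 1)))
    fp = int(np.sum((calls == 1) & (y == 0)))
    fn = int(np.sum((calls == 0) & (y == 1)))
    tn = int(np.sum((calls == 0) & (y == 0)))
    conf = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / conf.total if conf.total else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    single_class = np.unique(y).size < 2
    if single_class:
        roc_auc = pr_auc = None
        roc_df = pd.DataFrame(columns=["fpr", "tpr", "threshold"])
        pr_df = pd.DataFrame(columns=["recall", "precision"])
    else:
        fpr, tpr, thr = _skm.roc_curve(y, s)
        roc_auc = float(_skm.auc(fpr, tpr))
        prec_pts, rec_pts, _ = _skm.precision_recall_curve(y, s)
        pr_auc = float(_skm.average_precision_score(y, s))
        roc_df = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        pr_df = pd.DataFrame({"recall": rec_pts, "precision": prec_pts})

    return MetricsReport(
        confusion=conf,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        f1=f1,
        roc_auc=roc_auc,
        pr_auc=pr_auc,
        roc_curve=roc_df,
        pr_curve=pr_df,
    )


# ---------------------------------------------------------------------------
# feature importance by retraining


def _fit_and_score(dataset: SpliceDataset, config: ModelConfig, seed: int) -> tuple[SpliceRNNResults, MetricsReport]:
    res = SpliceRNN(dataset, config).fit(seed=seed)
    return res, res.metrics(which="test")


@dataclass
class ImportanceReport:
    """Leave-one-out deltas per channel (reference minus ablated)."""

    reference: dict  # mean reference metrics
    table: pd.DataFrame  # channel, delta_f1, delta_roc_auc, sd columns, rank
    variability: dict  # seed-to-seed sd of reference F1 / ROC AUC


def reference_variability(
    dataset: SpliceDataset, config: ModelConfig, seeds: Sequence[int]
) -> dict:
    """Seed-to-seed spread of the reference model's test metrics: the
    scale against which an ablation delta counts as real."""
    f1s, aucs = [], []
    for s in seeds:
        _, m = _fit_and_score(dataset, config, s)
        f1s.append(m.f1)
        aucs.append(m.roc_auc)
    return {
        "f1_sd": float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
        "roc_auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        "f1_values": f1s,
        "roc_auc_values": aucs,
    }


def leave_one_out_importance(
    dataset: SpliceDataset,
    config: ModelConfig,
    channels: Sequence[str] | None = None,
    seed: int = 0,
    n_repeats: int = 3,
    n_variability_seeds: int = 3,
) -> ImportanceReport:
    """Retrain without one channel at a time; report metric decreases.

    For each repeat r the reference model and every ablated model are
    trained with seed + r (hence an identical shuffle/split within the
    repeat); deltas are averaged over repeats.  Training failures for a
    channel are recorded and the remaining channels continue.
    """
    if channels is None:
        channels = dataset.epigenomic_channels
    if len(channels) < 2:
        raise ValueError("leave-one-out needs at least two non-DNA channels")

    ref_metrics = []
    deltas: dict[str, list[dict]] = {c: [] for c in channels}
    errors: dict[str, str] = {}
    for r in range(n_repeats):
        s = seed + r
        _, ref = _fit_and_score(dataset, config, s)
        ref_metrics.append(ref)
        for channel in channels:
            try:
                _, abl = _fit_and_score(dataset.drop_channel(channel), config, s)
            except Exception as exc:  # keep going for the other channels
                errors[channel] = str(exc)
                continue
            deltas[channel].append(
                {"delta_f1": ref.f1 - abl.f1, "delta_roc_auc": ref.roc_auc - abl.roc_auc}
            )

    rows = []
    for channel in channels:
        if not deltas[channel]:
            rows.append({"channel": channel, "delta_f1": np.nan, "delta_roc_auc": np.nan, "error": errors.get(channel, "")})
            continue
        df = pd.DataFrame(deltas[channel])
        rows.append(
            {
                "channel": channel,
                "delta_f1": df["delta_f1"].mean(),
                "delta_f1_sd": df["delta_f1"].std(ddof=1) if len(df) > 1 else 0.0,
                "delta_roc_auc": df["delta_roc_auc"].mean(),
                "delta_roc_auc_sd": df["delta_roc_auc"].std(ddof=1) if len(df) > 1 else 0.0,
                "error": "",
            }
        )
    table = pd.DataFrame(rows).sort_values("delta_roc_auc", ascending=False).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)

    variability = reference_variability(dataset, config, [seed + 1000 + i for i in range(n_variability_seeds)])
    reference = {
        "f1": float(np.mean([m.f1 for m in ref_metrics])),
        "roc_auc": float(np.mean([m.roc_auc for m in ref_metrics])),
    }
    return ImportanceReport(reference=reference, table=table, variability=variability)


def feature_gain(
    dataset: SpliceDataset,
    config: ModelConfig,
    candidates: Sequence[str] | None = None,
    base_channels: Sequence[str] = DNA_CHANNELS,
    pairs: bool = False,
    n_trials: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Add-one-in (or add-one-pair) information gain over a base model.

    For each trial t the base model and every augmented model share seed
    seed + t; the gain is augmented minus base, averaged over trials.
    """
    if candidates is None:
        candidates = dataset.epigenomic_channels
    groups: list[tuple[str, ...]] = (
        [tuple(p) for p in combinations(candidates, 2)] if pairs else [(c,) for c in candidates]
    )
    base = list(base_channels)

    rows = []
    for t in range(n_trials):
        s = seed + t
        _, base_m = _fit_and_score(dataset.subset_channels(base), config, s)
        for group in groups:
            _, aug_m = _fit_and_score(dataset.subset_channels(base + list(group)), config, s)
            rows.append(
                {
                    "channels": "+".join(group),
                    "trial": t,
                    "gain_f1": aug_m.f1 - base_m.f1,
                    "gain_roc_auc": aug_m.roc_auc - base_m.roc_auc,
                }
            )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("channels")
        .agg(
            gain_f1=("gain_f1", "mean"),
            gain_f1_sd=("gain_f1", "std"),
            gain_roc_auc=("gain_roc_auc", "mean"),
            gain_roc_auc_sd=("gain_roc_auc", "std"),
            n_trials=("trial", "count"),
        )
        .reset_index()
        .sort_values("gain_roc_auc", ascending=False)
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# transfer and reversal


@dataclass
class TransferReport:
    metrics: MetricsReport
    class_balance_model: float | None  # fraction included in training data
    class_balance_other: float  # fraction included in foreign data


def cross_cell_test(results: SpliceRNNResults, dataset_other: SpliceDataset) -> TransferReport:
    """Apply a fitted model, unchanged, to another dataset.

    The foreign dataset is shuffled/split with the model's seed and the
    metrics are computed on its held-out (test) partition, so the numbers
    are comparable to the model's own within-dataset test metrics.  Class
    balance of both datasets is reported because F1 is the fairer metric
    under imbalance.
    """
    labelled = np.flatnonzero(dataset_other.y >= 0)
    ds = dataset_other.subset_events(labelled)
    rng = np.random.default_rng(results.seed)
    fold = split_indices(len(ds), rng)["test"]
    scores = results.predict_proba(ds.subset_events(fold))
    report = compute_metrics(ds.y[fold], scores)
    balance_model = None
    if results.dataset is not None:
        y_tr = results.dataset.y
        balance_model = float((y_tr == 1).mean())
    return TransferReport(
        metrics=report,
        class_balance_model=balance_model,
        class_balance_other=float((ds.y == 1).mean()),
    )


@dataclass
class ReversalReport:
    forward: MetricsReport
    reversed: MetricsReport

    @property
    def delta_f1(self) -> float:
        return self.forward.f1 - self.reversed.f1

    @property
    def delta_roc_auc(self) -> float | None:
        if self.forward.roc_auc is None or self.reversed.roc_auc is None:
            return None
        return self.forward.roc_auc - self.reversed.roc_auc


def reversal_test(
    results: SpliceRNNResults,
    dataset: SpliceDataset | None = None,
    channels: Sequence[str] | None = None,
    which: str | None = "test",
) -> ReversalReport:
    """Evaluate a forward-trained model on time-reversed inputs.

    ``channels`` defaults to the epigenomic channels (DNA stays forward).
    Reversing an empty channel list reproduces the forward report exactly.
    """
    ds = dataset if dataset is not None else results.dataset
    if ds is None:
        raise ValueError("no dataset attached; pass one explicitly")
    if channels is None:
        channels = ds.epigenomic_channels
    fwd_scores = results.predict_proba(ds, which)
    rev_scores = results.predict_proba(ds.reverse_time(channels), which)
    y = ds.y if which is None else ds.y[results.split[which]]
    return ReversalReport(
        forward=compute_metrics(y, fwd_scores),
        reversed=compute_metrics(y, rev_scores),
    )
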