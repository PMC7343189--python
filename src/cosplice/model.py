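"""Two-branch recurrent splicing model: statsmodels-style Model / Results.

:class:`SpliceRNN` is constructed from a :class:`~cosplice.features.SpliceDataset`
and a :class:`ModelConfig`; :meth:`SpliceRNN.fit` shuffles the events with
the given seed, splits them 64/16/20 into fitting, validation and held-out
test folds, trains with mean binary cross-entropy under Adam, and returns
a :class:`SpliceRNNResults` carrying the trained gate parameters, the
per-epoch history and the split, with ``summary()``, prediction and
gate-weight inspection hanging off it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._engine import Adam, TwoBranchNet
from .cells import GATE_ORDER, CellParams, init_cell_params
from .features import EventTensorPair, SpliceDataset


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation settings.

    The ``main`` preset mirrors the reference architecture (branch RNNs of
    size 200 merged into a size-400 RNN, dropout, softmax head, 20 epochs);
    the ``interpret`` preset is the single-hidden-unit variant trained much
    longer, whose gate weights are read out directly per input channel.
    """

    cell_type: str = "lstm"  # lstm | gru | simple
    branch_size: int = 200
    merge_size: int = 400
    dropout_rate: float = 0.5
    epochs: int = 20
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    merge_mode: str = "time"  # time | feature
    head: str = "softmax"  # softmax | sigmoid
    channel_subset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.branch_size < 1 or self.merge_size < 1:
            raise ValueError("epochs and layer sizes must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.cell_type not in GATE_ORDER:
            raise ValueError(f"unknown cell type {self.cell_type!r}")

    @classmethod
    def main(cls, cell_type: str = "lstm", **overrides) -> "ModelConfig":
        return cls(cell_type=cell_type, **overrides)

    @classmethod
    def interpret(cls, cell_type: str = "lstm", **overrides) -> "ModelConfig":
        defaults = dict(branch_size=1, merge_size=1, dropout_rate=0.0, epochs=400)
        defaults.update(overrides)
        return cls(cell_type=cell_type, **defaults)

    @classmethod
    def benchmark(cls, cell_type: str = "lstm", **overrides) -> "ModelConfig":
        """CPU-scale settings used for the synthetic benchmarks: a small
        network is ample for the generator's signal strength and keeps a
        20-epoch run in the minutes range on one core."""
        defaults = dict(branch_size=16, merge_size=32, batch_size=128)
        defaults.update(overrides)
        return cls(cell_type=cell_type, **defaults)

    @classmethod
    def small(cls, cell_type: str = "lstm", **overrides) -> "ModelConfig":
        """Tiny fast-converging configuration for compact fixtures
        (direction and importance runs): no dropout, higher learning rate,
        small batches for more optimizer updates on few events."""
        defaults = dict(
            branch_size=8, merge_size=16, dropout_rate=0.0, lr=3e-3, batch_size=32, epochs=15
        )
        defaults.update(overrides)
        return cls(cell_type=cell_type, **defaults)


def split_indices(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Shuffled 64/16/20 fit/validation/test partition.

    20% of the data is set aside for testing; the remaining 80% is split
    80/20 again into fitting and validation folds.
    """
    perm = rng.permutation(n)
    n_test = int(round(0.2 * n))
    n_rest = n - n_test
    n_val = int(round(0.2 * n_rest))
    n_fit = n_rest - n_val
    return {
        "fit": perm[:n_fit],
        "val": perm[n_fit : n_fit + n_val],
        "test": perm[n_fit + n_val :],
    }


class SpliceRNN:
    """Model object: a labelled dataset plus a configuration.

    Unlabelled events (y == -1) are excluded from fitting.
    """

    def __init__(self, dataset: SpliceDataset, config: ModelConfig | None = None, **overrides):
        config = config or ModelConfig()
        if overrides:
            config = replace(config, **overrides)
        if config.channel_subset is not None:
            dataset = dataset.subset_channels(list(config.channel_subset))
        self.dataset = dataset
        self.config = config

    def fit(self, seed: int = 0, verbose: bool = False) -> "SpliceRNNResults":
        cfg = self.config
        labelled = np.flatnonzero(self.dataset.y >= 0)
        ds = self.dataset.subset_events(labelled)
        y = ds.y.astype(np.int64)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                f"training requires both classes; dataset has only class(es) {classes.tolist()}"
            )

        rng = np.random.default_rng(seed)
        split = split_indices(len(ds), rng)
        net = _init_net(rng, cfg, ds.n_channels)
        opt = Adam(net.param_list(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)

        Xa, Xd = ds.X_acc, ds.X_don
        fit_idx = split["fit"]
        history_rows = []
        for epoch in range(cfg.epochs):
            order = fit_idx[rng.permutation(len(fit_idx))]
            for lo in range(0, len(order), cfg.batch_size):
                batch = order[lo : lo + cfg.batch_size]
                mask = None
                if cfg.dropout_rate > 0:
                    keep = rng.random((len(batch), cfg.merge_size)) >= cfg.dropout_rate
                    mask = keep.astype(np.float32) / np.float32(1.0 - cfg.dropout_rate)
                p = net.forward(Xa[batch], Xd[batch], dropout_mask=mask)
                grads = net.backward(y[batch])
                opt.step(net.grad_list(grads))
            row = {"epoch": epoch + 1}
            for name in ("fit", "val"):
                idx = split[name]
                p = _predict_batched(net, Xa[idx], Xd[idx])
                key = "train" if name == "fit" else "val"
                row[f"{key}_loss"] = net.loss(p, y[idx])
                row[f"{key}_accuracy"] = float(((p >= 0.5).astype(int) == y[idx]).mean())
            history_rows.append(row)
            if verbose:
                print(
                    f"epoch {row['epoch']:3d}  train loss {row['train_loss']:.4f} "
                    f"acc {row['train_accuracy']:.3f}  val loss {row['val_loss']:.4f} "
                    f"acc {row['val_accuracy']:.3f}"
                )

        return SpliceRNNResults(
            config=cfg,
            net=net,
            channel_names=list(ds.channel_names),
            split={k: v.copy() for k, v in split.items()},
            history=pd.DataFrame(history_rows),
            seed=seed,
            dataset=ds,
        )


def _init_net(rng: np.random.Generator, cfg: ModelConfig, n_channels: int) -> TwoBranchNet:
    H1, H2 = cfg.branch_size, cfg.merge_size
    merge_in = H1 if cfg.merge_mode == "time" else 2 * H1
    branch_acc = init_cell_params(rng, cfg.cell_type, n_channels, H1)
    branch_don = init_cell_params(rng, cfg.cell_type, n_channels, H1)
    merge = init_cell_params(rng, cfg.cell_type, merge_in, H2)
    n_out = 2 if cfg.head == "softmax" else 1
    lim = np.sqrt(6.0 / (H2 + n_out))
    W_y = rng.uniform(-lim, lim, size=(H2, n_out)).astype(np.float32)
    b_y = np.zeros(n_out, dtype=np.float32)
    return TwoBranchNet(branch_acc, branch_don, merge, W_y, b_y, merge_mode=cfg.merge_mode, head=cfg.head)


def _predict_batched(net: TwoBranchNet, Xa: np.ndarray, Xd: np.ndarray, batch: int = 512) -> np.ndarray:
    out = np.empty(len(Xa), dtype=np.float64)
    for lo in range(0, len(Xa), batch):
        out[lo : lo + batch] = net.forward(Xa[lo : lo + batch], Xd[lo : lo + batch])
    return out


@dataclass
class SpliceRNNResults:
    """Fitted model state: parameters, split, history, and predictions."""

    config: ModelConfig
    net: TwoBranchNet
    channel_names: list[str]
    split: dict[str, np.ndarray]
    history: pd.DataFrame
    seed: int
    dataset: SpliceDataset | None = None

    # --- prediction -------------------------------------------------------

    def _check_channels(self, dataset: SpliceDataset) -> None:
        if list(dataset.channel_names) != list(self.channel_names):
            missing = set(self.channel_names) - set(dataset.channel_names)
            extra = set(dataset.channel_names) - set(self.channel_names)
            raise ValueError(
                f"channel registry mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )

    def predict_proba(self, dataset: SpliceDataset | None = None, which: str | None = None) -> np.ndarray:
        """Inclusion probabilities; ``which`` selects a stored fold
        ("fit"/"val"/"test") of the training dataset."""
        if dataset is None:
            if self.dataset is None:
                raise ValueError("no dataset attached; pass one explicitly")
            dataset = self.dataset
        self._check_channels(dataset)
        if which is not None:
            idx = self.split[which]
            return _predict_batched(self.net, dataset.X_acc[idx], dataset.X_don[idx])
        return _predict_batched(self.net, dataset.X_acc, dataset.X_don)

    def predict(self, dataset: SpliceDataset | None = None, which: str | None = None, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(dataset, which) >= threshold).astype(int)

    def predict_pair(self, pair: EventTensorPair) -> float:
        """Inclusion probability for a single acceptor/donor window pair."""
        Xa = pair.acceptor_window.values[None].astype(np.float32)
        Xd = pair.donor_window.values[None].astype(np.float32)
        if pair.acceptor_window.channel_names != self.channel_names:
            missing = set(self.channel_names) - set(pair.acceptor_window.channel_names)
            raise ValueError(f"channel registry mismatch: missing {sorted(missing)}")
        return float(self.net.forward(Xa, Xd)[0])

    def metrics(self, dataset: SpliceDataset | None = None, which: str | None = "test"):
        """MetricsReport on a fold (default the held-out test fold)."""
        from .evaluation import compute_metrics

        ds = dataset if dataset is not None else self.dataset
        if ds is None:
            raise ValueError("no dataset attached; pass one explicitly")
        scores = self.predict_proba(ds, which)
        y = ds.y if which is None else ds.y[self.split[which]]
        return compute_metrics(y, scores)

    # --- interpretation ---------------------------------------------------

    def extract_gate_weights(self) -> pd.DataFrame:
        """Per-channel input weights at each gate of the two branch cells.

        Designed for the single-hidden-unit interpretation preset, where
        each (channel, gate) entry is one scalar whose sign and magnitude
        are directly readable.  For larger hidden sizes the entries are
        aggregated as the signed mean across hidden units (a warning is
        issued) alongside the mean absolute magnitude.
        """
        H = self.config.branch_size
        if H > 1:
            warnings.warn(
                f"hidden size {H} > 1: gate weights aggregated across units",
                stacklevel=2,
            )
        rows = []
        for branch_name, cp in (("acceptor", self.net.branch_acc), ("donor", self.net.branch_don)):
            for gate in cp.gates:
                W = cp.Wx(gate)  # (C, H)
                for ci, channel in enumerate(self.channel_names):
                    rows.append(
                        {
                            "branch": branch_name,
                            "gate": gate,
                            "channel": channel,
                            "weight": float(W[ci].mean()),
                            "abs_weight": float(np.abs(W[ci]).mean()),
                        }
                    )
        return pd.DataFrame(rows)

    # --- reporting --------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        last = self.history.iloc[-1]
        lines = [
            "Two-branch recurrent splicing model",
            "=" * 48,
            f"cell type        {cfg.cell_type}",
            f"branch / merge   {cfg.branch_size} / {cfg.merge_size} ({cfg.merge_mode} merge)",
            f"dropout          {cfg.dropout_rate}",
            f"epochs           {cfg.epochs}   seed {self.seed}",
            f"channels ({len(self.channel_names)})    {', '.join(self.channel_names)}",
            f"events           fit {len(self.split['fit'])} / val {len(self.split['val'])} / test {len(self.split['test'])}",
            f"final train loss {last['train_loss']:.4f}  acc {last['train_accuracy']:.3f}",
            f"final val loss   {last['val_loss']:.4f}  acc {last['val_accuracy']:.3f}",
        ]
        if self.dataset is not None:
            m = self.metrics(which="test")
            lines.append(
                f"test             F1 {m.f1:.4f}  ROC AUC {m.roc_auc:.4f}  "
                f"precision {m.precision:.4f}  recall {m.recall:.4f}"
            )
        return "\n".join(lines)

    # --- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "channel_names": self.channel_names,
            "seed": self.seed,
            "split": {k: v.tolist() for k, v in self.split.items()},
        }
        (directory / "model.json").write_text(json.dumps(meta))
        arrays = {}
        for name, cp in (("branch_acc", self.net.branch_acc), ("branch_don", self.net.branch_don), ("merge", self.net.merge)):
            arrays[f"{name}.W_x"] = cp.W_x
            arrays[f"{name}.W_h"] = cp.W_h
            arrays[f"{name}.b"] = cp.b
        arrays["W_y"] = self.net.W_y
        arrays["b_y"] = self.net.b_y
        np.savez_compressed(directory / "params.npz", **arrays)
        self.history.to_csv(directory / "history.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "SpliceRNNResults":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        cfg_dict = meta["config"]
        if cfg_dict.get("channel_subset") is not None:
            cfg_dict["channel_subset"] = tuple(cfg_dict["channel_subset"])
        cfg = ModelConfig(**cfg_dict)
        arrays = np.load(directory / "params.npz")
        cells = {}
        for name in ("branch_acc", "branch_don", "merge"):
            cells[name] = CellParams(
                cell_type=cfg.cell_type,
                W_x=arrays[f"{name}.W_x"],
                W_h=arrays[f"{name}.W_h"],
                b=arrays[f"{name}.b"],
            )
        net = TwoBranchNet(
            cells["branch_acc"],
            cells["branch_don"],
            cells["merge"],
            arrays["W_y"],
            arrays["b_y"],
            merge_mode=cfg.merge_mode,
            head=cfg.head,
        )
        history = pd.read_csv(directory / "history.tsv", sep="\t")
        return cls(
            config=cfg,
            net=net,
            channel_names=list(meta["channel_names"]),
            split={k: np.asarray(v) for k, v in meta["split"].items()},
            history=history,
            seed=meta["seed"],
        )
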