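"""Metagene enrichment profiles around splice sites and related statistics.

Profiles average a signal track per position across many events aligned at
their acceptor or donor splice site, oriented 5'->3' in transcription
direction and stratified by PSI class (high = included, mid = 40-60% PSI
band, low = skipped).  Segment-level comparisons use the two-sided
Mann-Whitney-Wilcoxon rank-sum test with the star bins
ns (p > 0.05), * (<=0.05), ** (<=0.01), *** (<=0.001), **** (<=0.0001).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CassetteExonEvent
from .features import extract_track_window
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

HIGH, MID, LOW = "high", "mid", "low"
_CLASS_ALIASES = {
    "included": HIGH,
    "high": HIGH,
    "mid": MID,
    "skipped": LOW,
    "low": LOW,
}

# Segment scheme around the 3' acceptor, bp relative to the SS in
# transcription direction (negative = intronic side).  C covers the
# proximal intron containing the branch point; this tiling of [-100, 100)
# is a configuration default and is echoed in every report.
DEFAULT_SEGMENTS: dict[str, tuple[int, int]] = {
    "A": (-100, -50),  # distal intron
    "C": (-50, 0),  # proximal intron (branch-point region)
    "B": (0, 50),  # proximal exon
    "D": (50, 100),  # distal exon
}

STAR_BINS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars_for_p(p: float) -> str:
    for cutoff, stars in STAR_BINS:
        if p <= cutoff:
            return stars
    return "ns"


@dataclass
class MetageneProfile:
    site_kind: str  # acceptor_3p | donor_5p
    psi_class: str  # high | mid | low
    positions: np.ndarray  # -flank .. flank-1 relative to the SS
    mean_signal: np.ndarray
    n_events: int


@dataclass(frozen=True)
class SegmentComparison:
    segment_id: str
    group_pair: tuple[str, str]
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    stars: str


def _classes_of(events: Sequence[CassetteExonEvent], psi_records) -> dict[str, str]:
    """Normalise a PSI-class source to {event_id: high|mid|low}."""
    if isinstance(psi_records, pd.DataFrame):
        raw = dict(zip(psi_records["exon_id"], psi_records["psi_class"]))
    elif isinstance(psi_records, Mapping):
        raw = dict(psi_records)
    else:
        raise TypeError("psi_records must be a DataFrame or mapping")
    out = {}
    for ev in events:
        cls = raw.get(ev.event_id)
        if cls in _CLASS_ALIASES:
            out[ev.event_id] = _CLASS_ALIASES[cls]
    return out


def aggregate_profile(
    events: Sequence[CassetteExonEvent],
    track: SignalTrack,
    psi_records,
    flank: int = 500,
) -> list[MetageneProfile]:
    """Per-position mean signal around both splice sites, per PSI class.

    Events whose PSI class is undefined are ignored; classes with no events
    are omitted with a warning.
    """
    classes = _classes_of(events, psi_records)
    positions = np.arange(-flank, flank)
    profiles: list[MetageneProfile] = []
    for site_kind, site_of in (("acceptor_3p", lambda e: e.acceptor), ("donor_5p", lambda e: e.donor)):
        sums: dict[str, np.ndarray] = {}
        counts: dict[str, int] = {}
        for ev in events:
            cls = classes.get(ev.event_id)
            if cls is None:
                continue
            vec = extract_track_window(track, site_of(ev), flank)
            if cls not in sums:
                sums[cls] = np.zeros(2 * flank, dtype=np.float64)
                counts[cls] = 0
            sums[cls] += vec
            counts[cls] += 1
        for cls in (HIGH, MID, LOW):
            if cls not in sums:
                warnings.warn(f"no events in PSI class {cls!r} for {site_kind}", stacklevel=2)
                continue
            profiles.append(
                MetageneProfile(
                    site_kind=site_kind,
                    psi_class=cls,
                    positions=positions.copy(),
                    mean_signal=sums[cls] / counts[cls],
                    n_events=counts[cls],
                )
            )
    return profiles


def profiles_to_frame(profiles: Iterable[MetageneProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            pd.DataFrame(
                {
                    "site_kind": p.site_kind,
                    "psi_class": p.psi_class,
                    "position": p.positions,
                    "mean_signal": p.mean_signal,
                    "n_events": p.n_events,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# rank-sum machinery

_EXACT_LIMIT = 200_000  # max number of enumerated group assignments


def ranksum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U of x, p).

    Exact p by complete enumeration of group assignments (ties handled
    naturally) when the combined sample is small (C(n, n1) <=
    200,000, i.e. combined n <= 20 at worst balance); otherwise the normal
    approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    u_obs = _u_statistic(x, y)
    if comb(n1 + n2, n1) <= _EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        idx = np.arange(n1 + n2)
        total = 0
        le = 0
        ge = 0
        for pick in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            le += u <= u_obs
            ge += u >= u_obs
        p = min(1.0, 2.0 * min(le / total, ge / total))
        return float(u_obs), float(p)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x: pairs (xi > yj) plus half the ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def compare_segments(
    events: Sequence[CassetteExonEvent],
    track: SignalTrack,
    psi_records,
    segment_scheme: Mapping[str, tuple[int, int]] | None = None,
    flank: int | None = None,
) -> list[SegmentComparison]:
    """Rank-sum comparison of per-event mean segment signal between classes.

    Segments are bp intervals relative to the 3' acceptor in transcription
    direction (see :data:`DEFAULT_SEGMENTS`).  Pairs with a group smaller
    than two events are skipped.
    """
    scheme = dict(segment_scheme or DEFAULT_SEGMENTS)
    span = max(abs(lo) for lo, _ in scheme.values()), max(hi for _, hi in scheme.values())
    flank = flank or max(span)
    classes = _classes_of(events, psi_records)

    seg_values: dict[str, dict[str, list[float]]] = {s: {} for s in scheme}
    for ev in events:
        cls = classes.get(ev.event_id)
        if cls is None:
            continue
        vec = extract_track_window(track, ev.acceptor, flank)
        for seg, (lo, hi) in scheme.items():
            seg_mean = float(vec[lo + flank : hi + flank].mean())
            seg_values[seg].setdefault(cls, []).append(seg_mean)

    out: list[SegmentComparison] = []
    for seg in scheme:
        groups = seg_values[seg]
        for a, b in combinations([HIGH, MID, LOW], 2):
            if len(groups.get(a, [])) < 2 or len(groups.get(b, [])) < 2:
                logger.warning("segment %s: pair (%s, %s) skipped, group too small", seg, a, b)
                continue
            u, p = ranksum_test(groups[a], groups[b])
            out.append(
                SegmentComparison(
                    segment_id=seg,
                    group_pair=(a, b),
                    statistic=u,
                    p_value=p,
                    stars=stars_for_p(p),
                )
            )
    return out


# ---------------------------------------------------------------------------
# expression-enrichment coupling


def correlate_expression_enrichment(
    fpkm,
    signal,
    n_groups: int = 3,
) -> dict:
    """Pearson correlation of exonic expression with SS-proximal signal.

    Also groups exons into expression tertiles (configurable) and runs
    rank-sum tests between group signals.  Zero-variance input flags the
    correlation as undefined (None).
    """
    x = np.asarray(fpkm, dtype=float)
    y = np.asarray(signal, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("fpkm and signal must be paired 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least three paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    if np.std(x) == 0 or np.std(y) == 0:
        pcc, pcc_p = None, None
    else:
        r = stats.pearsonr(x, y)
        pcc, pcc_p = float(r.statistic), float(r.pvalue)

    # expression groups (tertiles by default), rank-sum between signals
    quantiles = np.quantile(x, np.linspace(0, 1, n_groups + 1))
    group_idx = np.clip(np.searchsorted(quantiles, x, side="right") - 1, 0, n_groups - 1)
    comparisons = []
    for a, b in combinations(range(n_groups), 2):
        ga, gb = y[group_idx == a], y[group_idx == b]
        if len(ga) < 2 or len(gb) < 2:
            continue
        u, p = ranksum_test(ga, gb)
        comparisons.append(
            {"groups": (a, b), "statistic": u, "p_value": p, "stars": stars_for_p(p)}
        )
    return {"pcc": pcc, "pcc_p": pcc_p, "group_comparisons": comparisons, "n_groups": n_groups}


# ---------------------------------------------------------------------------
# RBP peak binning

SPLICING_FACTOR_PREFIXES = ("HNRNP", "SRSF", "SF3", "U2AF", "TRA2")


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED6+/narrowPeak-like peak file (name = factor, score)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"]
    return df


def is_splicing_factor(name: str, prefixes: Sequence[str] = SPLICING_FACTOR_PREFIXES) -> bool:
    return name.upper().startswith(tuple(p.upper() for p in prefixes))


def bin_rbp_peaks(
    peaks: pd.DataFrame,
    events: Sequence[CassetteExonEvent],
    bin_size: int = 100,
    span: int = 1000,
    score_filter: float = 1000,
    factors: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Bin RBP peak midpoints around splice sites into fixed intervals.

    Peaks below ``score_filter`` are removed.  Each surviving peak midpoint
    within ``span`` bp of a splice site contributes to the bin of its
    position relative to that site, oriented 5'->3' in transcription
    direction.  Frequency is the per-bin count divided by the bin width;
    ``frequency_per_site`` additionally divides by the number of sites.

    Returns a frame with one row per (site_kind, bin_start).
    """
    if bin_size <= 0 or span % bin_size:
        raise ValueError("span must be a positive multiple of bin_size")
    sel = peaks[peaks["score"] >= score_filter]
    if factors is not None:
        sel = sel[sel["name"].isin(set(factors))]
    mids = ((sel["start"].to_numpy() + sel["end"].to_numpy()) // 2).astype(np.int64)
    chroms = sel["chrom"].to_numpy()

    n_bins = 2 * span // bin_size
    bin_starts = np.arange(-span, span, bin_size)
    rows = []
    for site_kind, site_of in (("acceptor_3p", lambda e: e.acceptor), ("donor_5p", lambda e: e.donor)):
        counts = np.zeros(n_bins, dtype=np.int64)
        n_sites = 0
        for ev in events:
            site = site_of(ev)
            n_sites += 1
            on_chrom = chroms == site.chrom
            if not on_chrom.any():
                continue
            m = mids[on_chrom]
            rel = m - site.pos if site.strand == "+" else site.pos - m - 1
            inside = (rel >= -span) & (rel < span)
            if inside.any():
                idx = (rel[inside] + span) // bin_size
                np.add.at(counts, idx, 1)
        for b, c in zip(bin_starts, counts):
            rows.append(
                {
                    "site_kind": site_kind,
                    "bin_start": int(b),
                    "count": int(c),
                    "frequency": c / bin_size,
                    "frequency_per_site": c / bin_size / max(n_sites, 1),
                }
            )
    return pd.DataFrame(rows)


def rbp_fold_profile(
    peaks: pd.DataFrame,
    events: Sequence[CassetteExonEvent],
    splicing_factors: Sequence[str],
    bin_size: int = 100,
    span: int = 1000,
    score_filter: float = 1000,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Splicing-factor vs non-splicing-factor binding-frequency fold."""
    all_names = set(peaks["name"])
    other = sorted(all_names - set(splicing_factors))
    sp = bin_rbp_peaks(peaks, events, bin_size, span, score_filter, factors=splicing_factors)
    ns = bin_rbp_peaks(peaks, events, bin_size, span, score_filter, factors=other)
    merged = sp.merge(ns, on=["site_kind", "bin_start"], suffixes=("_splicing", "_other"))
    merged["fold"] = (merged["frequency_splicing"] + pseudocount) / (merged["frequency_other"] + pseudocount)
    return merged
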