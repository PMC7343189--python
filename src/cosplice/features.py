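"""Feature-window construction around splice sites.

Every window is read in the 5'->3' direction of transcription: for a -
strand exon the genomic slice is reversed (and the DNA complemented), so
position 0 is always the base Pol II transcribes first.  DNA is one-hot
encoded over four channels (A, C, G, T; ambiguity codes give all-zero
rows); epigenomic tracks are capped and scaled to [0, 1] — ChIP-style
enrichment tracks use the -log10 Poisson p-value against a local
background, clipped at p = 1e-2 (i.e. a cap of 2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import CassetteExonEvent, SpliceSite
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

DNA_CHANNELS = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# one-hot lookup over byte values; unknown bases map to the all-zero row
_ONEHOT_LUT = np.zeros((256, 4), dtype=np.float32)
for _i, _b in enumerate("ACGT"):
    _ONEHOT_LUT[ord(_b), _i] = 1.0
    _ONEHOT_LUT[ord(_b.lower()), _i] = 1.0


@dataclass
class FeatureWindow:
    """Time-ordered (positions x channels) matrix around one splice site."""

    site: SpliceSite
    values: np.ndarray  # (T, C)
    channel_names: list[str]
    dna_channels: tuple[str, ...] = DNA_CHANNELS

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_names):
            raise ValueError("values shape inconsistent with channel_names")


@dataclass
class EventTensorPair:
    acceptor_window: FeatureWindow
    donor_window: FeatureWindow
    label: int | None = None


def one_hot(dna_sequence: str) -> np.ndarray:
    """One-hot encode a DNA string into a (T, 4) array, channels A,C,G,T."""
    raw = np.frombuffer(dna_sequence.encode("ascii"), dtype=np.uint8)
    out = _ONEHOT_LUT[raw]
    n_unknown = int(len(raw) - out.sum())
    if n_unknown and not set(dna_sequence.upper()) <= set("ACGTN"):
        logger.warning("one_hot: %d non-ACGTN symbols treated as N", n_unknown)
    return out.copy()


def poisson_enrichment(obs_count, background_rate: float, cap: float = 2.0):
    """-log10 upper-tail Poisson p-value, clipped at ``cap``.

    P(X >= k | Poisson(lambda)) measures how surprising an observed read
    count is against a background rate; the cap corresponds to a p-value
    floor of 10**-cap (default 1e-2).
    """
    if background_rate <= 0:
        raise ValueError("background rate must be positive")
    k = np.asarray(obs_count)
    if np.any(k < 0):
        raise ValueError("observed count must be non-negative")
    p = stats.poisson.sf(k - 1, background_rate)  # P(X >= k)
    with np.errstate(divide="ignore"):
        enrich = np.minimum(-np.log10(p), cap)
    if np.ndim(obs_count) == 0:
        return float(enrich)
    return enrich


def scale01(values, cap: float) -> np.ndarray:
    """Clip to [0, cap] then divide by cap."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return np.clip(np.asarray(values, dtype=np.float32), 0.0, cap) / np.float32(cap)


def _fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Slice a genome (dict of str, or pyfaidx.Fasta); out-of-bounds pads N."""
    if hasattr(genome, "keys") and not isinstance(genome, dict):
        seq_len = len(genome[chrom])
    elif isinstance(genome, dict):
        seq_len = len(genome[chrom])
    else:
        raise TypeError("genome must be a mapping of chromosome -> sequence")
    lo, hi = max(start, 0), min(end, seq_len)
    core = str(genome[chrom][lo:hi]) if hi > lo else ""
    return "N" * (lo - start) + core + "N" * (end - hi)


def extract_sequence_window(genome, site: SpliceSite, flank_bp: int) -> str:
    """DNA around a splice site, oriented 5'->3' in transcription direction."""
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    seq = _fetch_sequence(genome, site.chrom, site.pos - flank_bp, site.pos + flank_bp)
    if site.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def extract_track_window(track: SignalTrack, site: SpliceSite, flank_bp: int) -> np.ndarray:
    """Track values around a splice site, 5'->3' oriented (reversed on -)."""
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    vals = track.values(site.chrom, site.pos - flank_bp, site.pos + flank_bp)
    if site.strand == "-":
        vals = vals[::-1].copy()
    return vals


def extract_window(track_or_genome, site: SpliceSite, flank_bp: int):
    """Dispatch to the sequence or track extractor by argument type."""
    if isinstance(track_or_genome, SignalTrack):
        return extract_track_window(track_or_genome, site, flank_bp)
    return extract_sequence_window(track_or_genome, site, flank_bp)


def reverse_time(window: FeatureWindow, channels_subset: Sequence[str]) -> FeatureWindow:
    """Reverse the position axis of the selected channels only."""
    unknown = set(channels_subset) - set(window.channel_names)
    if unknown:
        raise KeyError(f"unknown channels: {sorted(unknown)}")
    values = window.values.copy()
    idx = [window.channel_names.index(c) for c in channels_subset]
    values[:, idx] = values[::-1, idx]
    return FeatureWindow(
        site=window.site,
        values=values,
        channel_names=list(window.channel_names),
        dna_channels=window.dna_channels,
    )


@dataclass
class SpliceDataset:
    """Batched feature tensors for a set of cassette-exon events.

    X_acc / X_don have shape (N, T, C) with T = 2 * flank and C = 4 DNA
    channels followed by the epigenomic channels.  y holds 1 (included),
    0 (skipped) or -1 (unlabelled).
    """

    event_ids: list[str]
    X_acc: np.ndarray
    X_don: np.ndarray
    y: np.ndarray
    channel_names: list[str]
    flank: int

    def __len__(self) -> int:
        return len(self.event_ids)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def epigenomic_channels(self) -> list[str]:
        return [c for c in self.channel_names if c not in DNA_CHANNELS]

    def subset_channels(self, channels: Sequence[str]) -> "SpliceDataset":
        """Keep only the named channels (order preserved as given)."""
        unknown = set(channels) - set(self.channel_names)
        if unknown:
            raise KeyError(f"unknown channels: {sorted(unknown)}")
        idx = [self.channel_names.index(c) for c in channels]
        return SpliceDataset(
            event_ids=list(self.event_ids),
            X_acc=np.ascontiguousarray(self.X_acc[:, :, idx]),
            X_don=np.ascontiguousarray(self.X_don[:, :, idx]),
            y=self.y.copy(),
            channel_names=list(channels),
            flank=self.flank,
        )

    def drop_channel(self, channel: str) -> "SpliceDataset":
        return self.subset_channels([c for c in self.channel_names if c != channel])

    def dna_only(self) -> "SpliceDataset":
        return self.subset_channels([c for c in self.channel_names if c in DNA_CHANNELS])

    def reverse_time(self, channels: Sequence[str] | None = None) -> "SpliceDataset":
        """Reverse the position axis of the selected channels (default: all
        epigenomic channels, leaving DNA in the forward direction)."""
        if channels is None:
            channels = self.epigenomic_channels
        unknown = set(channels) - set(self.channel_names)
        if unknown:
            raise KeyError(f"unknown channels: {sorted(unknown)}")
        idx = [self.channel_names.index(c) for c in channels]
        X_acc = self.X_acc.copy()
        X_don = self.X_don.copy()
        X_acc[:, :, idx] = X_acc[:, ::-1, idx]
        X_don[:, :, idx] = X_don[:, ::-1, idx]
        return SpliceDataset(
            event_ids=list(self.event_ids),
            X_acc=X_acc,
            X_don=X_don,
            y=self.y.copy(),
            channel_names=list(self.channel_names),
            flank=self.flank,
        )

    def subset_events(self, indices) -> "SpliceDataset":
        indices = np.asarray(indices)
        return SpliceDataset(
            event_ids=[self.event_ids[i] for i in indices],
            X_acc=self.X_acc[indices],
            X_don=self.X_don[indices],
            y=self.y[indices],
            channel_names=list(self.channel_names),
            flank=self.flank,
        )

    def save(self, path: str | Path) -> None:
        """Write arrays to <path>.npz plus a JSON sidecar <path>.json."""
        path = Path(path)
        base = path.with_suffix("") if path.suffix == ".npz" else path
        np.savez_compressed(
            base.with_suffix(".npz"),
            X_acc=self.X_acc,
            X_don=self.X_don,
            y=self.y,
        )
        sidecar = {
            "event_ids": self.event_ids,
            "channel_names": self.channel_names,
            "flank": self.flank,
        }
        base.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "SpliceDataset":
        path = Path(path)
        base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
        arrays = np.load(base.with_suffix(".npz"))
        sidecar = json.loads(base.with_suffix(".json").read_text())
        return cls(
            event_ids=sidecar["event_ids"],
            X_acc=arrays["X_acc"],
            X_don=arrays["X_don"],
            y=arrays["y"],
            channel_names=sidecar["channel_names"],
            flank=sidecar["flank"],
        )


_LABEL_CODE = {"included": 1, "skipped": 0, None: -1}


def build_dataset(
    events: Iterable[CassetteExonEvent],
    genome: Mapping[str, str],
    tracks: Sequence[SignalTrack] = (),
    flank_bp: int = 100,
    track_caps: Mapping[str, float] | None = None,
) -> SpliceDataset:
    """Assemble acceptor/donor feature tensors for a set of events.

    Each event yields two windows of T = 2 * flank_bp positions and
    C = 4 + len(tracks) channels.  Epigenomic values are scaled to [0, 1]:
    a track with a known cap (``track_caps[name]`` or a ``cap`` attribute)
    is clipped and divided by it; otherwise the channel is min-max scaled
    over the extracted windows.  Events on contigs missing from the genome
    are dropped (counted in the log).
    """
    events = list(events)
    track_caps = dict(track_caps or {})

    kept: list[CassetteExonEvent] = []
    n_dropped = 0
    for ev in events:
        if ev.exon.chrom not in genome:
            n_dropped += 1
            continue
        kept.append(ev)
    if n_dropped:
        logger.warning("build_dataset: dropped %d events on missing contigs", n_dropped)

    T = 2 * flank_bp
    C = 4 + len(tracks)
    N = len(kept)
    X_acc = np.zeros((N, T, C), dtype=np.float32)
    X_don = np.zeros((N, T, C), dtype=np.float32)
    y = np.full(N, -1, dtype=np.int8)
    ids = []

    for i, ev in enumerate(kept):
        ids.append(ev.event_id)
        X_acc[i, :, :4] = one_hot(extract_sequence_window(genome, ev.acceptor, flank_bp))
        X_don[i, :, :4] = one_hot(extract_sequence_window(genome, ev.donor, flank_bp))
        for j, track in enumerate(tracks):
            X_acc[i, :, 4 + j] = extract_track_window(track, ev.acceptor, flank_bp)
            X_don[i, :, 4 + j] = extract_track_window(track, ev.donor, flank_bp)
        y[i] = _LABEL_CODE.get(ev.label, -1)

    for j, track in enumerate(tracks):
        cap = track_caps.get(track.name, getattr(track, "cap", None))
        col_a, col_d = X_acc[:, :, 4 + j], X_don[:, :, 4 + j]
        if cap is not None:
            X_acc[:, :, 4 + j] = scale01(col_a, cap)
            X_don[:, :, 4 + j] = scale01(col_d, cap)
        else:
            lo = min(col_a.min(initial=np.inf), col_d.min(initial=np.inf)) if N else 0.0
            hi = max(col_a.max(initial=-np.inf), col_d.max(initial=-np.inf)) if N else 1.0
            span = hi - lo
            if N and span > 0:
                X_acc[:, :, 4 + j] = (col_a - lo) / span
                X_don[:, :, 4 + j] = (col_d - lo) / span
            elif N:
                X_acc[:, :, 4 + j] = 0.0
                X_don[:, :, 4 + j] = 0.0

    channel_names = list(DNA_CHANNELS) + [t.name for t in tracks]
    return SpliceDataset(
        event_ids=ids,
        X_acc=X_acc,
        X_don=X_don,
        y=y,
        channel_names=channel_names,
        flank=flank_bp,
    )
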