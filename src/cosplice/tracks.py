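"""Per-base signal track accessors (bigWig, bedGraph, in-memory arrays).

All accessors share one contract: ``values(chrom, start, end)`` returns a
float vector of length ``end - start`` on 0-based half-open coordinates;
bases not covered by the track (or outside chromosome bounds) take the
track's ``fill`` value.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SignalTrack:
    """Base accessor; subclasses implement :meth:`values`."""

    name: str = "track"
    fill: float = 0.0

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        raise NotImplementedError


class ArrayTrack(SignalTrack):
    """Dense in-memory track: one float array per chromosome."""

    def __init__(self, name: str, data: Mapping[str, np.ndarray], fill: float = 0.0):
        self.name = name
        self.data = {c: np.asarray(v, dtype=np.float32) for c, v in data.items()}
        self.fill = fill

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self.data:
            raise KeyError(f"track {self.name}: unknown chromosome {chrom!r}")
        arr = self.data[chrom]
        out = np.full(end - start, self.fill, dtype=np.float32)
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        elif end <= 0 or start >= len(arr):
            logger.warning("track %s: window %s:%d-%d entirely outside chromosome", self.name, chrom, start, end)
        return out


class ConstantTrack(SignalTrack):
    def __init__(self, name: str, value: float, chroms: set[str] | None = None):
        self.name = name
        self.value = value
        self.chroms = chroms

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if self.chroms is not None and chrom not in self.chroms:
            raise KeyError(f"track {self.name}: unknown chromosome {chrom!r}")
        return np.full(end - start, self.value, dtype=np.float32)


class BedGraphTrack(ArrayTrack):
    """bedGraph file (0-based half-open) materialised as dense arrays.

    Suited to toy genomes; for genome-scale data use :class:`BigWigTrack`.
    """

    def __init__(self, name: str, path: str | Path, chrom_sizes: Mapping[str, int], fill: float = 0.0):
        df = pd.read_csv(
            path,
            sep="\t",
            comment="t",  # skips "track" header lines
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float32},
        )
        data = {c: np.full(n, fill, dtype=np.float32) for c, n in chrom_sizes.items()}
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in data:
                raise KeyError(f"bedGraph {path}: chromosome {chrom!r} absent from chrom_sizes")
            arr = data[chrom]
            for s, e, v in zip(sub["start"].values, sub["end"].values, sub["value"].values):
                arr[max(s, 0) : min(e, len(arr))] = v
        super().__init__(name, data, fill=fill)


class BigWigTrack(SignalTrack):
    """bigWig accessor via pyBigWig; NaN (uncovered) replaced by fill."""

    def __init__(self, name: str, path: str | Path, fill: float = 0.0):
        import pyBigWig

        self.name = name
        self.bw = pyBigWig.open(str(path))
        self.fill = fill

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        chroms = self.bw.chroms()
        if chrom not in chroms:
            raise KeyError(f"track {self.name}: unknown chromosome {chrom!r}")
        size = chroms[chrom]
        out = np.full(end - start, self.fill, dtype=np.float32)
        lo, hi = max(start, 0), min(end, size)
        if hi > lo:
            vals = np.asarray(self.bw.values(chrom, lo, hi), dtype=np.float32)
            vals[np.isnan(vals)] = self.fill
            out[lo - start : hi - start] = vals
        return out


def load_track(name: str, path: str | Path, chrom_sizes: Mapping[str, int] | None = None, fill: float = 0.0) -> SignalTrack:
    """Open a track file by extension (.bw/.bigwig or .bedgraph/.bg)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".bw", ".bigwig"):
        return BigWigTrack(name, path, fill=fill)
    if suffix in (".bedgraph", ".bg", ".bdg"):
        if chrom_sizes is None:
            raise ValueError("bedGraph tracks need chrom_sizes")
        return BedGraphTrack(name, path, chrom_sizes, fill=fill)
    raise ValueError(f"unrecognised track format: {path}")


def write_bedgraph(data: Mapping[str, np.ndarray], path: str | Path, decimals: int = 4) -> None:
    """Write dense per-chromosome arrays as a run-length-merged bedGraph."""
    with open(path, "w") as fh:
        for chrom in data:
            arr = np.round(np.asarray(data[chrom], dtype=float), decimals)
            if len(arr) == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.{decimals}g}\n")
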