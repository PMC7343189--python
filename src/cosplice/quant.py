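"""Exon-level expression (FPKM) and junction-based percent-spliced-in (PSI).

Two labelling routes are supported:

* FPKM binarization — an exon is called "included" when its read count,
  normalised per kilobase of exon and per million mapped reads, reaches a
  threshold (default 1).  This only asks whether there is enough evidence
  that the exon made it into mature transcripts.
* PSI — the fraction of junction-spanning evidence supporting inclusion,
  with inclusion reads normalised by the larger footprint (L_i + L_f) they
  can land on and exclusion reads by the fragment length L_f:

      psi = 100 * (F_incl / (L_i + L_f)) / (F_incl/(L_i+L_f) + F_excl/L_f)

  Cutoffs at 20% / 80% assign skipped / included classes; the band scheme
  used by the enrichment profiles takes 40-60% as the "mid" class instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

SKIPPED = "skipped"
MID = "mid"
INCLUDED = "included"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class ExonExpression:
    exon_id: str
    count: int
    fpkm: float
    expressed: bool


@dataclass(frozen=True)
class JunctionCounts:
    """Junction read support for one exon.

    F_incl: reads supporting inclusion; F_excl: reads supporting exclusion
    (flanking-exon junction); L_f: fragment length in bp; L_i: exon length.
    """

    F_incl: int
    F_excl: int
    L_f: int
    L_i: int

    def __post_init__(self) -> None:
        if self.L_f <= 0 or self.L_i <= 0:
            raise ValueError("L_f and L_i must be positive")
        if self.F_incl < 0 or self.F_excl < 0:
            raise ValueError("junction counts must be non-negative")


@dataclass(frozen=True)
class PSIRecord:
    exon_id: str
    psi: float | None  # percent in [0, 100]; None when undefined
    psi_class: str


def compute_fpkm(count: float, exon_length_bp: int, total_mapped_reads: float) -> float:
    """Fragments per kilobase of exon per million mapped reads."""
    if exon_length_bp <= 0:
        raise ValueError("exon length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("library size must be positive")
    return count / ((exon_length_bp / 1e3) * (total_mapped_reads / 1e6))


def binarize_expression(fpkm: float, threshold: float = 1.0) -> bool:
    """An exon counts as expressed when FPKM >= threshold (closed boundary)."""
    return fpkm >= threshold


def compute_psi(jc: JunctionCounts) -> float | None:
    """Length-normalised percent spliced in; None when no junction evidence.

    Inclusion reads can start anywhere over the exon plus one fragment
    length, exclusion reads only over one fragment length, hence the
    asymmetric normalisation.
    """
    if jc.F_incl + jc.F_excl == 0:
        return None
    f_incl = jc.F_incl / (jc.L_i + jc.L_f)
    f_excl = jc.F_excl / jc.L_f
    return 100.0 * f_incl / (f_incl + f_excl)


def classify_psi(psi: float | None, low: float = 20.0, high: float = 80.0) -> str:
    """Class from PSI percent: <=low skipped, >=high included, else mid."""
    if psi is None:
        return UNDEFINED
    if not 0.0 <= psi <= 100.0:
        raise ValueError(f"psi out of range: {psi}")
    if psi <= low:
        return SKIPPED
    if psi >= high:
        return INCLUDED
    return MID


def classify_psi_band(psi: float | None, low: float = 20.0, band: tuple[float, float] = (40.0, 60.0), high: float = 80.0) -> str:
    """Banded scheme used by enrichment profiles: mid means 40-60% PSI.

    Events between the skipped cutoff and the band, or between the band and
    the included cutoff, fall outside every class and return "undefined".
    """
    if psi is None:
        return UNDEFINED
    if psi <= low:
        return SKIPPED
    if psi >= high:
        return INCLUDED
    if band[0] <= psi <= band[1]:
        return MID
    return UNDEFINED


def psi_record(exon_id: str, jc: JunctionCounts, scheme: str = "cutoff2080") -> PSIRecord:
    """Build a PSIRecord under a labelling scheme preset.

    scheme: "cutoff2080" (skipped <=20 / included >=80 / mid between) or
    "band406080" (mid restricted to the 40-60% band).
    """
    psi = compute_psi(jc)
    if scheme == "cutoff2080":
        cls = classify_psi(psi)
    elif scheme == "band406080":
        cls = classify_psi_band(psi)
    else:
        raise ValueError(f"unknown label scheme {scheme!r}")
    return PSIRecord(exon_id=exon_id, psi=psi, psi_class=cls)


def quantify_tables(
    counts_tsv: str | Path,
    junctions_tsv: str | Path,
    exon_lengths: dict[str, int],
    total_mapped_reads: float,
    fragment_length: int = 100,
    fpkm_threshold: float = 1.0,
    scheme: str = "cutoff2080",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify expression and PSI from TSV tables.

    counts_tsv columns: exon_id, count.  junctions_tsv columns: exon_id,
    F_incl, F_excl.  Returns (expression_df, psi_df).
    """
    counts = pd.read_csv(counts_tsv, sep="\t")
    juncs = pd.read_csv(junctions_tsv, sep="\t")

    expr_rows = []
    for row in counts.itertuples(index=False):
        if row.exon_id not in exon_lengths:
            raise KeyError(f"no length known for exon {row.exon_id}")
        fpkm = compute_fpkm(row.count, exon_lengths[row.exon_id], total_mapped_reads)
        expr_rows.append(
            {
                "exon_id": row.exon_id,
                "count": int(row.count),
                "fpkm": fpkm,
                "expressed": binarize_expression(fpkm, fpkm_threshold),
            }
        )

    psi_rows = []
    for row in juncs.itertuples(index=False):
        jc = JunctionCounts(
            F_incl=int(row.F_incl),
            F_excl=int(row.F_excl),
            L_f=fragment_length,
            L_i=exon_lengths[row.exon_id],
        )
        rec = psi_record(row.exon_id, jc, scheme=scheme)
        psi_rows.append({"exon_id": rec.exon_id, "psi": rec.psi, "psi_class": rec.psi_class})

    return pd.DataFrame(expr_rows), pd.DataFrame(psi_rows)
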