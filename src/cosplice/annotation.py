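"""Gene-annotation parsing and cassette-exon candidate enumeration.

Internal exons of multi-exon protein-coding transcripts are the candidate
cassette exons: the first and last exon of a transcript cannot be skipped
under the exon-definition model, so they are excluded.  Coordinates are
held 0-based half-open throughout; GTF input is read as 1-based inclusive
and BED output written 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger(__name__)

ACCEPTOR = "acceptor_3p"
DONOR = "donor_5p"


@dataclass(frozen=True)
class ExonRecord:
    """One exon of one transcript, 0-based half-open coordinates.

    ``rank`` is the ordinal position of the exon within its transcript in
    transcription direction (1 = first exon transcribed).
    """

    exon_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"exon {self.exon_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"exon {self.exon_id}: unknown strand {self.strand!r}")
        if self.rank < 1:
            raise ValueError(f"exon {self.exon_id}: rank must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpliceSite:
    """An exon boundary.

    ``pos`` is the 0-based genomic coordinate of the boundary: for a +
    strand exon the 3' acceptor sits at ``start`` and the 5' donor at
    ``end``; on the - strand the converse.
    """

    chrom: str
    pos: int
    kind: str  # ACCEPTOR or DONOR
    strand: str

    def __post_init__(self) -> None:
        if self.kind not in (ACCEPTOR, DONOR):
            raise ValueError(f"unknown splice-site kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass(frozen=True)
class CassetteExonEvent:
    """An internal exon with its two splice sites and an optional label."""

    exon: ExonRecord
    acceptor: SpliceSite
    donor: SpliceSite
    label: str | None = None  # "included" | "skipped" | None

    @property
    def event_id(self) -> str:
        return self.exon.exon_id


def splice_sites_of(exon: ExonRecord) -> tuple[SpliceSite, SpliceSite]:
    """Return (acceptor, donor) for an exon, strand-aware."""
    if exon.strand == "+":
        acc = SpliceSite(exon.chrom, exon.start, ACCEPTOR, "+")
        don = SpliceSite(exon.chrom, exon.end, DONOR, "+")
    else:
        acc = SpliceSite(exon.chrom, exon.end, ACCEPTOR, "-")
        don = SpliceSite(exon.chrom, exon.start, DONOR, "-")
    return acc, don


def parse_annotation(
    gtf_source: str | Path,
    unique: bool = False,
    drop_xy_ambiguous: bool = True,
) -> list[ExonRecord]:
    """Parse exon features from a GENCODE-style GTF.

    Parameters
    ----------
    gtf_source
        Path to a GTF file (1-based inclusive coordinates).
    unique
        Collapse duplicate exons sharing (chrom, start, end, strand); the
        first occurrence wins.  Duplicates arise from overlapping isoforms.
    drop_xy_ambiguous
        Remove exons of genes annotated on both chrX and chrY
        (pseudoautosomal-style duplicates that map ambiguously).

    Returns
    -------
    list of :class:`ExonRecord` with per-transcript ranks assigned in
    transcription direction.
    """
    try:
        db = gffutils.create_db(
            str(gtf_source),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises a zoo of parse errors
        raise ValueError(f"failed to parse GTF {gtf_source}: {exc}") from exc

    by_transcript: dict[str, list] = {}
    gene_chroms: dict[str, set[str]] = {}
    n_rejected = 0
    for feat in db.features_of_type("exon"):
        if feat.strand not in ("+", "-"):
            n_rejected += 1
            logger.warning("rejecting exon with unknown strand %r at %s:%s", feat.strand, feat.seqid, feat.start)
            continue
        try:
            gene_id = feat.attributes["gene_id"][0]
            transcript_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise ValueError(
                f"malformed attribute field (missing {exc}) at {feat.seqid}:{feat.start}-{feat.end}"
            ) from exc
        gene_chroms.setdefault(gene_id, set()).add(feat.seqid)
        by_transcript.setdefault(transcript_id, []).append((feat, gene_id))
    if n_rejected:
        logger.warning("rejected %d exon records with unknown strand", n_rejected)

    ambiguous_genes = {
        g
        for g, chroms in gene_chroms.items()
        if drop_xy_ambiguous and _has_xy_ambiguity(chroms)
    }

    records: list[ExonRecord] = []
    for transcript_id, feats in by_transcript.items():
        strands = {f.strand for f, _ in feats}
        if len(strands) > 1:
            raise ValueError(f"transcript {transcript_id} has exons on both strands: {sorted(strands)}")
        strand = strands.pop()
        # rank in transcription direction: genomic order for +, reversed for -
        feats_sorted = sorted(feats, key=lambda t: t[0].start, reverse=(strand == "-"))
        for rank, (feat, gene_id) in enumerate(feats_sorted, start=1):
            if gene_id in ambiguous_genes:
                continue
            exon_id = feat.attributes.get("exon_id", [f"{transcript_id}.exon{rank}"])[0]
            records.append(
                ExonRecord(
                    exon_id=exon_id,
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    chrom=feat.seqid,
                    start=feat.start - 1,  # GTF 1-based inclusive -> 0-based half-open
                    end=feat.end,
                    strand=strand,
                    rank=rank,
                )
            )

    if unique:
        records = unique_exons(records)
    return records


def _has_xy_ambiguity(chroms: set[str]) -> bool:
    norm = {c.lower().removeprefix("chr") for c in chroms}
    return "x" in norm and "y" in norm


def unique_exons(records: Iterable[ExonRecord]) -> list[ExonRecord]:
    """Collapse exons sharing (chrom, start, end, strand); first wins."""
    seen: set[tuple] = set()
    out: list[ExonRecord] = []
    for rec in records:
        key = (rec.chrom, rec.start, rec.end, rec.strand)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def extract_cassette_candidates(
    exons: Sequence[ExonRecord],
    labels: dict[str, str] | None = None,
    deduplicate: bool = True,
) -> list[CassetteExonEvent]:
    """Enumerate internal exons as cassette-exon candidate events.

    Transcripts contribute every exon that is neither first nor last in
    transcription order; transcripts with fewer than three exons contribute
    nothing.  Events are deduplicated across transcripts at the
    (chrom, start, end, strand) level afterwards.

    Parameters
    ----------
    exons
        Exon records with per-transcript ranks (see :func:`parse_annotation`).
    labels
        Optional mapping exon_id -> "included"/"skipped".
    """
    by_transcript: dict[str, list[ExonRecord]] = {}
    for rec in exons:
        by_transcript.setdefault(rec.transcript_id, []).append(rec)

    events: list[CassetteExonEvent] = []
    for transcript_id, recs in by_transcript.items():
        strands = {r.strand for r in recs}
        if len(strands) > 1:
            raise ValueError(f"transcript {transcript_id}: inconsistent strand across exons")
        if len(recs) < 3:
            continue
        recs = sorted(recs, key=lambda r: r.rank)
        for rec in recs[1:-1]:
            acc, don = splice_sites_of(rec)
            label = labels.get(rec.exon_id) if labels else None
            events.append(CassetteExonEvent(exon=rec, acceptor=acc, donor=don, label=label))

    if deduplicate:
        seen: set[tuple] = set()
        deduped = []
        for ev in events:
            key = (ev.exon.chrom, ev.exon.start, ev.exon.end, ev.exon.strand)
            if key not in seen:
                seen.add(key)
                deduped.append(ev)
        events = deduped
    return events


def events_to_bed(events: Iterable[CassetteExonEvent], path: str | Path) -> None:
    """Write events as BED6 (0-based half-open; name=exon_id, score=0)."""
    with open(path, "w") as fh:
        for ev in events:
            ex = ev.exon
            fh.write(f"{ex.chrom}\t{ex.start}\t{ex.end}\t{ex.exon_id}\t0\t{ex.strand}\n")


def events_from_bed(path: str | Path, labels: dict[str, str] | None = None) -> list[CassetteExonEvent]:
    """Read BED6 events written by :func:`events_to_bed`."""
    events = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{i}: expected BED6, got {len(fields)} fields")
            chrom, start, end, name, _score, strand = fields[:6]
            rec = ExonRecord(
                exon_id=name,
                gene_id=name,
                transcript_id=name,
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                rank=2,  # internal by construction when written from events
            )
            acc, don = splice_sites_of(rec)
            label = labels.get(name) if labels else None
            events.append(CassetteExonEvent(exon=rec, acceptor=acc, donor=don, label=label))
    return events


def relabel(event: CassetteExonEvent, label: str | None) -> CassetteExonEvent:
    return replace(event, label=label)
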