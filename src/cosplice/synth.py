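"""Seeded synthetic data: toy genome, annotation, tracks, reads, peaks.

The generator emulates the data context the rest of the package consumes,
with known ground truth.  A toy chromosome carries non-overlapping
multi-exon genes on both strands; each internal exon is assigned a class
(included / skipped, optionally a mid-PSI band) and a true inclusion
fraction.  Epigenomic channels add class-dependent Gaussian bumps at
configurable offsets from the splice sites (strand-oriented), optional
5'->3' positional skew between the classes, and white noise.  Junction
reads are drawn binomially at the true inclusion fraction, re-weighted so
the length-normalised PSI estimator is centred on the truth; exon counts
are Poisson with class-dependent rates so FPKM binarization recovers the
class.  All randomness flows from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import CassetteExonEvent, ExonRecord, events_to_bed, extract_cassette_candidates
from .features import SpliceDataset, build_dataset
from .tracks import ArrayTrack, write_bedgraph

_RC = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class BumpSpec:
    """One Gaussian bump anchored to a splice site.

    ``offset`` is bp downstream (transcription direction) of the site;
    ``width`` is the Gaussian sigma in bp.
    """

    site: str  # "acceptor" | "donor"
    offset: int
    width: float


@dataclass(frozen=True)
class ChannelSpec:
    """One synthetic epigenomic channel.

    kind "bump": Gaussian bumps (class-dependent amplitude) at the listed
    anchors; ``asymmetry`` (bp) shifts included-class bumps downstream and
    skipped-class bumps upstream, giving the signal a 5'->3' positional
    code.  kind "ramp": monotone 5'->3' gradient across the window around
    the anchor site, scaled by amplitude and the sign of ``asymmetry``.
    kind "noise": white noise only.
    """

    name: str
    kind: str = "bump"  # bump | ramp | noise
    site: str = "acceptor"
    center_offset: int = 0
    width: float = 30.0
    amplitude_included: float = 1.0
    amplitude_skipped: float = 0.0
    noise_sd: float = 0.1
    asymmetry: float = 0.0
    extra_bumps: tuple[BumpSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.amplitude_included < 0 or self.amplitude_skipped < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def bumps(self) -> tuple[BumpSpec, ...]:
        if self.kind != "bump":
            return ()
        return (BumpSpec(self.site, self.center_offset, self.width), *self.extra_bumps)

    def amplitude(self, cls: str) -> float:
        if cls == "included":
            return self.amplitude_included
        if cls == "skipped":
            return self.amplitude_skipped
        return 0.5 * (self.amplitude_included + self.amplitude_skipped)  # mid band

    @property
    def cap(self) -> float:
        """Scaling cap handed to the featurizer so values land in [0, 1]."""
        peak = max(self.amplitude_included, self.amplitude_skipped)
        return max(peak + 4.0 * self.noise_sd, 1e-6)


@dataclass(frozen=True)
class RBPFactorSpec:
    """An RBP whose peaks sit at a fixed offset from a splice site; a
    factor with ``site="uniform"`` scatters decoy peaks genome-wide."""

    name: str
    site: str = "acceptor"  # acceptor | donor | uniform
    offset: int = 0
    peaks_per_event: float = 1.0
    score: int = 1000
    peak_width: int = 20


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (150, 300)
    intron_len: tuple[int, int] = (300, 500)
    intergenic_len: tuple[int, int] = (200, 400)
    p_included: float = 0.5
    mid_fraction: float = 0.0  # fraction of events in the 40-60% PSI band
    channels: tuple[ChannelSpec, ...] = ()
    fragment_length: int = 100
    read_depth: float = 50.0
    total_mapped_reads: float = 2e7
    canonical_fraction: float = 0.95
    psi_included_range: tuple[float, float] = (0.85, 1.0)
    psi_skipped_range: tuple[float, float] = (0.0, 0.15)
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if not 0 < self.p_included < 1:
            raise ValueError("p_included must lie in (0, 1)")
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}")


@dataclass
class SyntheticData:
    """Everything one simulation run produced, with ground truth."""

    config: SyntheticConfig
    seed: int
    genome: dict[str, str]
    exons: list[ExonRecord]
    events: list[CassetteExonEvent]  # labelled internal exons
    truth: pd.DataFrame  # exon_id, cls, p_true, exon_len
    tracks: list[ArrayTrack]
    counts: pd.DataFrame  # exon_id, count
    junctions: pd.DataFrame  # exon_id, F_incl, F_excl
    peaks: pd.DataFrame | None = None

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def to_dataset(self, flank_bp: int = 100, channels: Sequence[str] | None = None) -> SpliceDataset:
        tracks = self.tracks
        if channels is not None:
            tracks = [t for t in tracks if t.name in set(channels)]
        return build_dataset(self.events, self.genome, tracks, flank_bp=flank_bp)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Materialise FASTA, GTF, bedGraph tracks, TSV counts, BED files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        fasta = outdir / "genome.fa"
        with open(fasta, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths["genome"] = fasta

        gtf = outdir / "annotation.gtf"
        with open(gtf, "w") as fh:
            by_tx: dict[str, list[ExonRecord]] = {}
            for rec in self.exons:
                by_tx.setdefault(rec.transcript_id, []).append(rec)
            for tx, recs in by_tx.items():
                recs = sorted(recs, key=lambda r: r.rank)
                gene = recs[0].gene_id
                strand = recs[0].strand
                lo = min(r.start for r in recs)
                hi = max(r.end for r in recs)
                attrs = f'gene_id "{gene}"; transcript_id "{tx}"; gene_type "protein_coding";'
                fh.write(f"{recs[0].chrom}\tsynth\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\t{attrs}\n")
                fh.write(f"{recs[0].chrom}\tsynth\ttranscript\t{lo + 1}\t{hi}\t.\t{strand}\t.\t{attrs}\n")
                for rec in recs:
                    a = attrs + f' exon_id "{rec.exon_id}"; exon_number {rec.rank};'
                    fh.write(f"{rec.chrom}\tsynth\texon\t{rec.start + 1}\t{rec.end}\t.\t{strand}\t.\t{a}\n")
        paths["annotation"] = gtf

        for track in self.tracks:
            p = outdir / f"{track.name}.bedgraph"
            write_bedgraph(track.data, p)
            paths[f"track:{track.name}"] = p

        counts_p = outdir / "exon_counts.tsv"
        self.counts.to_csv(counts_p, sep="\t", index=False)
        paths["counts"] = counts_p
        junc_p = outdir / "junction_counts.tsv"
        self.junctions.to_csv(junc_p, sep="\t", index=False)
        paths["junctions"] = junc_p

        events_p = outdir / "events.bed"
        events_to_bed(self.events, events_p)
        paths["events"] = events_p

        truth_p = outdir / "truth.json"
        truth_p.write_text(json.dumps(self.truth.to_dict(orient="records")))
        paths["truth"] = truth_p

        if self.peaks is not None:
            peaks_p = outdir / "rbp_peaks.bed"
            self.peaks.to_csv(peaks_p, sep="\t", index=False, header=False)
            paths["peaks"] = peaks_p

        cfg_p = outdir / "config.json"
        cfg_p.write_text(json.dumps({"seed": self.seed, "config": asdict(self.config)}, default=list))
        paths["config"] = cfg_p
        return paths


# ---------------------------------------------------------------------------
# generation steps


def generate_genome_and_annotation(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[ExonRecord], list[CassetteExonEvent], pd.DataFrame]:
    """Random genome with packed multi-exon genes and labelled internal exons."""
    chrom = config.chrom
    seq_parts: list[np.ndarray] = []
    exons: list[ExonRecord] = []
    cursor = 0
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    gene_layouts = []
    for g in range(config.n_genes):
        gap = int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        cursor += gap
        coords = []
        for e in range(n_ex):
            ex_len = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            coords.append((cursor, cursor + ex_len))
            cursor += ex_len
            if e < n_ex - 1:
                cursor += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
        gene_layouts.append((g, strand, coords))
    genome_len = cursor + int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))

    seq = bases[rng.integers(0, 4, size=genome_len)]

    truth_rows = []
    for g, strand, coords in gene_layouts:
        gene_id = f"G{g:04d}"
        tx_id = f"{gene_id}.t1"
        ordered = coords if strand == "+" else coords[::-1]
        for rank, (start, end) in enumerate(ordered, start=1):
            exon_id = f"{tx_id}.e{rank}"
            exons.append(
                ExonRecord(
                    exon_id=exon_id,
                    gene_id=gene_id,
                    transcript_id=tx_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    rank=rank,
                )
            )
            internal = 1 < rank < len(coords)
            if not internal:
                continue
            u = rng.random()
            if u < config.mid_fraction:
                cls = "mid"
                p_true = float(rng.uniform(0.45, 0.55))
            elif rng.random() < config.p_included:
                cls = "included"
                p_true = float(rng.uniform(*config.psi_included_range))
            else:
                cls = "skipped"
                p_true = float(rng.uniform(*config.psi_skipped_range))
            truth_rows.append(
                {"exon_id": exon_id, "cls": cls, "p_true": p_true, "exon_len": end - start}
            )
            # canonical splice dinucleotides: AG upstream of the acceptor,
            # GT downstream of the donor (transcript orientation)
            if rng.random() < config.canonical_fraction:
                if strand == "+":
                    seq[start - 2 : start] = np.frombuffer(b"AG", dtype=np.uint8)
                    seq[end : end + 2] = np.frombuffer(b"GT", dtype=np.uint8)
                else:
                    seq[end : end + 2] = np.frombuffer(b"CT", dtype=np.uint8)  # revcomp(AG)
                    seq[start - 2 : start] = np.frombuffer(b"AC", dtype=np.uint8)  # revcomp(GT)

    truth = pd.DataFrame(truth_rows)
    labels = {r["exon_id"]: r["cls"] for r in truth_rows if r["cls"] in ("included", "skipped")}
    events = extract_cassette_candidates(exons, labels=labels, deduplicate=False)
    genome = {chrom: seq.tobytes().decode("ascii")}
    return genome, exons, events, truth


def _genomic_center(site_pos: int, strand: str, offset_bp: float) -> float:
    """Map a transcription-direction offset to a genomic coordinate."""
    return site_pos + offset_bp if strand == "+" else site_pos - offset_bp - 1


def generate_tracks(
    config: SyntheticConfig,
    events: Sequence[CassetteExonEvent],
    truth: pd.DataFrame,
    genome_len: int,
    rng: np.random.Generator,
) -> list[ArrayTrack]:
    """Per-channel dense signal arrays with class-coupled geometry."""
    cls_of = dict(zip(truth["exon_id"], truth["cls"]))
    tracks = []
    for spec in config.channels:
        arr = np.zeros(genome_len, dtype=np.float64)
        for ev in events:
            cls = cls_of.get(ev.event_id)
            if cls is None:
                continue
            amp = spec.amplitude(cls)
            skew = {"included": spec.asymmetry, "skipped": -spec.asymmetry}.get(cls, 0.0)
            if spec.kind == "bump" and amp > 0:
                for bump in spec.bumps:
                    site = ev.acceptor if bump.site == "acceptor" else ev.donor
                    center = _genomic_center(site.pos, site.strand, bump.offset + skew)
                    half = int(np.ceil(4 * bump.width))
                    lo = max(int(center) - half, 0)
                    hi = min(int(center) + half + 1, genome_len)
                    x = np.arange(lo, hi)
                    arr[lo:hi] += amp * np.exp(-((x - center) ** 2) / (2 * bump.width**2))
            elif spec.kind == "ramp" and amp > 0 and spec.asymmetry != 0.0:
                site = ev.acceptor if spec.site == "acceptor" else ev.donor
                span = int(np.ceil(2 * spec.width))
                # linear 5'->3' gradient from 0 to amp (sign of asymmetry
                # flips the direction), mapped to genomic orientation
                rel = np.arange(-span, span)
                grad = amp * (rel + span) / (2 * span)
                if spec.asymmetry < 0:
                    grad = grad[::-1]
                if site.strand == "-":
                    grad = grad[::-1]
                    lo = site.pos - span
                else:
                    lo = site.pos - span
                lo_c, hi_c = max(lo, 0), min(lo + 2 * span, genome_len)
                arr[lo_c:hi_c] += grad[lo_c - lo : hi_c - lo]
        if spec.noise_sd > 0:
            arr += rng.normal(0.0, spec.noise_sd, size=genome_len)
        np.clip(arr, 0.0, None, out=arr)
        track = ArrayTrack(spec.name, {config.chrom: arr.astype(np.float32)})
        track.cap = spec.cap
        tracks.append(track)
    return tracks


def simulate_junction_reads(
    truth: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw exon counts and inclusion/exclusion junction reads.

    Total junction reads per event are Poisson(read_depth); inclusion
    reads are binomial with a success probability re-weighted by the
    footprint sizes, q = p (L_i + L_f) / (p (L_i + L_f) + (1 - p) L_f),
    so the length-normalised PSI estimator is centred on the true p.
    """
    L_f = config.fragment_length
    counts_rows, junc_rows = [], []
    for row in truth.itertuples(index=False):
        p = row.p_true
        L_i = row.exon_len
        total = int(rng.poisson(config.read_depth))
        w_incl = p * (L_i + L_f)
        q = w_incl / (w_incl + (1.0 - p) * L_f) if total else 0.0
        f_incl = int(rng.binomial(total, q)) if total else 0
        junc_rows.append({"exon_id": row.exon_id, "F_incl": f_incl, "F_excl": total - f_incl})
        # exon-body reads: included exons are expressed, skipped barely
        rate = config.read_depth * (1.0 if row.cls == "included" else 0.5 if row.cls == "mid" else 0.02)
        counts_rows.append({"exon_id": row.exon_id, "count": int(rng.poisson(rate))})
    return pd.DataFrame(counts_rows), pd.DataFrame(junc_rows)


def generate_rbp_peaks(
    events: Sequence[CassetteExonEvent],
    factors: Sequence[RBPFactorSpec],
    config: SyntheticConfig,
    rng: np.random.Generator,
    genome_len: int,
    n_uniform_peaks: int = 200,
) -> pd.DataFrame:
    """BED-like peak table: site-anchored factors plus uniform decoys."""
    rows = []
    for spec in factors:
        if spec.site == "uniform":
            for _ in range(n_uniform_peaks):
                start = int(rng.integers(0, max(genome_len - spec.peak_width, 1)))
                rows.append(
                    {"chrom": config.chrom, "start": start, "end": start + spec.peak_width,
                     "name": spec.name, "score": spec.score, "strand": "+"}
                )
            continue
        for ev in events:
            if rng.random() > spec.peaks_per_event:
                continue
            site = ev.acceptor if spec.site == "acceptor" else ev.donor
            center = int(_genomic_center(site.pos, site.strand, spec.offset))
            start = center - spec.peak_width // 2
            rows.append(
                {"chrom": config.chrom, "start": start, "end": start + spec.peak_width,
                 "name": spec.name, "score": spec.score, "strand": site.strand}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def simulate(
    config: SyntheticConfig,
    seed: int = 0,
    rbp_factors: Sequence[RBPFactorSpec] | None = None,
) -> SyntheticData:
    """Run the full generator under one seed."""
    rng = np.random.default_rng(seed)
    genome, exons, events, truth = generate_genome_and_annotation(config, rng)
    genome_len = len(genome[config.chrom])
    tracks = generate_tracks(config, events, truth, genome_len, rng)
    counts, junctions = simulate_junction_reads(truth, config, rng)
    peaks = None
    if rbp_factors:
        peaks = generate_rbp_peaks(events, rbp_factors, config, rng, genome_len)
    return SyntheticData(
        config=config,
        seed=seed,
        genome=genome,
        exons=exons,
        events=events,
        truth=truth,
        tracks=tracks,
        counts=counts,
        junctions=junctions,
        peaks=peaks,
    )


# ---------------------------------------------------------------------------
# named presets (the study conditions for the synthetic benchmarks)


def strong_signal_channels() -> tuple[ChannelSpec, ...]:
    """Six-channel roster by role: one dominant activating mark with
    exon-proximal bumps at acceptor +100 and donor +50 (class amplitude
    code), a weaker repressive mark anti-correlated with inclusion, one
    accessibility-like channel with no class information, and three pure
    noise channels.  Names are roles, not biological claims."""
    return (
        ChannelSpec(
            name="mark_act",
            kind="bump",
            site="acceptor",
            center_offset=100,
            width=20.0,
            amplitude_included=1.0,
            amplitude_skipped=0.15,
            noise_sd=0.08,
            extra_bumps=(BumpSpec("donor", 50, 20.0),),
        ),
        ChannelSpec(
            name="mark_rep",
            kind="bump",
            site="acceptor",
            center_offset=-60,
            width=40.0,
            amplitude_included=0.15,
            amplitude_skipped=0.35,
            noise_sd=0.15,
        ),
        ChannelSpec(
            name="access",
            kind="bump",
            site="acceptor",
            center_offset=0,
            width=30.0,
            amplitude_included=0.4,
            amplitude_skipped=0.4,
            noise_sd=0.1,
        ),
        ChannelSpec(name="noise1", kind="noise", noise_sd=0.2),
        ChannelSpec(name="noise2", kind="noise", noise_sd=0.2),
        ChannelSpec(name="noise3", kind="noise", noise_sd=0.2),
    )


def strong_signal_preset(n_genes: int = 667) -> SyntheticConfig:
    """~2,000 events (3 internal exons per 5-exon gene), 6 epigenomic
    channels, geometry sized for flank-100 model windows."""
    return SyntheticConfig(
        n_genes=n_genes,
        exons_per_gene=(5, 5),
        exon_len=(220, 260),
        intron_len=(300, 400),
        p_included=0.5,
        channels=strong_signal_channels(),
    )


def direction_preset(asymmetry_bp: float = 30.0, n_genes: int = 150) -> SyntheticConfig:
    """Construct-validity fixture for the time-reversal probe.

    With asymmetry > 0 the single informative channel codes class purely
    by bump position (included downstream of the acceptor, skipped
    upstream, equal amplitudes), so feeding the signal 3'->5' swaps the
    classes' appearance.  With asymmetry = 0 the class is coded purely by
    amplitude in a bump centred on the splice site, which is invariant
    under time reversal.
    """
    if asymmetry_bp > 0:
        # pure positional code: both classes carry equal-amplitude bumps at
        # each splice site, skewed downstream (included) / upstream (skipped)
        channel = ChannelSpec(
            name="dir_mark",
            kind="bump",
            site="acceptor",
            center_offset=0,
            width=12.0,
            amplitude_included=1.0,
            amplitude_skipped=1.0,
            noise_sd=0.1,
            asymmetry=asymmetry_bp,
            extra_bumps=(BumpSpec("donor", 0, 12.0),),
        )
    else:
        # time-symmetric amplitude code: included events carry a mirrored
        # pair of bumps at +/-25 bp of each site, which maps onto itself
        # under time reversal
        channel = ChannelSpec(
            name="dir_mark",
            kind="bump",
            site="acceptor",
            center_offset=-25,
            width=10.0,
            amplitude_included=1.0,
            amplitude_skipped=0.0,
            noise_sd=0.1,
            asymmetry=0.0,
            extra_bumps=(
                BumpSpec("acceptor", 25, 10.0),
                BumpSpec("donor", -25, 10.0),
                BumpSpec("donor", 25, 10.0),
            ),
        )
    return SyntheticConfig(
        n_genes=n_genes,
        exons_per_gene=(4, 4),
        exon_len=(160, 200),
        intron_len=(250, 350),
        p_included=0.5,
        channels=(channel, ChannelSpec(name="noise1", kind="noise", noise_sd=0.2)),
    )


def loo_preset(n_genes: int = 160) -> SyntheticConfig:
    """Compact six-channel roster for retraining-heavy importance runs.

    Same roles as the strong-signal roster but with geometry sized for
    flank-50 windows (informative bumps at +40 bp of each site) and fewer
    events, so a full leave-one-out sweep stays cheap.
    """
    channels = (
        ChannelSpec(
            name="mark_act",
            kind="bump",
            site="acceptor",
            center_offset=40,
            width=12.0,
            amplitude_included=1.0,
            amplitude_skipped=0.1,
            noise_sd=0.08,
            extra_bumps=(BumpSpec("donor", 40, 12.0),),
        ),
        ChannelSpec(
            name="mark_rep",
            kind="bump",
            site="acceptor",
            center_offset=-30,
            width=25.0,
            amplitude_included=0.1,
            amplitude_skipped=0.3,
            noise_sd=0.15,
        ),
        ChannelSpec(
            name="access",
            kind="bump",
            site="acceptor",
            center_offset=0,
            width=20.0,
            amplitude_included=0.4,
            amplitude_skipped=0.4,
            noise_sd=0.1,
        ),
        ChannelSpec(name="noise1", kind="noise", noise_sd=0.2),
        ChannelSpec(name="noise2", kind="noise", noise_sd=0.2),
        ChannelSpec(name="noise3", kind="noise", noise_sd=0.2),
    )
    return SyntheticConfig(
        n_genes=n_genes,
        exons_per_gene=(4, 4),
        exon_len=(160, 200),
        intron_len=(250, 350),
        p_included=0.5,
        channels=channels,
    )


def profile_preset(n_genes: int = 40) -> SyntheticConfig:
    """Long introns and exons for clean +/-500 bp metagene profiles, with
    a mid-PSI band populated."""
    channels = (
        ChannelSpec(
            name="mark_act",
            kind="bump",
            site="acceptor",
            center_offset=100,
            width=20.0,
            amplitude_included=1.0,
            amplitude_skipped=0.0,
            noise_sd=0.03,
            extra_bumps=(BumpSpec("donor", 50, 20.0),),
        ),
        ChannelSpec(name="noise1", kind="noise", noise_sd=0.1),
    )
    return SyntheticConfig(
        n_genes=n_genes,
        exons_per_gene=(5, 5),
        exon_len=(260, 320),
        intron_len=(1200, 1400),
        p_included=0.5,
        mid_fraction=0.2,
        channels=channels,
        read_depth=200.0,
    )
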