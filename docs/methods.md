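# Methods

## Problem setting and model

`cosplice` treats cassette-exon splicing as a sequence-classification
problem over the chromatin context that Pol II traverses. Each internal
exon of a multi-exon protein-coding transcript contributes one event with
two anchors: the 3' acceptor (intron→exon) and the 5' donor
(exon→intron). Around each anchor a window of `2·flank` positions is
extracted, oriented 5'→3' in transcription direction (reversed and, for
DNA, complemented on the − strand), with channels = 4 one-hot DNA rows
plus one row per epigenomic track. The default flank is 100 bp per side
of each splice site (200 bp per site, 400 bp per event); it is a config
knob.

The classifier is a two-branch recurrent network. Each branch consumes
one window and emits its full hidden-state sequence; the two sequences
are concatenated along the position axis, acceptor first, so the merge
RNN reads the event in transcription order (feature-axis concatenation is
available as `merge_mode="feature"`). The merge RNN's final hidden state
passes through inverted dropout and a dense two-unit softmax; the loss is
mean binary cross-entropy of the inclusion probability. A single-logit
sigmoid head is available and mathematically equivalent for two classes;
softmax is the default to mirror the two-class output layer of the
architecture this package follows. Cell equations (simple RNN, LSTM, GRU)
are implemented verbatim from their definitions in `cosplice.cells`; the
batched training engine in `cosplice._engine` is algebraically identical
(unit-tested against the step functions and against finite-difference
gradients) and hand-implements backpropagation through time and Adam in
NumPy.

### Named model configurations

| preset | branch/merge | dropout | epochs | notes |
|---|---|---|---|---|
| `main` | 200 / 400 | 0.5 | 20 | reference architecture |
| `benchmark` | 16 / 32 | 0.5 | 20 | CPU-scale synthetic benchmarks |
| `small` | 8 / 16 | 0.0 | 15, lr 3e-3, batch 32 | compact fixtures (reversal, importance) |
| `interpret` | 1 / 1 | 0.0 | 400 | gate-weight read-out per channel |

Adam uses lr 1e-3 (unless stated), β₁ 0.9, β₂ 0.999. Weights are
Glorot-style uniform, seeded; biases start at zero. The decision
threshold on p(inclusion) is 0.5. No class re-balancing is applied. The
`benchmark` and `small` hidden sizes are the package's own choice for the
synthetic benchmarks: the generator's signal is strong and a small
network separates it fully, while the 200/400 reference sizes remain the
`main` default for real-scale data.

### Data split

Events are shuffled once with the run seed, 20% is set aside as the test
fold, and the remaining 80% is split 80/20 again into fitting and
validation folds (64/16/20 of the total; for n = 100, exactly 64/16/20
events). Per-epoch loss and accuracy on the fitting and validation folds
are recorded in the results object.

## Quantification

Exon-level FPKM is `count / ((L_i/10³)·(N_mapped/10⁶))` with binarization
at FPKM ≥ 1 (closed boundary). Junction PSI normalises inclusion reads by
the footprint they can occupy (`L_i + L_f`) and exclusion reads by the
fragment length `L_f`; `PSI = 100·F̃_incl/(F̃_incl+F̃_excl)`, undefined
when both counts are zero. Class cutoffs are ≤ 20% skipped and ≥ 80%
included (boundaries closed; the source conventions do not specify open
vs. closed, so the inclusive reading was fixed here). The enrichment
profiles use the alternative banded scheme where "mid" means 40–60% PSI.
Fragment length is a per-dataset scalar (default 100 bp); it is not
estimated from data.

Either label route — FPKM binarization or PSI class — can define the
model's training label; FPKM binarization is the default, PSI labels are
selected via the `band406080`/`cutoff2080` scheme presets.

## Track processing

ChIP-style tracks are assumed already normalised against their input;
the per-base enrichment statistic is −log₁₀ of the upper-tail Poisson
p-value against a background rate, clipped at 2 (p = 10⁻²) because of the
wide dynamic range, then divided by the cap so model inputs lie in [0,1].
Bounded tracks (methylation fraction, nucleosome occupancy) are min-max
scaled; when a synthetic track declares its own cap the featurizer clips
and divides by it. Uncovered bases take fill value 0. bedGraph input is
read 0-based half-open; bigWig via pyBigWig.

## Annotation

GTF is read 1-based inclusive and converted to 0-based half-open.
Transcripts are ranked in transcription direction; every exon that is
neither first nor last in its transcript is a cassette candidate
(purely positional definition — observed skipping is established
downstream by expression/PSI labels, not required structurally). Events
are de-duplicated at (chrom, start, end, strand) across isoforms. Genes
with annotation on both chrX and chrY (pseudoautosomal-style ambiguity)
are removed; the mechanism "ambiguous XY mapping" is not defined by the
source conventions, so this explicit rule was chosen. Unknown strand
symbols reject the record; a malformed attribute field is a parse error
naming the location.

## Interrogation procedures

* **Leave-one-out importance** retrains the model without one channel at
  a time (same seed, hence same split, per repeat) and reports the mean
  decrease in F1 and ROC AUC. The number of seeded repeats defaults to 3;
  budget-constrained runs may pass 1. A seed-variability band — the
  spread of reference retrainings under different seeds — calibrates
  which deltas are distinguishable from noise. In tests the band is
  `max(3·SD, 0.05)`: with a held-out fold of ~60 events a single flipped
  call moves F1 by ~0.03, so deltas below 0.05 are below the metric's
  resolution regardless of the SD estimate.
* **Add-one-in gain** starts from a DNA-only model and adds one channel
  (or one unordered pair) at a time, averaged over 5 trials by default.
* **Cross-cell transfer** applies fitted weights unchanged to a foreign
  dataset, which is split with the model's seed so the test-fold numbers
  are comparable; class balance of both datasets is reported because F1
  is the fairer metric under imbalance.
* **Reversal test** evaluates a forward-trained model on inputs whose
  epigenomic channels are position-reversed (DNA stays forward, since the
  probe targets the temporal order of chromatin context, not sequence).
  Retraining on reversed inputs is available as an explicit call with a
  reversed dataset.

## Metrics

Precision, recall, accuracy and F1 come from the thresholded confusion
matrix; ROC AUC is the trapezoid area with tied scores grouped; PR AUC is
step-wise average precision (not linear interpolation, which is biased
optimistic). These are delegated to scikit-learn, whose conventions match
exactly; the test suite checks them against an independent
exhaustive-threshold oracle. With single-class labels the AUCs are
reported as undefined (None) while threshold metrics remain.

Rank-sum comparisons (profile segments, expression groups) use the
two-sided Mann-Whitney-Wilcoxon test: exact p by complete enumeration of
group assignments when C(n, n₁) ≤ 2·10⁵ (ties handled by mid-ranks /
half-counting), otherwise the normal approximation with continuity and
tie correction. Star bins: ns > 0.05 ≥ * > 0.01 ≥ ** > 0.001 ≥ *** >
0.0001 ≥ ****. No multiple-testing correction is applied anywhere, by
design. The default segment scheme around the acceptor tiles
[−100, +100) into four 50-bp segments (A distal intron, C proximal
intron covering the branch-point region, B proximal exon, D distal
exon); the scheme is configuration and is echoed in every report.

RBP peaks are filtered at score ≥ 1000, reduced to their midpoint, and
binned into 100-bp intervals over ±1000 bp of each splice site, oriented
5'→3'; frequency is count per bp of bin, with a per-site-normalised
column alongside and a splicing-vs-other fold profile as a second output.

## Synthetic data generator

The generator emulates the data context, not the biology: a uniform
random genome with non-overlapping multi-exon genes on both strands;
canonical AG/GT dinucleotides written at 95% of event boundaries
(configurable; the remainder stay non-canonical); per-event classes drawn
with prevalence `p_included` (default 0.5), plus an optional mid-PSI
band; junction reads Poisson-distributed in depth with the inclusion
binomial re-weighted by `q = p(L_i+L_f)/(p(L_i+L_f)+(1−p)L_f)` so the
length-normalised PSI estimator is centred on the true p; exon counts
Poisson with class-dependent rates so FPKM ≥ 1 recovers the class.

Channels are Gaussian bumps anchored at splice-site offsets
(class-dependent amplitude), optional monotone 5'→3' ramps, or pure
noise; the `asymmetry` parameter shifts included-class bumps downstream
and skipped-class bumps upstream, creating a purely positional 5'→3'
code. All values are clipped at zero, which adds a small positive
baseline to otherwise-zero regions (the tests' analytic oracles model
this via the clipped-Gaussian expectation).

Preset conditions:

* `strong-signal` — ~2,000 events (667 five-exon genes), six epigenomic
  channels: a dominant activating mark with included-class bumps at
  acceptor +100 bp and donor +50 bp (exonic side), a weaker
  anti-correlated repressive mark, a class-neutral accessibility channel,
  three noise channels. Bump offsets follow the observed placement of
  activating-mark enrichment just inside the exon. Geometry (exons
  220–260 bp, introns 300–400 bp) is sized for flank-100 windows.
* `direction` — the reversal construct-validity fixture. With
  `asymmetry_bp > 0` the single informative channel codes class purely by
  bump position (±asymmetry bp around each site, equal amplitudes), so
  time reversal swaps the classes' appearance and performance must
  collapse. With `asymmetry_bp = 0` the included class carries a mirrored
  pair of bumps at ±25 bp of each site — a pattern invariant under time
  reversal — so forward and reversed performance must agree. The
  mirrored-pair design (rather than one centred bump) keeps signal near
  the end of each window, where a last-state recurrent read-out learns it
  reliably.
* `loo` — the importance fixture: the strong-signal roster scaled to
  flank-50 geometry with one clearly dominant informative channel.
* `profile` — long introns (1.2–1.4 kb) and exons (260–320 bp) for clean
  ±500 bp metagene profiles, with a populated 40–60% PSI band.

What the generator does **not** emulate: sequence-motif-driven splicing
grammar (DNA is class-independent noise apart from the canonical
dinucleotides), nucleosome phasing, realistic track autocorrelation,
coverage biases, and cross-channel correlation structure. Passing the
synthetic benchmarks therefore demonstrates that the machinery — windows,
orientation, training, interrogation — is correct and sensitive, not that
comparable accuracy would be reached on real epigenomes.

## Problem sizes in tests and the acceptance script

The end-to-end benchmarks train the `benchmark` configuration for 20
epochs on the ~2,000-event strong-signal preset (LSTM and GRU; the simple
RNN is allowed to underperform, as memory-less recurrences do on long
windows). Reversal uses 5 seeds × ~300 events with the `small`
configuration; leave-one-out uses one repeat with a 3-seed variability
band on ~320 events. These sizes were chosen so a full run completes in
minutes on a single core while every effect being tested is far larger
than its sampling noise.

## Known limitations

* The NumPy engine is CPU-only and processes dense windows; genome-scale
  training (10⁵ events × 17 channels) is out of its intended range.
* `BedGraphTrack` materialises dense per-chromosome arrays — fine for toy
  genomes, wasteful for real ones (use bigWig there).
* The interpret preset reads branch-cell input weights directly; for
  hidden sizes > 1 the per-channel summary aggregates across units and
  loses sign structure (a warning is issued).
* Cross-cell transfer assumes identical channel registries by name; no
  channel matching or imputation is attempted.
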