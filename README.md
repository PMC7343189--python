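# cosplice

**Predicting cassette-exon inclusion from DNA sequence and epigenomic
context with two-branch recurrent networks.**

Most human splicing happens co-transcriptionally: the spliceosome works
next to elongating Pol II, so the chromatin context around a splice site
is presented to the splicing machinery in a fixed 5'→3' temporal order.
`cosplice` models that layout directly. For each internal ("cassette")
exon it takes per-base windows around the 3' acceptor and 5' donor splice
sites — one-hot DNA plus epigenomic signal channels (histone marks,
accessibility, methylation), all oriented in transcription direction and
scaled to [0, 1] — and feeds them to a recurrent network that predicts
whether the exon is included in the mature transcript.

The package is aimed at computational genomicists who want to (a) train
and interrogate such models on their own exon/track data, and (b) probe
*how* the temporal chromatin context matters, via leave-one-out channel
importance, add-one-in gains, cross-cell-type transfer, and a
time-direction reversal test. A seeded synthetic-data module generates
toy genomes, class-coupled signal tracks, junction reads and RBP peaks
with known ground truth, so the whole pipeline is testable end to end
without any downloads.

## The model

Three recurrent cells are implemented exactly from their defining
equations (σ is the logistic sigmoid, ⊗ the Hadamard product):

simple RNN: `h_t = tanh(W_h^T h_{t−1} + W_x^T x_t + b)`

LSTM:

```
f_t = σ(W_hf^T h_{t−1} + W_xf^T x_t + b_f)        (forget gate)
i_t = σ(W_hi^T h_{t−1} + W_xi^T x_t + b_i)        (input gate)
o_t = σ(W_ho^T h_{t−1} + W_xo^T x_t + b_o)        (output gate)
g_t = tanh(W_hg^T h_{t−1} + W_xg^T x_t + b_g)
c_t = f_t ⊗ c_{t−1} + i_t ⊗ g_t
h_t = o_t ⊗ tanh(c_t)
```

GRU: `z_t, r_t = σ(·)`, `h_t = (1−z_t) ⊗ h_{t−1} + z_t ⊗ tanh(W_hh^T (r_t ⊗ h_{t−1}) + W_xh^T x_t + b_h)`

The network has two branch RNNs (one per splice site) whose hidden-state
sequences are concatenated along the position axis — acceptor first, so
the merge RNN reads the whole event in transcription order — followed by
dropout and a two-unit softmax head. Training uses binary cross-entropy
under Adam with a seeded shuffle and a 64/16/20 fit/validation/test
split. Forward, backward (BPTT) and the optimizer are written in NumPy;
there is no deep-learning framework dependency.

Quantification follows the standard exon-level definitions: FPKM per exon
with binarization at 1, and junction-based percent spliced in

```
PSI = 100 · (F_incl/(L_i+L_f)) / (F_incl/(L_i+L_f) + F_excl/L_f)
```

with cutoffs at 20%/80% for skipped/included classes.

## Worked example

```python
from cosplice.synth import strong_signal_preset, simulate
from cosplice.model import ModelConfig, SpliceRNN

data = simulate(strong_signal_preset(), seed=7)   # ~2,000 cassette events
ds = data.to_dataset(flank_bp=100)                 # windows: 200 bp x 10 channels
res = SpliceRNN(ds, ModelConfig.benchmark("lstm", epochs=8)).fit(seed=7)
print(res.summary())
```

prints (machine-generated, seed 7):

```
Two-branch recurrent splicing model
================================================
cell type        lstm
branch / merge   16 / 32 (time merge)
dropout          0.5
epochs           8   seed 7
channels (10)    A, C, G, T, mark_act, mark_rep, access, noise1, noise2, noise3
events           fit 1281 / val 320 / test 400
final train loss 0.0805  acc 1.000
final val loss   0.0806  acc 1.000
test             F1 1.0000  ROC AUC 1.0000  precision 1.0000  recall 1.0000
```

The held-out fold is perfectly separated because the preset's activating
mark carries a strong class-dependent bump just inside the exon at both
splice sites; the three noise channels contribute nothing, which the
leave-one-out analysis (`cosplice.evaluation.leave_one_out_importance`)
recovers as near-zero deltas.

The same pipeline is available from the shell:

```bash
cosplice simulate --preset strong-signal --seed 7 --out sim/
cosplice featurize --genome sim/genome.fa --events sim/events.bed \
    --track mark_act=sim/mark_act.bedgraph --truth sim/truth.json \
    --flank 100 --out data
cosplice train --dataset data --cell lstm --seed 7 --out model/
cosplice evaluate --model model/ --dataset data --out report.json
```

## Layout

- `cosplice.annotation` — GTF parsing, internal-exon enumeration, BED I/O
- `cosplice.quant` — FPKM, PSI, class assignment
- `cosplice.features` / `cosplice.tracks` — oriented feature windows,
  one-hot DNA, Poisson enrichment, 0–1 scaling, track readers
- `cosplice.cells` / `cosplice.model` — cell equations; Model/Results API
- `cosplice.evaluation` — metrics, importance, transfer, reversal
- `cosplice.profiles` — metagene profiles, rank-sum segment tests, RBP binning
- `cosplice.synth` — seeded synthetic data with ground truth
- `cosplice.cli` — `cosplice` command with one subcommand per step

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
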