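# nanorevise

Post-basecalling error correction for Oxford Nanopore sequencing reads.

Nanopore basecallers translate raw pore current into DNA one read at a
time and leave a characteristic error profile — deletion, insertion and
mismatch rates each of a few percent. `nanorevise` revises reads *after*
basecalling, without consensus across reads: it re-segments the
basecaller's events against the raw signal so that each called base owns
one event, then asks two neural sequence-labeling models about every
base — model 1 predicts the event's **error type** `y₁ ∈ {A,C,G,T,I,D}`
(I = spurious inserted base, D = a reference base missing after this
event), model 2 predicts the **true base** `y₂ ∈ {A,C,G,T}` — and merges
their predictions with the original read under conservative rules (edit
only on agreement; otherwise keep the original base).

Both models share one architecture: a residual 1-D CNN (kernel 1×3,
8 filters) over the normalized raw signal, two Bi-LSTM layers (state 16)
over per-event features (called base, event mean/stdv/length, optional
methylation flag), a merged Bi-LSTM trunk (state 64) with dropout 0.2,
and two dense layers with softmax over a 13-event window centred on the
base being classified. Training minimizes softmax cross-entropy plus a
center-loss term,

    L = Ls + λ·Lc,   Lc = ½ Σᵢ ‖xᵢ − c_{yᵢ}‖²,   λ = 0.2,

which tightens the feature clusters of the rare I/D classes. Evaluation
uses alignment-based rates with a shared denominator,

    XRate = Xlength / Alignlength,   Alignlength = readlength + deletionlength,

for X ∈ {deletion, insertion, mismatch}, and ErrorRate their sum,
optionally stratified over annotated methylated positions (m6A, m4C,
modified).

The network, its backpropagation and the Adam/center-loss training loop
are implemented directly in NumPy and verified by finite-difference
gradient checks; no deep-learning framework is required.

## Worked example

Simulate a ground-truth fixture set (k-mer Gaussian currents, geometric
dwells, move-0/1/2 event streams, 15% injected error split
del:ins:mm = 6:5:8), then score its truth alignments:

```bash
$ nanorevise simulate --n 20 --length 400 --seed 7 --out demo_fix
wrote 20 reads to demo_fix

$ nanorevise eval --sam demo_fix/truth.sam --reference demo_fix/ref.fa
metric  value
deletion_rate   4.644709856436241
insertion_rate  3.4865484376885028
mismatch_rate   5.971769815418024
error_rate      14.103028109542766
align_length    8289
read_length     7904
```

The rates are percentages over the pooled read set: of the 8289
alignment columns (7904 read bases + 385 deleted reference bases), 4.6%
are deletions, 3.5% insertions and 6.0% mismatches — a 14.1% error rate,
matching the configured injection within sampling noise. Training and
revision run the same way:

```bash
nanorevise train  --events demo_fix/events --sam demo_fix/truth.sam \
                  --reference demo_fix/ref.fa --epochs 10 --out run/
nanorevise revise --events demo_fix/events --model1 run/model1.npz \
                  --model2 run/model2.npz --output revised.fasta
nanorevise eval   --sam revised.sam --reference demo_fix/ref.fa
```

(`revised.sam` is the revised reads re-aligned by any SAM-producing
aligner, e.g. `minimap2 --eqx`.) The same steps are available as library
functions (`nanorevise.pipeline`, `nanorevise.experiment`) — see
`docs/methods.md` for the model, the generator's assumptions, and all
numerical choices.

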