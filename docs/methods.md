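# Methods

## Problem and model

Phage virion proteins (PVPs) are recognized from sequence alone in two
stages: a binary virion / non-virion classifier over all proteins, then a
seven-way functional classifier (portal, major capsid, minor capsid, major
tail, minor tail, baseplate, tail fiber) over the predicted virion
proteins. Both stages share one architecture and differ only in the width
of the final layer.

The input to either classifier is a fixed-length protein representation:
per-residue embeddings from a protein language model's last layer, averaged
over residue positions into a single vector (1024-dimensional in the
reference configuration). Mean pooling is permutation-invariant in its rows
and linear, which the property tests assert directly.

The classifier is a small 1-D convolutional network applied to the
embedding vector treated as a one-channel signal:

| stage | output shape |
|---|---|
| input reshaped | (N, 1, 1024) |
| Conv1d, 32 filters, kernel 3, stride 1, no padding | (N, 32, 1022) |
| BatchNorm(32) + ReLU | (N, 32, 1022) |
| MaxPool1d, kernel 3, stride 2 | (N, 32, 510) |
| Flatten | (N, 16320) |
| Dense(64) + BatchNorm(64) + ReLU | (N, 64) |
| Dense(C) | (N, C) |

Padding is zero everywhere; that is the only setting that produces the
1022/510/16320 chain from a 1024-length input. The dense layer after the
flatten infers its input width from the shape chain at build time, so any
embedding dimension ≥ 5 works. The network emits raw logits; softmax is
applied by the loss during training and by the prediction path when
confidences are reported. ReLU after each batch normalization is this
package's choice — the architecture is equally buildable with
`activation="none"`.

## Asymmetric loss

With logits x, p = softmax(x), one-hot labels y and focusing exponents
γ₊ (positive/true-class) and γ₋ (negative/other-class):

* **standard mode (default)** — per sample,
  `L = Σ_c −[ y_c (1−p_c)^γ₊ log p_c + (1−y_c) p_c^γ₋ log(1−p_c) ]`.
  The factor p_c^γ₋ suppresses the loss (and gradient) of negatives the
  model already rejects, so training capacity shifts toward the rare
  classes. Defaults (γ₊, γ₋) = (0, 4).
* **literal mode** — per sample only the true-class term contributes,
  `L = −(1−p_t)^γ₊ log p_t`. Under one-hot labels γ₋ cancels
  identically in this reading, so it degenerates to focal-style weighting
  of the positive term and, at γ₊ = 0, to categorical cross-entropy. It is
  retained as a configuration switch and as the cross-entropy ablation
  baseline (`cross_entropy_config()`).

Both modes average over the batch. The two readings exist because the
per-sample form and the reported γ₋ sensitivity cannot both hold under
one-hot labels; the standard form is the one in which γ₋ is active, which
matches the observed behaviour of the method class this loss belongs to,
so it is the default. Probabilities are clamped to
[prob_floor, 1 − prob_floor] (default 1e−8) before logs and powers; the
floor is the only regime in which literal-mode/cross-entropy equivalence
is numerically inexact. Gradients are computed analytically through the
softmax Jacobian and are finite-difference-checked in the tests, as is
every layer of the network.

## Training

Mini-batch Adam (lr 1e−3, β = 0.9/0.999, batch 128) for up to 100 epochs
with early stopping (patience 10) on the loss over a stratified validation
split (10% of the training set), best-validation parameters retained.
These optimizer settings are this package's defaults — robust, not tuned —
and are all configurable. Everything is seeded: parameter initialization,
the validation split, and the per-epoch shuffles derive from
`TrainConfig.seed`, so two fits from the same seed produce bit-identical
parameters. Network arithmetic is float32 (a deliberate bandwidth choice;
the conv-map batch normalization dominates runtime otherwise); losses and
metrics are computed in float64.

## Benchmark splitting

* **By time** — train on proteins released strictly before the cutoff
  (default 2020-12-01, "before December" read as before the month's first
  day), test on the rest. Optional binary balancing down-samples the
  majority class to the minority count within each partition, mirroring
  the balanced binary protocol; multi-class splits preserve the original
  distribution.
* **By similarity** — the pairwise score is identity × coverage from a
  local alignment: identity = identical columns / alignment columns,
  coverage = alignment columns / query length (capped at 1). The built-in
  scorer is Smith–Waterman with BLOSUM62 and affine gaps (open −11,
  extend −1); an external aligner's tabular scores drop in unchanged.
  Scores are symmetrized as the max over the two query orderings, because
  the constraint must hold regardless of direction. Proteins with score
  > t are linked and the connected components move as blocks: components
  are shuffled (seeded) and assigned to the test side, stratified by
  component-majority class, until each class's test fraction (default 0.2)
  is met or first exceeded. This single-linkage construction provably
  leaves no cross-split pair above t, and `max_cross_split_score` asserts
  exactly that exhaustively on every test instance. A component holding
  more than (1 − test_fraction) of a class makes the threshold
  unattainable and raises with advice to increase t.
* **By imbalance** — all PVPs are kept and r × as many non-PVPs are
  subsampled (seeded), then both classes are split train/test at the same
  fraction, so the non-PVP : PVP ratio r holds in both partitions within
  one record per class.

## Keyword labeling

Reference-database annotation lines are mapped to labels by
case-insensitive substring rules: structural keywords ("portal", "capsid",
"tail", "fiber", "tape measure", "baseplate", "structural") ⇒ PVP, with
the functional category taken from the longest matching category phrase
("major capsid" beats "capsid"); otherwise non-structural keywords
("transcription", "holin", "lysin", "regulator") or any whitespace-
delimited word ending in "-ase" ⇒ non-PVP; otherwise unlabeled. Structural
matches take precedence over the enzyme suffix ("capsid maturation
protease" is structural), because the virion set is built first. Generic
structural hits without a category phrase enter the binary dataset only.
The precedence between simultaneously matching structural and
non-structural vocabulary is this package's choice; annotation text rarely
exercises it.

## Synthetic data

The generators define the conditions under which the pipeline is tested:

* **Gaussian embeddings** — class c is an isotropic unit-variance Gaussian
  whose mean lies at separation/√2 along one of k mutually orthogonal
  random unit directions, giving every pair of class means distance
  `separation` (in within-class σ units, the single separability knob).
  Signal is deliberately spread across all coordinates, as pooled
  language-model embeddings are; a construction that concentrates the
  class difference in one coordinate interacts pathologically with a
  weight-shared 3-tap convolution and does not resemble PLM geometry.
  Because the directions are drawn per seed, held-out evaluation must
  split rows of one draw (train and test share the class structure), not
  compare across seeds.
* **Protein families** — one uniform-random ancestor per family; members
  substitute each site with the given rate, uniformly over the other 19
  residues. Within-family aligned identity concentrates near (1−rate)²
  (both members mutate independently); between families it is chance.
  These drive the similarity splitter: at t = 0.4 whole families co-locate
  on one side.
* **Annotation corpus** — description lines assembled from the labeling
  vocabulary plus distractors ("hypothetical protein"), with ground truth
  attached; the labeler must reproduce it exactly.

What passing these tests shows — and does not. The Gaussian fixtures
verify that the architecture, loss, optimizer and early stopping learn a
separable geometry, stay at chance without signal, and that ASL(0,4)
matches or beats cross-entropy on minority-class recall under 9:1
imbalance (majority of 5 paired seeds, weighted F1 within 0.05). They do
not certify accuracy on real phage proteins, which depends on the quality
of real PLM embeddings and curated labels at database scale.

## Problem sizes used by the test suite

Learning sanity runs at the generator defaults (dim 1024, 200 per class,
separation 10 and 0, seed 7) with a 40-epoch cap. The imbalance ablation
runs at n = 1800/200, separation 2.0 and dim 256 — separation in σ units
is carried by the projection onto the mean-difference axis, so the
comparison is dimension-independent while ten trainings stay desk-sized —
with a 25-epoch cap. Unit tests use dim 32–64 throughout.

## Numerical and design notes

* Translation is frame-0 CDS translation; stop codons terminate without
  being emitted, codons containing N (or any non-ACGT character) become X,
  trailing partial codons are dropped. Minus-strand ORFs are
  reverse-complemented first. ORF discovery itself is out of scope — the
  pipeline consumes protein FASTA or an ORF table as produced by external
  gene callers.
* Residues outside the 20 standard letters map to X on input rather than
  being rejected (real database entries contain B/Z/U/*).
* The seven-way head has no rejection option: out-of-category proteins
  receive the argmax label with a low confidence, surfaced through the
  `high` (> 0.997, configurable) vs `moderate_low` band rather than
  suppressed.
* Embedding caches are a self-describing binary container (magic bytes,
  JSON header with ids/dim/backend, float32 payload); truncation and
  dimension mismatches are detected at load. A TSV export exists for
  inspection.
* Sequences longer than 4000 residues are truncated with a warning before
  embedding (transformer context limits; configurable).
* GFF3 output is 1-based inclusive with URL-escaped attribute values;
  internal indexing is 0-based half-open.
* Batch normalization uses momentum 0.1 running statistics; evaluation
  mode is a pure function of (parameters, input). Checkpoints round-trip
  bit-identically.

## Known limitations

* The offline k-mer-hash backend preserves edit-distance locality but not
  the functional/evolutionary structure of real PLM embeddings; models
  trained on it are placeholders for pipeline testing.
* The similarity splitter computes all-against-all alignments in quadratic
  time — appropriate for benchmark construction at up to a few thousand
  sequences, not for database scale (import precomputed scores there).
* Single-linkage component assignment can overshoot the requested test
  fraction when components are large; the per-class target is met "or
  first exceeded" by construction.
* Multi-class MCC uses the correlation-coefficient generalization over the
  full confusion matrix; weighted averaging is the default because
  support-weighted recall equals accuracy, a consistency identity the
  suite asserts.
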