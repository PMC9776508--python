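# Methods

## Overview

`mdanet` predicts unobserved miRNA–disease associations from three inputs: a
binary association catalog A (nm miRNAs × nd diseases), a precomputed miRNA
functional-similarity matrix, and a disease-ontology forest of DAGs. The
pipeline has four stages:

1. **Similarity integration.** Disease semantic similarity is computed from
   the ontology; Gaussian interaction-profile (GIP) kernels computed from A
   fill in pairs with no functional/semantic similarity, yielding integrated
   matrices Sm (miRNA) and Sd (disease).
2. **Unsupervised embedding.** A stacked graph autoencoder (three
   graph-convolutional encoder/decoder pairs trained jointly on summed
   reconstruction losses) compresses each entity's similarity profile to a
   64-dimensional embedding Z.
3. **Feature assembly.** Each entity's final embedding is V = [Z | F¹],
   where F¹ is its association profile (row or column of A); a pair feature
   is [Vm_i | Vd_j]. At the real catalog scale this gives 447-dimensional
   miRNA and 559-dimensional disease embeddings (64 + 383 and 64 + 495).
4. **Scoring.** A two-hidden-layer MLP (ReLU, sigmoid output) is trained
   with binary cross-entropy on all known associations plus an equal-size
   random sample of unknown pairs, and scores every unknown pair.

## Disease semantic similarity

Each disease d owns a DAG (d, T(d), E(d)) with T(d) the disease plus its
ancestors. Two contribution models are averaged:

* **Decay model.** The disease's own node contributes 1; an ancestor k
  contributes max over its in-DAG children c of δ·contribution(c), with
  decay factor δ = 0.5 (the conventional value). A node reachable by
  several paths takes the maximum over paths, consistent with the
  max-recursion.
* **Information-content model.** Node k contributes
  −ln(#DAGs containing k / #diseases), so rare ontology terms weigh more.
  The log base is the natural log; pairwise similarities are invariant to
  the base because it rescales numerator and denominator identically (a
  unit test asserts this).

For either model, sim(di, dj) = Σ_{k∈T(di)∩T(dj)} (c_i(k) + c_j(k)) /
(DV(di) + DV(dj)). Diseases with several tree positions use the union of
their ancestor closures. Diseases without a DAG get a zero row/column (unit
diagonal) and are flagged as "no semantic similarity" so the GIP kernel
fills in.

## GIP kernels and integration

K(i,j) = exp(−γ‖IP(i)−IP(j)‖²) with γ = γ′ / mean_i ‖IP(i)‖² and γ′ = 1;
IP(i) is entity i's row (or column) of A. Integration selects the
functional/semantic value where one is available and the GIP value
otherwise. "Available" defaults to "the off-diagonal entry is nonzero",
matching the convention that similarity files encode missingness as 0; an
explicit 0/1 mask file can override this.

## Stacked graph autoencoder

The propagation operator is the symmetric normalization Â = D^(−1/2) S
D^(−1/2) of the integrated similarity, whose spectrum lies in [−1, 1]. Per
layer:

    Enc(Â, Y) = tanh(Â · ReLU(Â Y W0) · W1)
    Dec(Â, Z) = sigmoid(Â · ReLU(Â Z W2) · W3)

Layer l maps Z^(l−1) → Z^l → reconstruction X^l; the objective is
Σ_l ‖Z^(l−1) − X^l‖²_F, optimized **jointly** over all layers (not greedy
layer-wise training) — gradients flow through the whole chain because Z^l
is also the next layer's input. The loss compares the sigmoid-valued X^l
against tanh-valued targets for l ≥ 2; this codomain mismatch is part of
the model definition and is implemented exactly as defined.

Choices where the design was open:

* **Layer widths.** Three layers ending at 64. Inputs wider than 256 use
  256 → 128 → 64; narrower (synthetic-scale) inputs use a geometric
  interpolation from the input width down to 64 so the chain stays strictly
  decreasing at any scale. Each encoder's internal ReLU width is 2× the
  layer's output width; the decoder mirrors the encoder. The final
  dimension is configurable over {16, 32, 64, 128, 256}; 64 is the default
  because both ROC and PR performance peak there in dimension sweeps.
* **Optimization.** Full-batch Adam, lr 1e−3, no weight decay, 300
  pre-training epochs, Glorot-uniform initialization, no bias terms in the
  graph convolutions. Training is bit-reproducible under a seed. Gradients
  are hand-derived and validated against central finite differences in the
  test suite.

## Classifier and evaluation protocol

MLP hidden widths 512 and 128, full-batch Adam, lr 1e−3, 100 epochs,
decision threshold 0.5 (natural for balanced classes). Negative sampling
draws unknown pairs uniformly without replacement, equal in number to the
positives; the library default repeats this 10 times (seeds seed+0..seed+9)
and reports mean ± SD over all resampling × fold combinations of AUC, AUPR,
accuracy, precision, recall and F1. AUPR uses step-wise precision–recall
integration (not trapezoidal), which is what `average_precision_score`
computes; ROC-AUC equals the Mann–Whitney statistic with ties counted 0.5.
Folds are stratified by label so each stays balanced.

**Leakage policy.** By default the association-profile features F¹ and the
GIP profiles are rebuilt per fold from the training folds only, with
test-fold positives zeroed ("leakage-safe"). `paper_mode=True` builds all
features from the full matrix A once per resampling — the apparent protocol
of published predictors in this family, whose reported accuracies partly
reflect the test pair's own entry being visible inside its features. Both
policies are first-class and labeled so results are comparable either way.

## Synthetic data: what it emulates and what it cannot

`generate_planted_bundle` plants B matched miRNA/disease blocks: A(i,j) ~
Bernoulli(p_in) within matched blocks and p_out otherwise; similarities are
sim_in within blocks and sim_out across, plus symmetric Gaussian noise,
clipped to [0,1] with unit diagonal. Defaults nm=100, nd=80, B=4, p_in=0.3,
p_out=0.02 (about 1/5 of the real catalog scale, chosen so a full
cross-validation completes quickly on one CPU); sim_in=0.7, sim_out=0.1,
noise sd 0.05 keep within/between-block similarity clearly separated, as in
real functional-similarity matrices.

Two structural limits of this generator matter when interpreting results:

* **Information cap under the leakage-safe policy.** Conditional on block
  membership, each association is pure Bernoulli noise, so no method can
  beat the block-oracle scorer; on the default bundle that oracle reaches
  AUC ≈ 0.83, and the pipeline lands close to it. Accuracies above this
  bound on the planted bundle are only reachable under `paper_mode`, where
  features contain the test entry itself.
* **No similarity surplus.** Similarity matrices are generated from the
  same block labels as A plus independent noise, so they are conditionally
  independent of the residual association signal given blocks. The learned
  embedding block therefore adds no information beyond the association
  profiles on this generator, and the full feature mode does not
  systematically beat the association-only ablation here — unlike on real
  catalogs, where functional and semantic similarity carry information the
  sparse association profiles lack. Passing tests on synthetic data
  demonstrate mechanical correctness and structure recovery, not the
  real-data advantage of pre-training.

`generate_toy_ontology` builds forests of rooted DAGs with ancestor chains
drawn from a shared pool (the first two diseases always share exactly one
parent, giving a guaranteed sibling pair with decay-model similarity 1/3 at
δ = 0.5). It does not emulate MeSH's multi-tree descriptors or realistic
term frequencies.

## Numerical conventions and degenerate inputs

* Input similarity asymmetries ≤ 1e−6 are averaged away; larger ones are
  errors. Outputs are forced exactly symmetric by construction.
* Matrices round-trip through text at 10 significant digits.
* All-zero GIP profiles, zero graph row sums, single-class training sets,
  ontology cycles and unknown entity names raise typed errors rather than
  propagating NaNs; non-finite training losses abort with the epoch index.
* Ranking ties break by miRNA name ascending for deterministic output.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` computes structural quantities at the real catalog
scale (495 × 383, 5430 positives; the embedding stage runs 5 epochs there,
since widths do not depend on training length) and behavioral quantities on
the default planted bundle with k=5 and one negative resampling under
`paper_mode` — sizes chosen so the full run finishes in about a minute while
the CV estimates remain stable to a few thousandths of AUC.

## Known limitations

* The model is not end-to-end: embeddings are pre-trained unsupervised and
  frozen before classification.
* Computing the miRNA functional-similarity matrix itself is out of scope;
  it is consumed as an input file.
* Dense matrices throughout; intended for catalogs up to a few thousand
  entities per axis, not genome-scale graphs.
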