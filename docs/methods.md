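# Methods

`circdis` predicts circRNA–disease associations by link prediction on a
heterogeneous biological network. This note documents the model, the
numerical choices, and what the synthetic benchmark does and does not show.

## Model

### Network construction

Known associations form a binary matrix **A** ∈ {0,1}^{n×m} over n circRNAs
and m diseases; the heterogeneous network is the bipartite block adjacency
**X** = [[0, **A**], [**A**ᵀ, 0]] with circRNA nodes first.

Four similarity networks are built:

* **Disease semantic similarity (DS).** Diseases live in a rooted DAG
  (MeSH-style, supplied as a child→parent edge list). The semantic
  contribution of an ancestor d to a target dᵢ is SC_{dᵢ}(dᵢ) = 1 and
  otherwise max over children d′ of d inside the ancestor closure of
  γ·SC_{dᵢ}(d′) — i.e. γ^(shortest downward distance) for γ ≤ 1. With
  semantic value SV(dᵢ) = Σ SC over the closure,
  DS(dᵢ,dⱼ) = Σ_{shared ancestors}(SC_{dᵢ}+SC_{dⱼ}) / (SV(dᵢ)+SV(dⱼ)).
  γ defaults to 0.5, the conventional decay for DAG-based disease
  similarity. Diseases absent from the ontology are treated as isolated
  terms with a warning; the kernel fallback below fills their rows.
* **circRNA functional similarity (FS).** Under the hypothesis that similar
  circRNAs associate with similar diseases, FS(cᵢ,cⱼ) scores each disease in
  cᵢ's disease set by its best semantic match in cⱼ's set and vice versa,
  summing and dividing by the two set sizes. Either set empty gives 0. (A
  literal reading of the source formula's index sets would make every term
  the self-match and the statistic constant; the cross-set best-match form
  implemented here is the standard one and the only non-degenerate reading.)
* **Gaussian interaction profile (GIP) kernels (CK/DK).** K(u,v) =
  exp(−λ‖profile_u − profile_v‖²) over rows (circRNAs) or columns (diseases)
  of **A**, with bandwidth λ = p / Σ‖profile‖² for p profiles. An all-zero
  **A** leaves λ undefined and is an error. Profiles are whole interaction
  rows/columns; this is the only interpretation consistent with the
  bandwidth normalisation.
* **Integrated networks (Xc/Xd).** Elementwise: the semantic/functional
  value where non-zero, otherwise the GIP kernel — the kernel patches the
  sparsity of the curated similarity.

### Feature extraction

Each row of Xc (and Xd) is compressed by a sparse auto-encoder:
y = σ(x·W1 + b1) with hidden width k, then z = σ(y·W2 + b2) with a square
k×k second layer. The default training loss is literally the mean squared
discrepancy between hidden code and output, (1/p)Σ‖y − z‖², plus an
optional L1 penalty on hidden activations (default 0); σ is the logistic
sigmoid (so the objective is not trivially zero), trained by full-batch
gradient descent (defaults: 200 epochs, lr 1e-3, seeded normal init scaled
by 1/√fan-in). Because a k×k second layer cannot reconstruct the
p-dimensional input, a conventional mode (`mode="reconstruction"`, decoder
k×p, loss ‖x − z′‖², hidden codes used downstream) is provided behind a
flag; the literal form is the default. The per-row outputs Zc (n×k) and Zd
(m×k) are stacked into the node feature matrix Q ∈ R^{(n+m)×k}.

The hidden width defaults to k = 64 but is capped by the input dimension
(k ≤ min(n, m)); the desk-scale benchmarks here use k = 16 to respect the
m = 30 fixture.

### Local and global embeddings

* **Local (GCN propagation).** Â = D̃^{−1/2}(X+I)D̃^{−1/2}, and
  H^{(t+1)} = ReLU(Â·W_t·H^{(t)}) from H⁰ = Q for `depth` layers (default
  2), with seeded random **untrained** square weight matrices W_t. This is a
  deliberate design: the weights are never trained, so the local embedding
  is a random-projection smoothing of node features over neighbourhoods.
* **Global (biased walks + skip-gram).** Second-order random walks with
  return parameter p = 1.0 and in-out parameter q = 0.25 (a depth-first,
  community-exploring regime): from v, reached via t, a neighbour x is
  drawn proportionally to edge weight times 1/p if x = t, 1 if x neighbours
  t, 1/q otherwise. Defaults: 10 walks of length 80 per non-isolated node,
  window 5. The corpus is embedded by skip-gram with 5 negative samples
  drawn from the unigram^0.75 distribution, implemented as count-averaged
  mini-batch SGD in numpy (batch 512, initial rate 0.5 decaying linearly to
  5% — with a small vocabulary each node occurs many times per batch, so
  per-node gradients are averaged within the batch and the rate is set for
  that averaged regime). Isolated nodes receive zero vectors. All sampling
  is driven by a single seeded generator; embeddings are bit-reproducible.

The fused representation is the column concatenation H = [H_l ‖ H_g].

### Classification

A candidate pair (cᵢ, dⱼ) is represented by concatenating the two fused
node rows (width 4k; an elementwise-product variant is available).
Positives are the known associations; negatives are sampled uniformly
without replacement from unknown cells at ratio 1:1 (configurable) —
the balanced design implied by reporting near-equal sensitivity and
specificity. The classifier is extremely randomised trees with library
defaults (`ExtraTreesClassifier(random_state=seed, n_jobs=1)`); RF,
logistic regression, KNN and Gaussian naive Bayes are pluggable
alternatives. Thresholded metrics use a fixed cut-off of 0.5.

## Evaluation protocol

k-fold cross-validation (default 5 folds, 10 repeats) partitions the
**positive pairs**; nodes are shared across folds (the standard design for
association prediction; a node-wise split is not provided). Per fold,
every training-side artifact — DS is fold-independent, but FS, both GIP
kernels, the integrated similarities, the auto-encoder, both embeddings and
the negative sample — is rebuilt from the training positives only, with
test-fold positives zeroed. Training negatives are drawn from the zero
cells of the *training* matrix (so nothing on the training side can depend
on where the test positives sit; a handful of training negatives may
therefore coincide with held-out positives, a standard and conservative
source of label noise). Held-out positives are scored against an
equal-sized, disjoint sample of unknown cells of the full matrix. A
`gip_scope="global"` flag computes the kernels from the full matrix once,
for comparison with protocols that do not mask; it is leakage-unsafe and
off by default.

Metrics: accuracy, sensitivity, specificity, precision, MCC (any zero
confusion margin gives MCC 0 by convention), AUROC (probability a positive
outranks a negative, ties ½) and AUPR (precision–recall step integration).
Reports give per-fold-run values and mean ± std over all folds × repeats,
printed to 4 decimals.

The ablation harness runs three schemes — local embedding only, global
only, fused — on identical fold partitions, negative samples and classifier
seeds, so scheme differences are paired.

## Synthetic benchmark

The generator plants a learnable signal: latent scores are a product of two
non-negative rank-r gamma factor matrices, the top `n_pos` cells become
positives, and the disease ontology is a random recursive tree (depth-capped)
with ~15% extra child→ancestor edges so multi-parent terms exercise the max
rule. The standard desk-scale benchmark is n = 100 circRNAs, m = 30
diseases, 300 positives (density 0.10), rank 3 — sized so the full 5-fold
ablation completes in about a minute on one core while the planted
structure remains clearly recoverable.

What it emulates: a sparse binary bipartite network with block/low-rank
structure and a disease hierarchy correlated with nothing (the ontology is
independent of the planted factors, so the semantic channel contributes
realistic noise rather than signal). What it does not emulate: the extreme
sparsity (~1%) and long-tailed degree distributions of curated disease
databases, literature-biased positive ascertainment, or any sequence-level
circRNA information. Passing the desk-scale checks therefore demonstrates
that the machinery recovers plantable network structure without leakage —
not that real-data headline numbers transfer.

On this benchmark the fused scheme reaches mean 5-fold AUROC ≈ 0.83, the
global-only scheme is comparable, and the local-only scheme trails — the
qualitative ordering expected when random-walk embeddings carry most of the
signal on a sparse bipartite graph and the untrained GCN view adds local
smoothing.

## Numerical choices and edge cases

* One master seed fans out to every stochastic stage through
  `numpy.random.SeedSequence`; two identical runs produce byte-identical
  score files.
* Ties in ranked outputs break lexicographically on identifiers.
* Self-loops in the normalised adjacency guarantee positive degrees, so no
  degenerate divisions occur; its spectral radius is ≤ 1.
* Duplicate association rows collapse on load; identifiers are sorted
  lexicographically so matrix layout never depends on file order.
* An association list cannot represent circRNAs/diseases with zero
  associations; round-tripping is exact over ids with ≥ 1 association.

## Known limitations

* The GCN weights are untrained by design; the local view is a random
  projection, not a learned encoder, and is the weaker of the two views.
* Negative "labels" are unverified unknowns; reported specificity and
  precision are relative to the sampled-negative design, not to biological
  truth.
* The printed auto-encoder objective (hidden-vs-output) can be driven down
  by making the second layer near-identity; it regularises rather than
  reconstructs. Use `mode="reconstruction"` for a conventional auto-encoder.
* No probability calibration, hyperparameter search, or statistical tests
  between schemes are provided.
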