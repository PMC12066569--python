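# Methods

This note documents the model, the choices made where the design was
genuinely open, the synthetic data the package tests itself on, and the
limits of what those tests demonstrate.

## Problem setting

Drug repositioning asks which unobserved entries of a binary drug-disease
association matrix `S` (drugs in rows, diseases in columns) are likely true
therapeutic links.  The inputs are `S` itself plus two precomputed
similarity matrices: drug-drug and disease-disease, square, symmetric,
entries in [0, 1], unit diagonal.  The model treats each similarity matrix
as a graph signal and the association matrix as both supervision and a
third (bipartite) graph.

## Graph construction

Each similarity matrix becomes a k-nearest-neighbour graph: node `i`
connects to its `k` most similar other nodes (ties broken by lowest index
for determinism), the directed edge set is symmetrised by union — which
keeps sparse similarity structure connected, unlike mutual-kNN — and every
node receives a self-loop so that its own features enter its neighbourhood
aggregation.  `k` defaults to 15, a common choice for similarity graphs
with a few hundred nodes; adjacency is binary because attention only needs
neighbourhood membership.  Node features default to the rows of the
similarity matrix itself, which requires no external chemistry or ontology
data.

The association view is a bipartite graph on drugs ∪ diseases whose edges
are the *training-fold* positives only, plus self-loops.  It is rebuilt for
every fold, so held-out pairs never participate in message passing.

## Encoder

Three GAT stacks with identical architecture and separate weights ("twin"
encoders plus an association encoder), each three layers deep.  Per head,

    alpha_ij = softmax_{j in Ne(i)} LeakyReLU(a · [W h_i || W h_j]),
    h_i' = LeakyReLU( sum_j alpha_ij W h_j ),

with a learnable per-head score vector `a` (the printed attention formula
omits it; the standard GAT parameterisation is used).  Hidden layers
concatenate `K` heads (per-head width d/K), the last layer averages heads
at full width `d`; no extra nonlinearity after averaging.  Defaults:
`d` = 128 embedding width, `K` = 4 heads, LeakyReLU slope 0.2, dropout 0.2
applied both to layer inputs and to attention coefficients during training
(the two standard GAT dropout sites).  Initial node features are a learned
linear projection of the similarity rows to width `d`.

## Adaptive fusion

To counter over-smoothing, each view's last-layer output is mixed with a
residual transform `R(h0) = Elu(W h0 + b)` of its initial features:

    H^(v) = eps_v · H^l + (1 − eps_v) · R(h0),

and the similarity view and association view of each entity are fused as

    H = [ eta · H^(1) + (1 − eta) · H^(2) ; H^(1) ; H^(2) ],

i.e. the convex mix concatenated with both views (fused width = 3d).  The
mixing scalars are sigmoids of unconstrained parameters initialised at 0,
so they start at 0.5 (unbiased mixing) and remain strictly inside (0, 1)
throughout training.  With eps = 1 and eta = 0.5 the pipeline reduces to
concatenated GAT outputs, a regression baseline used in tests.

## Scoring head

The pair score is `sigmoid(head(features))`.  Three heads are provided:

- **kan** (default): a Kolmogorov-Arnold network of widths
  [input, 64, 1] — one learnable activation
  `phi(x) = w_b·SiLU(x) + w_s·sum_i c_i B_i(x)` per edge, node values
  formed by summing incoming post-activations.  `B_i` are cubic B-splines
  on a fixed grid of 5 uniform intervals over [−2, 2] (no grid
  refinement); head inputs pass through a non-learned layer-norm rescale
  so they land in the grid range, and values still outside are clamped
  (zero spline gradient there).  Spline coefficients start near zero with
  `w_s = 1/√fan-in` and fan-in-scaled *random* base weights: starting all
  base weights equal would make every hidden unit the same function at
  initialisation, collapsing the layer's effective width and stalling
  training.
- **mlp**: an affine + SiLU stack with one hidden layer (64 units by
  default), the ablation baseline.
- **dot**: the literal inner product of the fused embeddings.

The head input is the Hadamard product `M_i ⊙ D_j` of the fused pair
(option `pair_features: product`).  The inner-product score is the special
case of identity activations on these products, so the KAN head strictly
generalises the dot scorer; feeding the concatenation `[M_i ; D_j]`
(option `concat`, also provided) forces the head to discover multiplicative
interactions from scratch, which trains far more slowly at this scale —
with `concat` features neither the KAN nor the MLP head fit even the
training folds within the reference epoch budget, while `product` features
train cleanly.  The B-spline basis is evaluated by the Cox-de Boor
recursion with the analytic degree-lowering derivative for
backpropagation; the test suite cross-checks it against an independent
B-spline implementation and checks all gradients against central finite
differences.

## Objective

Binary cross-entropy over the scored pair set (mean reduction by default
for learning-rate stability; the summed form, which the formula tests
exercise, is available via `ce_reduction: sum`), plus two cross-view
contrastive regularisers weighted by `w_MC = w_DC = 0.1`:

    L_view = (1/N²) · sum_ij [ dis(m_i^1, m_i^2) − dis(m_i^1, m_j^2) ],

with `dis(u, v) = −cos(u, v)`, computed once over drugs and once over
diseases.  Averaging over anchors as well as contrasts makes the value
independent of entity count.  View 1 is the similarity-graph embedding,
view 2 the association-graph embedding.  Negative pairs for the
cross-entropy are resampled every epoch at a 1:1 ratio to the training
positives from the fold's unknown pairs (scoring every unknown pair each
epoch would be quadratic).

## Training and evaluation protocol

Adam with learning rate 1e-3 and classic L2 weight decay 1e-3, 300 epochs,
no early stopping.  Cross-validation partitions *all* drug-disease pairs
(positives and negatives together) into 10 random test folds of near-equal
size; each fold's model trains on the other nine and scores the held-out
pairs.  Reported metrics: AUROC (midrank tie handling), recall and F1 at a
0.5 probability threshold — the threshold is a package convention and is
reported explicitly, since threshold-dependent metrics are meaningless
without it.  Per-fold values are aggregated as mean ± SD.  A
`disease-cold` split mode holds out whole disease columns instead,
for generalisation to diseases with no known associations.

All randomness derives from one run seed through named substreams (fold
shuffle, parameter init, negative sampling, dropout), so equal seeds give
byte-identical artifacts.

## Synthetic data

The generator plants the structure the model assumes: unit-norm latent
factor rows `U` (drugs, 100×8 by default) and `V` (diseases, 80×8);
similarity `(1 + cos)/2` plus Gaussian noise (sd 0.05), symmetrised,
clipped to [0, 1], unit diagonal; associations drawn Bernoulli from
`sigmoid(4·U_i·V_j + b)` with `b` bisected so the expected positive rate
equals the requested density (0.05).  Ground-truth factors ship with the
bundle so tests can use the oracle scorer `U V^T`.

Because labels are sampled with a finite logistic slope, even the
ground-truth oracle's AUC is bounded well below 1 (≈0.83 at the defaults);
trained-model AUCs should be read against that ceiling, not against 1.0.
What the generator does **not** emulate: realistic similarity kernels
(chemical fingerprints, semantic ontologies), block/community structure,
popularity skew in associations, and cross-dataset covariate shift.
Passing the synthetic checks therefore shows the pipeline can recover a
planted low-rank signal end to end — it does not certify performance on
the public benchmarks, whose loaders are validated separately against
their published dimensions and association counts when the downloads are
present.

## Desk-scale evaluation configuration

The self-contained evaluation runs (acceptance script, end-to-end tests)
use the reference synthetic condition above with a reduced model —
embedding width 32, 2 heads, 300 epochs — and evaluate one fold of the
10-fold split per seed; medians are taken over seeds (3 seeds for the
trained-vs-untrained gain, 5 for the ablation tendency).  The reduced
width keeps a single run around 20 s on one CPU without changing any
qualitative behaviour observed at width 128.

## Numerical choices

- Tensor arithmetic in float64 throughout; gradients are exact
  closed-form rules, verified against central differences at 1e-4.
- Attention softmax subtracts the row maximum before exponentiation;
  masked (non-neighbour) entries get probability exactly 0.
- Cross-entropy clamps probabilities at 1e-12 before logs.
- Cosine distances add 1e-12 inside the norm only in the differentiable
  training path; the plain function raises on zero vectors.
- Similarity symmetry is enforced at read time to 1e-8, with the worst
  cell named in the error.
- Matrix files round-trip bit-exactly (17-significant-digit output,
  round-trip float parsing).

## Known limitations

- Dense adjacency and attention matrices: fine for benchmark-scale
  networks (hundreds of nodes), wasteful beyond ~10⁴ nodes.
- Recall/F1 depend on the fixed 0.5 threshold; under severe class
  imbalance they are close to 0 for scores calibrated near the base rate,
  which is expected behaviour rather than a defect (AUC is the primary
  metric).
- No grid refinement or pruning in the KAN layer.
- The ablation comparison (KAN vs MLP head) on planted low-rank data sits
  near the problem's noise ceiling, where head flexibility matters little;
  differences there are small by construction.
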