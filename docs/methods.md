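# Methods

## Problem setting

DNA–protein binding prediction is treated as transductive link prediction
on a homogeneous undirected graph: every DNA element and every protein is
a vertex (with a class label carried as a node attribute), every known
binding is an edge of the single relation type, and candidate pairs are
scored for edge existence. Negative examples are entity corruptions of
positives: one endpoint of a known binding pair is replaced, uniformly at
random, by another vertex of the same class, rejecting replacements that
recreate a known positive. The corruption side (DNA vs protein) is chosen
by a fair coin.

## The algebraic path engine

The pair representation is the ⊕-aggregation over all walks u→v of the
⊗-product of edge values along the walk, computed by the generalized
Bellman-Ford recursion with boundary condition h⁰(u,v) = 1̄·[v=u]. Two
semantic commitments matter:

- **Walks, not simple paths.** The recursion counts walks (vertices may
  repeat); the brute-force oracle therefore enumerates walks too. This is
  the semantics under which Katz and PageRank are exact instantiations.
- **Truncation at T iterations equals aggregation over walks of length
  ≤ T**, because the boundary term is ⊕-added at every iteration. The
  enumeration oracle is capped at length 8 (exponential cost) and the
  equivalence is asserted exactly for integer-valued semirings and to
  1e-9 otherwise.

Undirected edges contribute both directions with the same value.
Personalized PageRank is realized as the same sum–product recursion with
degree-normalized damped transition values α/deg(x) on each directed arc,
with the restart mass (1−α) applied as a final scaling — walk-sum algebra
identical to the other four instantiations. ⊗ is not required to be
commutative; matrix-valued edge representations are exercised in tests.

## Neural parametrization

Each layer computes, for every node v,
`h_v^t = W·AGG({MES(h_x^{t−1}, w) : (x,v) ∈ E(v)} ∪ {h_v⁰}) + b`.

- The boundary term h⁰ participates in **every** layer's aggregation, not
  just at t=0; mean aggregation counts it as one element (divisor deg+1).
- Messages: DistMult (elementwise product), TransE (translation), RotatE
  (elementwise complex rotation; phases parameterized as angles so the
  rotation is exactly unit-modulus, requiring even hidden dimension).
- A learned linear mixing (W, b) follows aggregation in each layer; with
  W = I, b = 0, scalar states and DistMult+sum the layer is *exactly* one
  sum–product Bellman-Ford step, which is the keystone reduction test.
- Edge representations are per-layer vectors shared by all edges of the
  single binding relation.

For sum and mean aggregation the message+reduce pair is linear in the
neighbor states and is evaluated as one sparse adjacency product per
layer; max aggregation materializes per-edge messages and routes
gradients to the argmax entry (boundary wins ties). All differentiable
computation runs on a small tape-based reverse-mode autodiff over numpy
(float64), written for exactly the operator set this model needs; there
is no deep-learning framework dependency and runs are bit-reproducible
from the seed on one CPU.

## Pooling

**SortPooling** sorts node rows by a continuous Weisfeiler-Lehman-style
color — the last feature channel, ties broken by the preceding channels
right-to-left and finally by the stable canonical node order, so runs are
reproducible — keeps the top K rows (default K = 10) and zero-pads when
fewer rows are available.

**AlphaMEX** pools an M×d matrix per channel by
`(1/log(α/(1−α))) · log((1/n) Σᵢ (α/(1−α))^{hᵢ})`. The trainable α is
realized as α = 0.5 + 0.5·σ(θ), confining it to (0.5, 1): at α = 0.5 the
normalizer vanishes and below it the pool flips toward a soft minimum, so
only the soft-max branch is exposed. Initial α = 0.9. The sum is
evaluated in log-space with a max shift; results equal the literal
formula to 1e-9 for |h| ≤ 50, far beyond where naive exponentiation
overflows. Note the convergence toward the channel maximum as α → 1⁻ is
logarithmic: on inputs {0, 1} the pooled value is 1 − log 2 / log(α/(1−α)),
which is ≈ 0.90 at α = 0.999 and crosses 0.99 only within ~1e-30 of 1.

## Classifier architecture

Three feature modules (2 NBFnet layers each by default, total depth
T = 6, on the rationale that walks longer than about six hops contribute
little to link prediction; the depth sweep is exposed via the ablation
grid for anyone who wants to re-examine this) each apply
leaky ReLU (slope 0.2) and SortPooling; three per-module AlphaMEX pools
are summed by the addition module. Because graph-level pooling alone
would lose the identity of the target node, the pooled summary is
concatenated with the source-conditioned target state h(u, v) from the
final module before the fully connected stack (256 → 64 → 2, leaky ReLU
between, log-softmax head computed jointly for stability). SortPooling is
applied over the pair's enclosing context: nodes within two hops of u or
v, with u and v always included.

## Training protocol

Adam (lr 1e-3), batch size 32, default 30 epochs, one freshly corrupted
negative per positive per epoch. Per-fold seeds are master seed + fold
index; every random draw (initialization, corruption, shuffling,
splitting) flows from `numpy.random.default_rng` seeds, so loss traces
are bitwise reproducible. Multiplicative edge representations are
initialized near 1/mean-degree so initial states stay O(1) across six
layers of walk accumulation.

Two leakage controls are applied:

1. Test-fold positive edges are removed from the fold's message-passing
   graph (standard transductive hygiene).
2. Within each training batch, the batch's own positive query edges are
   additionally masked from that batch's adjacency. Without this the
   model simply reads off first-hop adjacency during training and
   transfers nothing to held-out links (measured: chance-level test
   AUROC); with it, the model must predict each edge from the surrounding
   path structure, which is the quantity that generalizes.

A label-shuffled control run through the identical pipeline loses the
planted signal; note it can score *below* 0.5 AUROC, because query-edge
masking is label-driven — under shuffled labels, true edges labelled 0
keep their edges at training time while evaluated positives do not, which
inverts the adjacency cue. Comparisons against the control therefore use
the margin of the informative run over it, not the control's absolute
distance from 0.5.

Thresholded metrics use 0.5 on the positive-class probability; AUROC is
trapezoidal. Metrics with degenerate denominators are reported as an
explicit NA marker (`None`), never silently 0, and fold averages skip
them.

## Synthetic benchmark

The generator plants a latent-factor Bernoulli bipartite graph: factor
vectors z ∈ R^f with i.i.d. N(0, 1/f) entries per node, link probability
σ(scale·⟨z_d, z_p⟩ + bias) with the bias calibrated by root finding so
the expected density matches ρ. Defaults: 100 DNA × 100 protein nodes,
f = 4, ρ = 0.05, scale = 8. The scale was fixed so that the benchmark is
demonstrably learnable before the classifier is judged: a factor oracle
scoring held-out positives against matched corrupted negatives achieves
AUROC ≈ 0.95 (the package requires ≥ 0.9). Shared latent factors induce
the multi-hop shared-partner structure a path-based predictor exploits.

What the generator does *not* emulate: motif-level sequence signal,
degree heavy tails of real ChIP-derived networks, assay noise structure,
or inter-dataset heterogeneity. Passing the synthetic benchmark shows the
pipeline learns planted relational structure end to end; it does not
certify performance on experimental compendia.

An important property of these conditions, measured on the same CV folds
the classifier sees: with 500 observed edges and 800 latent parameters,
the observed graph carries limited information about held-out links. A
logistic regression over walk-count features attains mean test AUROC
0.819, rank-4 SVD 0.708, and rank-4 logistic matrix factorization — the
generating model family itself — 0.759. The default classifier's ≈ 0.82
therefore sits at the measured ceiling; substantially higher values at
these sizes would indicate leakage, not skill. Scores are reported per
fold and as fold means.

## Problem sizes

Defaults are sized for a single CPU: the walk-enumeration oracle runs on
graphs of ≤ 8 nodes and lengths ≤ 8; engine and reduction checks use
20 / 10 random graphs; the benchmark is 200 nodes / ~1000 labelled pairs
with 4-fold CV; the acceptance script runs one full CV plus one
label-shuffled control CV.

## Known limitations

- Transductive only: nodes unseen at fit time cannot be scored.
- Single relation type; no heterogeneous-graph support.
- Sequence-derived features (k-mer composition for DNA, conjoint-triad
  7-group composition for proteins) are generated and encodable but the
  default model is structure-only; wiring them into the indicator is
  future work.
- The scoring is conditioned on the first endpoint of the pair (source);
  scores are not symmetrized.
- Exact non-truncated Katz (matrix inverse) is exposed for testing only.
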