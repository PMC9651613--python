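# nbflink

Path-based graph neural link prediction for DNA–protein binding.

Experimentally mapping which DNA elements bind which proteins (e.g. by
ChIP-seq) is slow and expensive, so a common computational strategy is to
pose binding as **link prediction**: known bindings form the edges of an
interaction graph whose vertices are DNA elements and proteins, and the
task is to score unobserved vertex pairs. `nbflink` implements this for
people who study protein–DNA interaction networks — a self-contained
Python package with an exact algebraic path engine, a neural Bellman-Ford
link classifier, evaluation machinery, and a planted-structure synthetic
benchmark so the whole pipeline is testable without any external data.

## The model

For a pair (u, v), the pair representation is a generalized sum over all
walks from u to v of generalized products of edge representations:

    h(u, v) = ⊕_{P ∈ P_uv} ⊗_{e ∈ P} w(e)

With (⊕, ⊗) forming a semiring, this is computed in polynomial time by the
generalized Bellman-Ford recursion

    h⁰(u, v) = 1̄ · [v = u]
    hᵗ(u, v) = ( ⊕_{(x,v) ∈ E(v)} hᵗ⁻¹(u, x) ⊗ w(x, v) ) ⊕ h⁰(u, v)

Classical link-prediction scores are instances: graph distance (min, +),
Katz (+, ×), widest path (max, min), most reliable path (max, ×), and
personalized PageRank (damped sum–product). All five are available
exactly via `nbflink.semiring`, validated against brute-force walk
enumeration.

The neural model replaces the algebra with learned operators: an
INDICATOR writes a query embedding on the source row, a MESSAGE function
(DistMult ∘ / TransE + / RotatE complex rotation) combines neighbor
states with learned edge representations, and an AGGREGATE (sum / mean /
max, always including the boundary term) reduces them. Three feature
modules (NBFnet layers → leaky ReLU, slope 0.2 → SortPooling) feed three
trainable log-mean-exp (AlphaMEX) global pools; their sum, concatenated
with the target-node state h(u, v), passes through fully connected layers
of 256, 64 and 2 units and a log-softmax to give (log p₊, log p₋).
Training minimizes the negative log-likelihood over positives plus
freshly corrupted negatives. Everything runs on one CPU with a built-in
reverse-mode autodiff over numpy; there is no GPU or deep-learning
framework dependency.

## Worked example

```python
from nbflink import DPBNBFnet, TrainConfig, cross_validate, generate

# planted bipartite benchmark: 100 DNA x 100 protein nodes, 4 latent
# factors, 5% link density
ds = generate(n_dna=100, n_protein=100, f=4, density=0.05, seed=3)
print(len(ds.positives), len(ds.negatives))   # 502 502

res = cross_validate(ds.graph, ds.examples, TrainConfig(epochs=30, seed=1))
print({k: round(v, 3) for k, v in res.mean.items()})
# {'precision': 0.787, 'recall': 0.665, 'accuracy': 0.741,
#  'mcc': 0.49, 'auroc': 0.816}
```

Each fold trains on 3/4 of the labelled pairs (test-fold positive edges
are removed from the message-passing graph) and is scored on the held-out
quarter. Mean test AUROC ≈ 0.82 here is at the information ceiling of
this graph: on the same folds, a logistic regression over walk-count
features reaches 0.819 and a rank-4 logistic matrix factorization — the
model family that generated the data — reaches 0.759. The corresponding
label-shuffled control sits at chance (≈ 0.5).

The same pipeline is scriptable from the shell:

```sh
nbflink simulate --seed 7 --n-dna 100 --n-protein 100 --density 0.05 --out data/toy.tsv
nbflink cv --graph data/toy.tsv --outdir runs/cv0 --epochs 30 --seed 1
nbflink classic --method katz --beta 0.05 --source d0001 --iters 10 --graph data/toy.tsv
nbflink ablate --graph data/toy.tsv --outdir runs/grid --grid functions
```

## Layout

- `nbflink.graph` — interaction-graph data model, edge-TSV/FASTA I/O,
  negative sampling by entity corruption, stratified k-fold splitting
- `nbflink.semiring` — generalized Bellman-Ford over pluggable semirings,
  the walk-enumeration oracle, the five classical instantiations
- `nbflink.autodiff` — minimal reverse-mode autodiff over numpy
- `nbflink.layers` — INDICATOR / MESSAGE / AGGREGATE and the layered
  neural Bellman-Ford forward pass
- `nbflink.pooling` — SortPooling and AlphaMEX
- `nbflink.model` — the `DPBNBFnet` scikit-learn-style estimator and loss
- `nbflink.train_eval` — training protocol, confusion/MCC/AUROC metrics,
  cross-validation
- `nbflink.synthetic` — planted latent-factor benchmark generator and
  sequence composition encoders
- `nbflink.cli` — the `nbflink` command-line tool

See `docs/methods.md` for the modelling choices and their rationale.
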