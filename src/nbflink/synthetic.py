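"""Synthetic bipartite DNA-protein interaction benchmarks.

Positive links are planted by a latent-factor Bernoulli model: every node
carries a factor vector z ∈ R^f with i.i.d. N(0, 1/f) entries, and a
DNA-protein pair links with probability sigmoid(scale·⟨z_d, z_p⟩ + bias),
the bias calibrated by root finding so the expected edge density matches
the target ρ.  Shared latent factors induce the multi-hop shared-partner
structure a path-based link predictor is designed to exploit, which is
what makes the benchmark learnable from topology alone.  Negatives are
entity corruptions of positives (one endpoint replaced uniformly within
its class), matching the training-time negative sampling.

Optional sequence features: random nucleotide / amino-acid sequences per
node plus the standard composition encoders (k-mer fractions for DNA and
conjoint-triad 7-group fractions for proteins).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .graph import (
    DNA,
    PROTEIN,
    CorruptionExhaustedError,
    InteractionGraph,
    LinkExample,
    corrupt_negative,
)

#: conjoint-triad physicochemical grouping of the 20 standard residues
PROTEIN_7GROUPS = (
    frozenset("AGV"),
    frozenset("ILFP"),
    frozenset("YMTS"),
    frozenset("HNQW"),
    frozenset("RK"),
    frozenset("DE"),
    frozenset("C"),
)
_RESIDUE_GROUP = {aa: i for i, grp in enumerate(PROTEIN_7GROUPS) for aa in grp}


@dataclass
class LatentFactors:
    """Planted per-node factors and the calibrated link model."""

    dna_factors: np.ndarray  # (n_dna, f)
    protein_factors: np.ndarray  # (n_protein, f)
    scale: float
    bias: float
    density: float

    def pair_score(self, i_dna: int, j_protein: int) -> float:
        """Planted affinity ⟨z_d, z_p⟩ — the oracle score for a pair."""
        return float(self.dna_factors[i_dna] @ self.protein_factors[j_protein])

    def link_probability(self) -> np.ndarray:
        return expit(self.scale * (self.dna_factors @ self.protein_factors.T) + self.bias)


@dataclass
class SyntheticDataset:
    graph: InteractionGraph
    positives: list[LinkExample]
    negatives: list[LinkExample]
    heldout: list[LinkExample]
    heldout_negatives: list[LinkExample]
    factors: LatentFactors
    seed: int
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def examples(self) -> list[LinkExample]:
        """Training pool: observed positives plus matched negatives."""
        return self.positives + self.negatives


def dna_id(i: int) -> str:
    return f"d{i:04d}"


def protein_id(j: int) -> str:
    return f"p{j:04d}"


def generate(
    n_dna: int = 100,
    n_protein: int = 100,
    f: int = 4,
    density: float = 0.05,
    heldout_frac: float = 0.0,
    seed: int = 0,
    scale: float = 8.0,
    with_sequences: bool = False,
    dna_length: int = 100,
    protein_length: int = 200,
) -> SyntheticDataset:
    """Draw a planted bipartite interaction dataset.

    ``scale`` controls how sharply the link probability follows the latent
    affinity (higher = less noise); the bias is calibrated so the expected
    density equals ``density``.  Every draw is a pure function of ``seed``.
    """
    if n_dna < 1 or n_protein < 1:
        raise ValueError("need at least one node per class")
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must be in (0, 1), got {density}")
    if not 0.0 <= heldout_frac < 1.0:
        raise ValueError(f"heldout_frac must be in [0, 1), got {heldout_frac}")
    rng = np.random.default_rng(seed)

    zd = rng.normal(0.0, 1.0 / np.sqrt(f), size=(n_dna, f))
    zp = rng.normal(0.0, 1.0 / np.sqrt(f), size=(n_protein, f))
    affinity = zd @ zp.T

    def mean_prob(bias: float) -> float:
        return float(expit(scale * affinity + bias).mean())

    lo, hi = -50.0, 50.0
    if not mean_prob(lo) < density < mean_prob(hi):
        raise ValueError(f"cannot calibrate density {density} at scale {scale}")
    bias = brentq(lambda b: mean_prob(b) - density, lo, hi, xtol=1e-10)
    factors = LatentFactors(zd, zp, scale, bias, density)

    graph = InteractionGraph()
    for i in range(n_dna):
        graph.add_node(dna_id(i), DNA)
    for j in range(n_protein):
        graph.add_node(protein_id(j), PROTEIN)

    prob = factors.link_probability()
    draws = rng.random(size=prob.shape)
    pos_pairs = [
        (dna_id(i), protein_id(j))
        for i, j in zip(*np.nonzero(draws < prob))
    ]
    all_positives = [LinkExample(u, v, 1) for u, v in pos_pairs]

    n_held = int(round(heldout_frac * len(all_positives)))
    held_idx = set(rng.choice(len(all_positives), size=n_held, replace=False).tolist())
    heldout = [e for i, e in enumerate(all_positives) if i in held_idx]
    positives = [e for i, e in enumerate(all_positives) if i not in held_idx]
    for e in positives:
        graph.add_edge(e.u, e.v)

    # matched corrupted negatives, disjoint from every planted positive
    forbidden = {e.key() for e in all_positives}
    negatives, heldout_negatives = [], []
    for source, sink in ((positives, negatives), (heldout, heldout_negatives)):
        for pos in source:
            try:
                neg = corrupt_negative(graph, pos, rng, forbidden=forbidden)
            except CorruptionExhaustedError:
                continue
            forbidden.add(neg.key())
            sink.append(neg)

    sequences: dict[str, str] = {}
    if with_sequences:
        nts = np.array(list("ACGT"))
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for i in range(n_dna):
            sequences[dna_id(i)] = "".join(rng.choice(nts, size=dna_length))
        for j in range(n_protein):
            sequences[protein_id(j)] = "".join(rng.choice(aas, size=protein_length))

    return SyntheticDataset(
        graph=graph,
        positives=positives,
        negatives=negatives,
        heldout=heldout,
        heldout_negatives=heldout_negatives,
        factors=factors,
        seed=seed,
        sequences=sequences,
    )


def write_dataset(dataset: SyntheticDataset, tsv_path, fasta_path=None) -> None:
    """Write the edge TSV (and optional FASTA) for the generated dataset."""
    from .graph import write_edge_tsv

    write_edge_tsv(tsv_path, dataset.graph, dataset.examples)
    if fasta_path is not None and dataset.sequences:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=node, description="synthetic")
            for node, seq in dataset.sequences.items()
        ]
        SeqIO.write(records, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Sequence composition encoders


def encode_protein_7group(sequence: str, *, skip_unknown: bool = False) -> np.ndarray:
    """Composition fractions over the 7 conjoint-triad residue classes."""
    counts = np.zeros(7)
    n = 0
    for aa in sequence.upper():
        g = _RESIDUE_GROUP.get(aa)
        if g is None:
            if skip_unknown:
                continue
            raise ValueError(f"unknown residue {aa!r}")
        counts[g] += 1
        n += 1
    if n == 0:
        raise ValueError("empty protein sequence")
    return counts / n


def encode_dna_kmer(sequence: str, k: int, *, skip_unknown: bool = False) -> np.ndarray:
    """Normalized k-mer composition over {A,C,G,T}^k (k ≤ 4)."""
    if not 1 <= k <= 4:
        raise ValueError(f"k must be in 1..4, got {k}")
    seq = sequence.upper()
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    index = {km: i for i, km in enumerate(kmers)}
    counts = np.zeros(len(kmers))
    n = 0
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km not in index:
            if skip_unknown:
                continue
            raise ValueError(f"ambiguous base in k-mer {km!r}")
        counts[index[km]] += 1
        n += 1
    if n == 0:
        raise ValueError("no valid k-mers in sequence")
    return counts / n
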