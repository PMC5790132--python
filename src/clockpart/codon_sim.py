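"""Codon alignment simulation under the M3 (discrete) codon model.

Sites fall into K omega classes (nonsynonymous/synonymous rate ratios
omega_k with probabilities p_k).  Within a class, substitution follows a
Goldman-Yang-type codon model on the 61 sense codons of the universal
code: only single-nucleotide changes have positive rate, transitions are
weighted by kappa and nonsynonymous changes by omega.  The class matrices
share one global scale factor chosen so that the mixture-averaged
substitution rate is 1 per codon site per unit branch length, which makes
the simulated branch lengths (3x the nucleotide-scale lengths of the gene
trees) read as expected substitutions per codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .clock_sim import GeneRealization
from .trees import SpeciesTimeTree

__all__ = [
    "SENSE_CODONS",
    "M3Model",
    "CodonAlignment",
    "NucleotideAlignment",
    "build_codon_rate_matrix",
    "normalize_mixture",
    "simulate_alignment",
    "concatenate_alignments",
    "conserved_gene_model",
    "less_conserved_gene_model",
    "write_fasta",
    "write_phylip",
    "write_partition_file",
]

_NUCS = "TCAG"  # PAML ordering
SENSE_CODONS: list[str] = [
    a + b + c
    for a in _NUCS
    for b in _NUCS
    for c in _NUCS
    if a + b + c not in standard_dna_table.stop_codons
]
_AA = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}
_NUC_INDEX = {n: i for i, n in enumerate("ACGT")}
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _single_diff(c1: str, c2: str) -> int | None:
    """Position (0..2) of the single differing nucleotide, else None."""
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    return diffs[0] if len(diffs) == 1 else None


@dataclass(frozen=True)
class M3Model:
    """M3 (discrete) codon model: K omega classes sharing kappa and pi."""

    kappa: float = 2.0
    omegas: tuple[float, ...] = (0.01, 0.5, 0.9)
    probs: tuple[float, ...] = (0.8, 0.19, 0.01)
    pi: np.ndarray = field(default_factory=lambda: np.full(61, 1.0 / 61.0))
    n_codons: int = 500

    def __post_init__(self) -> None:
        if len(self.omegas) != len(self.probs):
            raise ValueError("one probability per omega class required")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if any(w < 0 for w in self.omegas):
            raise ValueError("omega ratios must be non-negative")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (61,) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
            raise ValueError("pi must be a distribution over the 61 sense codons")

    @property
    def mean_omega(self) -> float:
        return float(np.dot(self.probs, self.omegas))


def conserved_gene_model(n_codons: int = 500, kappa: float = 2.0) -> M3Model:
    """Conserved-gene mixture (mean omega 0.112)."""
    return M3Model(kappa=kappa, omegas=(0.01, 0.5, 0.9),
                   probs=(0.8, 0.19, 0.01), n_codons=n_codons)


def less_conserved_gene_model(n_codons: int = 500, kappa: float = 2.0) -> M3Model:
    """Less-conserved-gene mixture (mean omega 0.335)."""
    return M3Model(kappa=kappa, omegas=(0.01, 0.5, 0.9),
                   probs=(0.5, 0.3, 0.2), n_codons=n_codons)


def build_codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unscaled 61x61 instantaneous rate matrix of one omega class.

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for codon
    pairs differing at exactly one nucleotide, 0 otherwise; rows sum to 0.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (61,):
        raise ValueError("pi must have length 61 (sense codons only)")
    q = np.zeros((61, 61))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            k = _single_diff(ci, cj)
            if k is None:
                continue
            rate = pi[j]
            if frozenset((ci[k], cj[k])) in _TRANSITIONS:
                rate *= kappa
            if _AA[ci] != _AA[cj]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def normalize_mixture(
    matrices: list[np.ndarray], probs, pi: np.ndarray
) -> list[np.ndarray]:
    """Rescale class matrices so the mixture-mean rate is 1 per codon site.

    One global factor is applied to all classes (classes keep their
    relative rates), so that sum_k p_k sum_i pi_i (-q_ii^(k)) = 1.
    """
    pi = np.asarray(pi, dtype=float)
    total = sum(
        p * float(-np.dot(pi, np.diag(q))) for p, q in zip(probs, matrices)
    )
    if total <= 0:
        raise ValueError("total substitution rate must be positive")
    return [q / total for q in matrices]


class _ClassKernels:
    """Cached spectral decompositions of the scaled class matrices."""

    def __init__(self, model: M3Model):
        raw = [build_codon_rate_matrix(model.kappa, w, model.pi) for w in model.omegas]
        self.matrices = normalize_mixture(raw, model.probs, model.pi)
        self.pi = np.asarray(model.pi, dtype=float)
        sq = np.sqrt(self.pi)
        self._decomp = []
        for q in self.matrices:
            sym = (sq[:, None] * q) / sq[None, :]
            lam, vec = np.linalg.eigh((sym + sym.T) / 2.0)
            self._decomp.append((lam, vec))
        self._sq = sq

    def transition_matrix(self, klass: int, t: float) -> np.ndarray:
        lam, vec = self._decomp[klass]
        inner = (vec * np.exp(lam * t)) @ vec.T
        p = (inner / self._sq[:, None]) * self._sq[None, :]
        np.maximum(p, 0.0, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


@dataclass
class CodonAlignment:
    """Simulated codon alignment plus simulation metadata."""

    taxa: list[str]
    codons: np.ndarray         # (n_taxa, n_sites) indices into SENSE_CODONS
    site_classes: np.ndarray   # (n_sites,) omega-class label per site
    gene: int = 0

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def sequences(self) -> list[str]:
        return [
            "".join(SENSE_CODONS[c] for c in row) for row in self.codons
        ]

    def to_nucleotides(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (n_taxa, 3n) matrix of nucleotide indices (ACGT=0..3)
        and the 1-based codon position of every column."""
        codon_nucs = np.array(
            [[_NUC_INDEX[ch] for ch in codon] for codon in SENSE_CODONS],
            dtype=np.int8,
        )
        nt = codon_nucs[self.codons].reshape(self.codons.shape[0], -1)
        pos = np.tile(np.array([1, 2, 3], dtype=np.int8), self.n_sites)
        return nt, pos


@dataclass
class NucleotideAlignment:
    """Nucleotide super-alignment with per-column block annotation."""

    taxa: list[str]
    matrix: np.ndarray      # (n_taxa, n_cols) int8, ACGT = 0..3
    col_gene: np.ndarray    # (n_cols,) gene index of each column
    col_pos: np.ndarray     # (n_cols,) codon position 1/2/3

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def columns(self, index: np.ndarray) -> "NucleotideAlignment":
        return NucleotideAlignment(
            taxa=list(self.taxa),
            matrix=self.matrix[:, index],
            col_gene=self.col_gene[index],
            col_pos=self.col_pos[index],
        )

    def sequences(self) -> list[str]:
        lut = np.array(list("ACGT"))
        return ["".join(lut[row]) for row in self.matrix]


def simulate_alignment(
    gene: GeneRealization,
    model: M3Model,
    tree: SpeciesTimeTree,
    rng: np.random.Generator,
    kernels: _ClassKernels | None = None,
) -> CodonAlignment:
    """Evolve one gene's codon alignment down the species tree.

    Each site draws an omega class (multinomially, probabilities p_k) and a
    root codon from pi, then evolves along every branch with the class
    transition matrix exp(Q_k * codon branch length).
    """
    if kernels is None:
        kernels = _ClassKernels(model)
    n = model.n_codons
    n_classes = len(model.omegas)
    classes = rng.choice(n_classes, size=n, p=np.asarray(model.probs))
    states = np.empty((tree.n_nodes, n), dtype=np.int16)
    states[tree.root_index] = rng.choice(61, size=n, p=kernels.pi)

    blen = {int(c): float(t) for c, t in zip(tree.branch_child, gene.codon_lengths)}
    order = [tree.root_index]
    for v in order:
        for c in tree.children[v]:
            order.append(c)

    for v in order[1:]:
        t = blen[v]
        parent_states = states[tree.parent[v]]
        child = np.empty(n, dtype=np.int16)
        if t == 0.0:
            child[:] = parent_states
        else:
            u = rng.random(n)
            for k in range(n_classes):
                mask = classes == k
                if not mask.any():
                    continue
                cum = np.cumsum(kernels.transition_matrix(k, t), axis=1)
                rows = cum[parent_states[mask]]
                child[mask] = (rows > u[mask, None]).argmax(axis=1)
        states[v] = child

    return CodonAlignment(
        taxa=list(tree.tip_names),
        codons=states[: tree.n_tips].copy(),
        site_classes=classes,
        gene=gene.gene,
    )


def concatenate_alignments(alignments: list[CodonAlignment]) -> NucleotideAlignment:
    """Concatenate genes into a nucleotide super-alignment with block
    annotation (gene id and codon position per column)."""
    if not alignments:
        raise ValueError("no alignments to concatenate")
    taxa = alignments[0].taxa
    mats, genes, poss = [], [], []
    for aln in alignments:
        if aln.taxa != taxa:
            raise ValueError("alignments must share taxa in the same order")
        nt, pos = aln.to_nucleotides()
        mats.append(nt)
        poss.append(pos)
        genes.append(np.full(nt.shape[1], aln.gene, dtype=np.int32))
    return NucleotideAlignment(
        taxa=list(taxa),
        matrix=np.concatenate(mats, axis=1),
        col_gene=np.concatenate(genes),
        col_pos=np.concatenate(poss),
    )


# -- plain-text writers ---------------------------------------------------

def write_fasta(path, taxa: list[str], sequences: list[str]) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(taxa, sequences):
            fh.write(f">{name}\n{seq}\n")


def write_phylip(path, taxa: list[str], sequences: list[str]) -> None:
    """Sequential PHYLIP with relaxed (whitespace-delimited) names."""
    with open(path, "w") as fh:
        fh.write(f" {len(taxa)} {len(sequences[0])}\n")
        for name, seq in zip(taxa, sequences):
            fh.write(f"{name}  {seq}\n")


def write_partition_file(path, aln: NucleotideAlignment) -> None:
    """RAxML-style partition file over (gene, codon-position-class) blocks.

    Positions 1+2 of a gene form one block and position 3 another, written
    as 1-based inclusive ranges with the ``\\3`` stride notation.
    """
    with open(path, "w") as fh:
        for g in np.unique(aln.col_gene):
            cols = np.flatnonzero(aln.col_gene == g)
            start, stop = cols[0] + 1, cols[-1] + 1
            fh.write(f"DNA, gene{g}_pos12 = {start}-{stop}\\3, {start + 1}-{stop}\\3\n")
            fh.write(f"DNA, gene{g}_pos3 = {start + 2}-{stop}\\3\n")
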