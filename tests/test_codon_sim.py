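import numpy as np
import pytest
from scipy.linalg import expm

from clockpart.clock_sim import GeneRealization
from clockpart.codon_sim import (
    SENSE_CODONS,
    M3Model,
    _ClassKernels,
    build_codon_rate_matrix,
    concatenate_alignments,
    conserved_gene_model,
    less_conserved_gene_model,
    normalize_mixture,
    simulate_alignment,
    write_fasta,
    write_partition_file,
    write_phylip,
)
from clockpart.trees import SpeciesTimeTree


def test_sense_codons():
    assert len(SENSE_CODONS) == 61
    assert len(set(SENSE_CODONS)) == 61
    for stop in ("TAA", "TAG", "TGA"):
        assert stop not in SENSE_CODONS
    assert SENSE_CODONS[0] == "TTT"  # TCAG ordering


def test_mixture_mean_omegas():
    assert np.isclose(conserved_gene_model().mean_omega, 0.112)
    assert np.isclose(less_conserved_gene_model().mean_omega, 0.335)


def test_rate_matrix_structure():
    pi = np.full(61, 1.0 / 61.0)
    q = build_codon_rate_matrix(2.0, 0.5, pi)
    np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)
    assert np.all(q - np.diag(np.diag(q)) >= 0)
    # only single-nucleotide changes have positive rate
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            ndiff = sum(a != b for a, b in zip(ci, cj))
            if ndiff > 1:
                assert q[i, j] == 0.0
    # detailed balance under uniform pi: symmetric off-diagonals
    np.testing.assert_allclose(q, q.T, atol=1e-12)


def test_mixture_normalization_unit_rate():
    m = conserved_gene_model()
    raw = [build_codon_rate_matrix(m.kappa, w, m.pi) for w in m.omegas]
    scaled = normalize_mixture(raw, m.probs, m.pi)
    rate = sum(
        p * float(-np.dot(m.pi, np.diag(q))) for p, q in zip(m.probs, scaled)
    )
    assert np.isclose(rate, 1.0, atol=1e-12)
    # the shared scale preserves relative class rates
    r0 = -np.dot(m.pi, np.diag(raw[0])) / -np.dot(m.pi, np.diag(raw[1]))
    r0s = -np.dot(m.pi, np.diag(scaled[0])) / -np.dot(m.pi, np.diag(scaled[1]))
    assert np.isclose(r0, r0s)


def test_transition_matrix_against_expm():
    m = conserved_gene_model()
    kern = _ClassKernels(m)
    for klass, t in ((0, 0.05), (1, 0.3), (2, 1.2)):
        p = kern.transition_matrix(klass, t)
        np.testing.assert_allclose(p, expm(kern.matrices[klass] * t), atol=1e-8)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(p >= 0)


def _two_taxon_tree():
    return SpeciesTimeTree.from_newick("(sp1,sp2)1;", {1: 1.0})


def test_simulated_identity_fraction_matches_theory(rng):
    """On a two-taxon tree the probability that both tips show the same
    codon is sum_k p_k sum_ij pi_i P_ij(t1)^(k) P_ij(t2)^(k)."""
    t = _two_taxon_tree()
    model = M3Model(n_codons=30000)
    gr = GeneRealization(
        gene=0, mu_g=0.4, branch_rates=np.array([0.4, 0.6]),
        nuc_lengths=np.array([0.4, 0.6]) * t.branch_durations(),
    )
    kern = _ClassKernels(model)
    aln = simulate_alignment(gr, model, t, rng, kernels=kern)
    same = float((aln.codons[0] == aln.codons[1]).mean())
    theory = 0.0
    for k, p in enumerate(model.probs):
        p1 = kern.transition_matrix(k, gr.codon_lengths[0])
        p2 = kern.transition_matrix(k, gr.codon_lengths[1])
        theory += p * float(np.sum(kern.pi[:, None] * p1 * p2))
    assert abs(same - theory) < 0.01


def test_zero_length_branch_copies_parent(rng):
    t = _two_taxon_tree()
    gr = GeneRealization(
        gene=0, mu_g=0.4, branch_rates=np.zeros(2), nuc_lengths=np.zeros(2)
    )
    aln = simulate_alignment(gr, M3Model(n_codons=200), t, rng)
    np.testing.assert_array_equal(aln.codons[0], aln.codons[1])


def test_to_nucleotides_and_concatenate(tree, small_replicate):
    aln, _ = small_replicate
    assert aln.matrix.shape == (9, 8 * 120 * 3)
    assert aln.matrix.dtype == np.int8
    assert set(np.unique(aln.matrix)) <= {0, 1, 2, 3}
    assert set(np.unique(aln.col_pos)) == {1, 2, 3}
    assert list(np.unique(aln.col_gene)) == list(range(8))
    # codon positions tile 1,2,3 within every gene
    first_gene = aln.col_pos[aln.col_gene == 0]
    np.testing.assert_array_equal(first_gene[:6], [1, 2, 3, 1, 2, 3])


def test_concatenate_requires_matching_taxa(rng):
    t = _two_taxon_tree()
    gr = GeneRealization(
        gene=0, mu_g=0.4, branch_rates=np.ones(2), nuc_lengths=np.ones(2) * 0.1
    )
    a = simulate_alignment(gr, M3Model(n_codons=10), t, rng)
    b = simulate_alignment(gr, M3Model(n_codons=10), t, rng)
    b.taxa = ["spX", "sp2"]
    with pytest.raises(ValueError):
        concatenate_alignments([a, b])


def test_writers(tmp_path, small_replicate):
    aln, _ = small_replicate
    seqs = aln.sequences()
    write_fasta(tmp_path / "a.fasta", aln.taxa, seqs)
    write_phylip(tmp_path / "a.phy", aln.taxa, seqs)
    write_partition_file(tmp_path / "a.partitions", aln)
    fasta = (tmp_path / "a.fasta").read_text().splitlines()
    assert fasta[0] == ">sp1"
    assert len(fasta) == 18
    phy = (tmp_path / "a.phy").read_text().splitlines()
    assert phy[0].split() == ["9", str(aln.n_cols)]
    parts = (tmp_path / "a.partitions").read_text().splitlines()
    assert len(parts) == 16  # two blocks per gene
    assert parts[0].startswith("DNA, gene0_pos12 = 1-")


def test_model_validation():
    with pytest.raises(ValueError):
        M3Model(probs=(0.5, 0.5))  # length mismatch with omegas
    with pytest.raises(ValueError):
        M3Model(omegas=(0.1, 0.2, 0.3), probs=(0.5, 0.4, 0.3))
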