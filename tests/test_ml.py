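import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from clockpart.codon_sim import NucleotideAlignment
from clockpart.ml import (
    ApproxLikelihoodSurface,
    PruningEngine,
    SubstModelConfig,
    _rate_matrix,
    discrete_gamma_rates,
    fit_branch_lengths,
    loglik_unrooted,
    read_surfaces,
    taylor_approx_loglik,
    write_surfaces,
)
from clockpart.trees import _unrooted_branch_map, rooted_to_unrooted_lengths
from helpers import quartet, simulate_hky


def random_alignment(tree, n_cols, rng):
    return NucleotideAlignment(
        taxa=list(tree.tip_names),
        matrix=rng.integers(0, 4, size=(tree.n_tips, n_cols)).astype(np.int8),
        col_gene=np.zeros(n_cols, dtype=np.int32),
        col_pos=np.ones(n_cols, dtype=np.int8),
    )


def brute_force_loglik(aln, tree, unrooted_lengths, config):
    """Enumerate internal-node states of the rooted tree; the merged
    root edge length is placed entirely on the first root child."""
    q = _rate_matrix(config, kappa=config.kappa)
    pi = np.asarray(config.freqs)
    rates = (
        discrete_gamma_rates(config.alpha, config.n_cats)
        if config.alpha is not None
        else np.ones(1)
    )
    mapping, _ = _unrooted_branch_map(tree)
    root = tree.root_index
    root_kids = tree.children[root]
    rooted = np.empty(tree.n_branches)
    for b, c in enumerate(tree.branch_child):
        if int(c) == root_kids[0]:
            rooted[b] = unrooted_lengths[0]
        elif int(c) == root_kids[1]:
            rooted[b] = 0.0
        else:
            rooted[b] = unrooted_lengths[mapping[b]]
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    branch_of = {int(c): b for b, c in enumerate(tree.branch_child)}
    total = 0.0
    for site in range(aln.n_cols):
        site_l = 0.0
        for r in rates:
            pm = {b: expm(q * r * rooted[b]) for b in range(tree.n_branches)}
            for states in itertools.product(range(4), repeat=len(internals)):
                s = {v: x for v, x in zip(internals, states)}
                for t in range(tree.n_tips):
                    s[t] = int(aln.matrix[t, site])
                term = pi[s[root]]
                for v in range(tree.n_nodes):
                    if v == root:
                        continue
                    term *= pm[branch_of[v]][s[int(tree.parent[v])], s[v]]
                site_l += term
        total += np.log(site_l / len(rates))
    return total


def test_discrete_gamma_rates():
    r = discrete_gamma_rates(0.5, 4)
    assert r.shape == (4,)
    assert np.isclose(r.mean(), 1.0)
    assert np.all(np.diff(r) > 0)
    # no rate variation in the large-shape limit
    np.testing.assert_allclose(discrete_gamma_rates(1e6, 4), 1.0, atol=1e-2)


def test_rate_matrix_scaling_and_balance():
    cfg = SubstModelConfig(kappa=3.0, freqs=(0.1, 0.2, 0.3, 0.4))
    q = _rate_matrix(cfg)
    pi = np.asarray(cfg.freqs)
    np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)
    assert np.isclose(-np.dot(pi, np.diag(q)), 1.0)
    np.testing.assert_allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)


@pytest.mark.parametrize(
    "cfg",
    [
        SubstModelConfig(kappa=1.0, alpha=None),           # Jukes-Cantor
        SubstModelConfig(kappa=2.5, alpha=0.7),            # HKY + gamma
        SubstModelConfig(kappa=4.0, freqs=(0.1, 0.2, 0.3, 0.4), alpha=1.3),
    ],
)
def test_pruning_matches_brute_force(cfg):
    t = quartet()
    rng = np.random.default_rng(7)
    aln = random_alignment(t, 12, rng)
    lengths = rng.uniform(0.02, 0.8, size=5)
    got = loglik_unrooted(aln, t, lengths, cfg)
    want = brute_force_loglik(aln, t, lengths, cfg)
    assert np.isclose(got, want, rtol=0, atol=1e-8)


def test_likelihood_invariant_to_column_order(tree, small_replicate):
    aln, _ = small_replicate
    sub = aln.columns(np.arange(600))
    cfg = SubstModelConfig()
    perm = np.random.default_rng(3).permutation(600)
    l1 = loglik_unrooted(sub, tree, np.full(15, 0.1), cfg)
    l2 = loglik_unrooted(sub.columns(perm), tree, np.full(15, 0.1), cfg)
    assert np.isclose(l1, l2, rtol=0, atol=1e-9)


def test_analytic_gradient_matches_finite_differences(tree, small_replicate):
    aln, _ = small_replicate
    sub = aln.columns(np.arange(900))
    eng = PruningEngine(sub, tree, SubstModelConfig())
    b = np.random.default_rng(11).uniform(0.02, 0.4, size=15)
    ll, g = eng.loglik_and_grad(b)
    assert np.isclose(ll, eng.loglik(b))
    h = 1e-6
    for i in range(15):
        bp, bm = b.copy(), b.copy()
        bp[i] += h
        bm[i] -= h
        fd = (eng.loglik(bp) - eng.loglik(bm)) / (2 * h)
        assert np.isclose(g[i], fd, rtol=1e-5, atol=1e-4)


def test_branch_length_recovery_at_1e5_sites():
    """MLEs recover the generating lengths within 5% at 10^5 sites.

    Uses moderate branch lengths without among-site rate variation, so
    the per-branch standard error (~1.3% relative) leaves 5% as a
    multiple-sigma bound rather than a coin flip."""
    t = quartet()
    cfg = SubstModelConfig(kappa=2.0, alpha=None)
    rng = np.random.default_rng(42)
    rooted = 0.4 * t.branch_durations()
    aln = simulate_hky(t, rooted, cfg, 100_000, rng)
    surf = fit_branch_lengths(aln, t, cfg)
    true_un = rooted_to_unrooted_lengths(t, rooted)
    np.testing.assert_allclose(surf.bhat, true_un, rtol=0.05)
    assert abs(surf.kappa - 2.0) < 0.1


def test_joint_fit_consistency_nine_taxa(tree):
    """On the full tree with gamma rates, the joint MLE stays within its
    own curvature-implied uncertainty of the truth."""
    cfg = SubstModelConfig(kappa=2.0, alpha=1.0)
    rng = np.random.default_rng(42)
    rooted = 0.5 * tree.branch_durations()
    aln = simulate_hky(tree, rooted, cfg, 100_000, rng)
    surf = fit_branch_lengths(aln, tree, cfg)
    true_un = rooted_to_unrooted_lengths(tree, rooted)
    sd = np.sqrt(np.diag(np.linalg.inv(-surf.hessian)))
    assert np.all(np.abs(surf.bhat - true_un) < 5.0 * sd + 1e-4)
    assert abs(surf.kappa - 2.0) < 0.2
    assert abs(surf.alpha - 1.0) < 0.15


def test_surface_properties(small_surface):
    s = small_surface
    assert s.converged
    # interior maximum: tiny gradient relative to curvature
    assert np.all(np.linalg.eigvalsh(s.hessian) < 0)
    np.testing.assert_allclose(s.hessian, s.hessian.T)
    step = np.linalg.solve(s.hessian, s.gradient)
    assert np.max(np.abs(step)) < 1e-3
    # the expansion equals the fitted log-likelihood at bhat
    assert np.isclose(taylor_approx_loglik(s, s.bhat), s.loglik)


def test_taylor_truncates_negative_proposals(small_surface):
    s = small_surface
    b = s.bhat.copy()
    b[3] = -0.05
    bz = s.bhat.copy()
    bz[3] = 0.0
    assert taylor_approx_loglik(s, b) == taylor_approx_loglik(s, bz)


def test_surface_round_trip(tmp_path, small_surface):
    path = tmp_path / "surfaces.json"
    write_surfaces(path, [small_surface], meta={"replicate": 0})
    back = read_surfaces(path)
    assert len(back) == 1
    np.testing.assert_allclose(back[0].bhat, small_surface.bhat)
    np.testing.assert_allclose(back[0].hessian, small_surface.hessian)
    assert back[0].loglik == small_surface.loglik
    assert back[0].partition == small_surface.partition


def test_input_validation(tree, small_replicate):
    aln, _ = small_replicate
    with pytest.raises(ValueError):
        SubstModelConfig(family="JTT")
    with pytest.raises(ValueError):
        SubstModelConfig(freqs=(0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        loglik_unrooted(aln, tree, np.ones(7), SubstModelConfig())
    with pytest.raises(ValueError):
        loglik_unrooted(aln, tree, -np.ones(15), SubstModelConfig())
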