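"""Shared test utilities (oracle simulators and small trees)."""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from clockpart.codon_sim import NucleotideAlignment
from clockpart.ml import SubstModelConfig, _rate_matrix, discrete_gamma_rates
from clockpart.trees import SpeciesTimeTree

QUARTET_NEWICK = "((sp1,sp2)2,(sp3,sp4)3)1;"
QUARTET_AGES = {1: 1.0, 2: 0.4, 3: 0.5}


def quartet() -> SpeciesTimeTree:
    return SpeciesTimeTree.from_newick(QUARTET_NEWICK, QUARTET_AGES)


def planted_block_vectors(rng, n_per_group=8, n_branches=15):
    """Branch-length vectors for two planted groups with distinct
    per-branch patterns and arbitrary per-block scale factors."""
    base_a = rng.uniform(0.2, 1.0, size=n_branches)
    base_b = base_a[::-1] * rng.uniform(0.5, 2.0, size=n_branches)
    vecs = []
    for _ in range(n_per_group):
        vecs.append(base_a * rng.uniform(0.5, 2.0) * rng.normal(1.0, 0.02, n_branches))
    for _ in range(n_per_group):
        vecs.append(base_b * rng.uniform(0.5, 2.0) * rng.normal(1.0, 0.02, n_branches))
    return np.abs(np.stack(vecs))


def clock_like_block_vectors(rng, n_blocks=12, n_branches=15):
    """Branch-length vectors that differ only by overall rate."""
    base = rng.uniform(0.2, 1.0, size=n_branches)
    return np.abs(
        np.stack(
            [
                base * rng.uniform(0.3, 3.0) * rng.normal(1.0, 0.01, n_branches)
                for _ in range(n_blocks)
            ]
        )
    )


def simulate_hky(
    tree: SpeciesTimeTree,
    rooted_lengths: np.ndarray,
    cfg: SubstModelConfig,
    n_sites: int,
    rng: np.random.Generator,
    col_gene: int = 0,
) -> NucleotideAlignment:
    """Direct nucleotide simulation under HKY + discrete gamma, using
    scipy's expm as an independent transition-matrix oracle."""
    q = _rate_matrix(cfg)
    pi = np.asarray(cfg.freqs)
    if cfg.alpha is not None:
        rates = discrete_gamma_rates(cfg.alpha, cfg.n_cats)
    else:
        rates = np.ones(1)
    n_cats = rates.size
    cats = rng.integers(0, n_cats, size=n_sites)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    states[tree.root_index] = rng.choice(4, size=n_sites, p=pi)
    order = [tree.root_index]
    for v in order:
        order.extend(tree.children[v])
    branch_of = {int(c): b for b, c in enumerate(tree.branch_child)}
    for v in order[1:]:
        t = rooted_lengths[branch_of[v]]
        parent_states = states[int(tree.parent[v])]
        u = rng.random(n_sites)
        out = np.empty(n_sites, dtype=np.int8)
        for c in range(n_cats):
            mask = cats == c
            cum = np.cumsum(expm(q * rates[c] * t), axis=1)
            out[mask] = (cum[parent_states[mask]] > u[mask, None]).argmax(axis=1)
        states[v] = out
    return NucleotideAlignment(
        taxa=list(tree.tip_names),
        matrix=states[: tree.n_tips].copy(),
        col_gene=np.full(n_sites, col_gene, dtype=np.int32),
        col_pos=np.tile(np.array([1, 2, 3], dtype=np.int8), (n_sites + 2) // 3)[:n_sites],
    )
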