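"""Partition schemes over (gene x codon-position) data blocks.

Blocks are the atoms: codon positions 1+2 of a gene form one block and
position 3 another.  Six scheme families are supported:

* fixed schemes -- concatenation (C), codon position (CP), gene (G),
  gene-and-codon-position (GCP);
* greedy BIC merging of blocks under a linked proportional-branch-length
  model (PF-style);
* clustering of blocks by a scaled branch-length distance with the gap
  statistic choosing the number of clusters and k-medoids (PAM) assigning
  blocks (CS-style).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .codon_sim import NucleotideAlignment
from .ml import PruningEngine, SubstModelConfig
from .trees import SpeciesTimeTree

__all__ = [
    "DataBlock",
    "PartitionScheme",
    "make_blocks",
    "fixed_scheme",
    "bic_greedy_merge",
    "sbsd_min_distance",
    "sbsd_distance_matrix",
    "k_medoids",
    "gap_statistic_cluster",
    "write_scheme_json",
    "read_scheme_json",
]


@dataclass(frozen=True)
class DataBlock:
    """One gene x codon-position-class block of alignment columns."""

    gene: int
    pos_class: str               # "12" or "3"
    columns: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.pos_class not in ("12", "3"):
            raise ValueError("pos_class must be '12' or '3'")


@dataclass
class PartitionScheme:
    """Assignment of data blocks to partitions.

    ``assignment[i]`` is the 1-based partition id of block ``i``; ids are
    contiguous from 1.  Every block is assigned exactly once, so a scheme
    is a set partition of the blocks by construction.
    """

    label: str
    assignment: list[int]

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("partition ids must be contiguous from 1")

    @property
    def n_partitions(self) -> int:
        return max(self.assignment)

    @property
    def n_blocks(self) -> int:
        return len(self.assignment)

    def blocks_of(self, partition_id: int) -> list[int]:
        return [i for i, p in enumerate(self.assignment) if p == partition_id]

    def partition_columns(
        self, blocks: list[DataBlock]
    ) -> list[np.ndarray]:
        """Column index set of each partition (1..n_partitions)."""
        if len(blocks) != self.n_blocks:
            raise ValueError("scheme and block list sizes differ")
        out = []
        for pid in range(1, self.n_partitions + 1):
            cols = np.concatenate(
                [blocks[i].columns for i in self.blocks_of(pid)]
            )
            out.append(np.sort(cols))
        return out


def make_blocks(aln: NucleotideAlignment) -> list[DataBlock]:
    """Split a super-alignment into (gene, codon-position-class) blocks,
    ordered gene0:pos12, gene0:pos3, gene1:pos12, ..."""
    blocks = []
    for g in np.unique(aln.col_gene):
        in_gene = aln.col_gene == g
        cols12 = np.flatnonzero(in_gene & (aln.col_pos != 3))
        cols3 = np.flatnonzero(in_gene & (aln.col_pos == 3))
        blocks.append(DataBlock(gene=int(g), pos_class="12", columns=cols12))
        blocks.append(DataBlock(gene=int(g), pos_class="3", columns=cols3))
    return blocks


def fixed_scheme(kind: str, n_genes: int) -> PartitionScheme:
    """Fixed schemes over the 2 x n_genes blocks.

    C: one partition; CP: positions 1+2 pooled vs position 3 pooled;
    G: one partition per gene; GCP: every block its own partition.
    """
    if kind not in ("C", "CP", "G", "GCP"):
        raise ValueError(f"unknown fixed scheme kind: {kind!r}")
    n_blocks = 2 * n_genes
    if kind == "C":
        assignment = [1] * n_blocks
    elif kind == "CP":
        assignment = [1 if i % 2 == 0 else 2 for i in range(n_blocks)]
    elif kind == "G":
        assignment = [i // 2 + 1 for i in range(n_blocks)]
    else:
        assignment = [i + 1 for i in range(n_blocks)]
    return PartitionScheme(label=kind, assignment=assignment)


# ---------------------------------------------------------------------------
# PF-style greedy BIC merging
# ---------------------------------------------------------------------------

def _empirical_freqs(matrix: np.ndarray) -> tuple[float, float, float, float]:
    counts = np.bincount(matrix.ravel(), minlength=4).astype(float)
    counts = np.maximum(counts, 1.0)
    f = counts / counts.sum()
    return tuple(f)


def _fit_scaled_block(
    aln: NucleotideAlignment,
    cols: np.ndarray,
    tree: SpeciesTimeTree,
    shared_bl: np.ndarray,
    config: SubstModelConfig,
) -> float:
    """Max log-likelihood of one (merged) block under the linked model:
    branch lengths = c * shared_bl with free (c, kappa, alpha) and
    empirical base frequencies."""
    sub = aln.columns(cols)
    cfg = SubstModelConfig(
        family="HKY85",
        kappa=config.kappa,
        freqs=_empirical_freqs(sub.matrix),
        alpha=config.alpha if config.alpha is not None else 1.0,
        n_cats=config.n_cats,
    )
    engine = PruningEngine(sub, tree, cfg)

    def nll(theta):
        c, kappa, alpha = np.exp(theta)
        return -engine.loglik(c * shared_bl, kappa=kappa, alpha=alpha)

    res = minimize(
        nll,
        np.log([1.0, cfg.kappa, cfg.alpha]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
    )
    return float(-res.fun)


# parameters counted per partition under the linked model:
# rate multiplier + kappa + 3 free base frequencies + gamma shape
_PARAMS_PER_PARTITION = 6


def bic_greedy_merge(
    blocks: list[DataBlock],
    alignment: NucleotideAlignment,
    tree: SpeciesTimeTree,
    config: SubstModelConfig | None = None,
    shared_bl: np.ndarray | None = None,
    max_rounds: int | None = None,
    label: str = "PF",
) -> PartitionScheme:
    """Greedy BIC merging of data blocks (PartitionFinder-style).

    Starts from every block separate and repeatedly applies the single
    merge that most improves the total BIC under the linked
    proportional-branch-length model: one shared branch-length set
    (estimated once on the full alignment and held fixed), with a free
    rate multiplier, kappa, gamma shape and empirical base frequencies
    per partition.  Stops when no merge improves BIC.  BIC uses
    N = total alignment columns and counts the shared branch lengths once
    plus 6 parameters per partition.
    """
    if not blocks:
        raise ValueError("no data blocks given")
    if config is None:
        config = SubstModelConfig()
    if shared_bl is None:
        from .ml import fit_branch_lengths

        surf = fit_branch_lengths(alignment, tree, config)
        shared_bl = surf.bhat

    n_total = alignment.n_cols
    groups: list[list[int]] = [[i] for i in range(len(blocks))]

    def group_loglik(group: list[int]) -> float:
        cols = np.sort(np.concatenate([blocks[i].columns for i in group]))
        return _fit_scaled_block(alignment, cols, tree, shared_bl, config)

    loglik = {tuple(g): group_loglik(g) for g in groups}

    def total_bic() -> float:
        ll = sum(loglik[tuple(g)] for g in groups)
        k = (2 * tree.n_tips - 3) + _PARAMS_PER_PARTITION * len(groups)
        return -2.0 * ll + k * math.log(n_total)

    current = total_bic()
    rounds = 0
    while len(groups) > 1:
        if max_rounds is not None and rounds >= max_rounds:
            break
        rounds += 1
        best = None
        for a, b in itertools.combinations(range(len(groups)), 2):
            merged = sorted(groups[a] + groups[b])
            key = tuple(merged)
            if key not in loglik:
                loglik[key] = group_loglik(merged)
            ll = (
                sum(
                    loglik[tuple(g)]
                    for i, g in enumerate(groups)
                    if i not in (a, b)
                )
                + loglik[key]
            )
            k = (2 * tree.n_tips - 3) + _PARAMS_PER_PARTITION * (len(groups) - 1)
            bic = -2.0 * ll + k * math.log(n_total)
            if bic < current and (best is None or bic < best[0]):
                best = (bic, a, b, merged)
        if best is None:
            break
        _, a, b, merged = best
        groups = [g for i, g in enumerate(groups) if i not in (a, b)]
        groups.append(merged)
        current = best[0]

    assignment = [0] * len(blocks)
    for pid, g in enumerate(sorted(groups, key=min), start=1):
        for i in g:
            assignment[i] = pid
    return PartitionScheme(label=label, assignment=assignment)


# ---------------------------------------------------------------------------
# CS-style clustering: scaled branch-length distance + gap statistic + PAM
# ---------------------------------------------------------------------------

def sbsd_min_distance(bl_a, bl_b) -> float:
    """Scale-minimized branch-length distance between two blocks.

    For each direction, the root-sum-of-squares difference between one
    vector and the optimally scaled other (scale s >= 0, least squares),
    normalized by the norm of the first; the distance is the maximum of
    the two directions, so it is symmetric, non-negative and zero exactly
    when the vectors are proportional.
    """
    a = np.asarray(bl_a, dtype=float)
    b = np.asarray(bl_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("branch-length vectors must have equal length")

    def directed(x, y) -> float:
        nx = float(np.linalg.norm(x))
        if nx == 0:
            return 0.0 if float(np.linalg.norm(y)) == 0 else 1.0
        yy = float(np.dot(y, y))
        s = max(float(np.dot(x, y)) / yy, 0.0) if yy > 0 else 0.0
        return float(np.linalg.norm(x - s * y)) / nx

    return max(directed(a, b), directed(b, a))


def sbsd_distance_matrix(bl_vectors: np.ndarray) -> np.ndarray:
    """Pairwise scaled branch-length distances, (n_blocks, n_blocks)."""
    bl = np.asarray(bl_vectors, dtype=float)
    n = bl.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sbsd_min_distance(bl[i], bl[j])
    return d


def k_medoids(
    dist: np.ndarray, k: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PAM (build + swap) k-medoids on a distance matrix.

    Returns (medoid indices, assignment of each point to 0..k-1).
    Deterministic: the build phase is greedy and the swap phase takes the
    best improving swap until none exists.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if not (1 <= k <= n):
        raise ValueError("need 1 <= k <= n points")
    # build
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gains = np.array(
            [np.maximum(cur - d[:, j], 0.0).sum() if j not in medoids else -1.0
             for j in range(n)]
        )
        medoids.append(int(np.argmax(gains)))
    # swap
    def cost(meds):
        return float(d[:, meds].min(axis=1).sum())

    best_cost = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, medoids = c, trial
                    improved = True
    medoids_arr = np.asarray(sorted(medoids), dtype=int)
    assign = np.argmin(d[:, medoids_arr], axis=1)
    return medoids_arr, assign


def _within_dispersion(dist: np.ndarray, assign: np.ndarray) -> float:
    """Tibshirani-style pooled within-cluster dispersion."""
    w = 0.0
    for c in np.unique(assign):
        idx = np.flatnonzero(assign == c)
        if idx.size > 1:
            w += dist[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return w


def _cmds_embedding(dist: np.ndarray, max_dim: int = 5) -> np.ndarray:
    """Classical multidimensional scaling of a distance matrix."""
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    lam, vec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    keep = lam > max(1e-10, 1e-8 * lam.max(initial=0.0))
    lam, vec = lam[keep][:max_dim], vec[:, keep][:, :max_dim]
    if lam.size == 0:
        return np.zeros((n, 1))
    return vec * np.sqrt(lam)[None, :]


def gap_statistic_cluster(
    distance_matrix: np.ndarray,
    max_k: int = 10,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
    label: str = "CS",
) -> PartitionScheme:
    """Choose the number of block clusters by the gap statistic and
    assign blocks by k-medoids.

    For k = 1..max_k the within-cluster dispersion W_k of the PAM
    clustering is compared with its expectation under a null of points
    drawn uniformly in the bounding box of a classical MDS embedding of
    the distance matrix (``n_boot`` bootstrap replicates).  The selected k
    is the smallest with Gap(k) >= Gap(k+1) - s.e.(k+1) (one-standard-
    error rule); degenerate all-zero distance matrices yield k = 1.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if rng is None:
        rng = np.random.default_rng(0)
    n = d.shape[0]
    max_k = min(max_k, n)
    if n == 1 or float(d.max()) <= 1e-12:
        return PartitionScheme(label=label, assignment=[1] * n)

    emb = _cmds_embedding(d)
    lo, hi = emb.min(axis=0), emb.max(axis=0)

    log_w = np.empty(max_k)
    assigns = []
    for k in range(1, max_k + 1):
        _, assign = k_medoids(d, k)
        assigns.append(assign)
        log_w[k - 1] = math.log(max(_within_dispersion(d, assign), 1e-12))

    log_w_null = np.empty((n_boot, max_k))
    for b in range(n_boot):
        pts = rng.uniform(lo, hi, size=emb.shape)
        dd = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        for k in range(1, max_k + 1):
            _, assign = k_medoids(dd, k)
            log_w_null[b, k - 1] = math.log(
                max(_within_dispersion(dd, assign), 1e-12)
            )

    gap = log_w_null.mean(axis=0) - log_w
    se = log_w_null.std(axis=0, ddof=0) * math.sqrt(1.0 + 1.0 / n_boot)

    chosen = max_k
    for k in range(1, max_k):
        if gap[k - 1] >= gap[k] - se[k]:
            chosen = k
            break

    assign = assigns[chosen - 1]
    # relabel clusters contiguously by first appearance
    remap: dict[int, int] = {}
    assignment = []
    for a in assign:
        if a not in remap:
            remap[a] = len(remap) + 1
        assignment.append(remap[a])
    return PartitionScheme(label=label, assignment=assignment)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_scheme_json(path, scheme: PartitionScheme, blocks: list[DataBlock] | None = None) -> None:
    payload = {
        "label": scheme.label,
        "n_partitions": scheme.n_partitions,
        "assignment": list(scheme.assignment),
    }
    if blocks is not None:
        payload["blocks"] = [
            {"gene": b.gene, "pos_class": b.pos_class, "n_columns": int(b.columns.size)}
            for b in blocks
        ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_scheme_json(path) -> PartitionScheme:
    with open(path) as fh:
        payload = json.load(fh)
    return PartitionScheme(
        label=payload["label"], assignment=list(payload["assignment"])
    )
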