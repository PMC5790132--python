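"""Maximum-likelihood branch lengths and the approximate likelihood surface.

Branch lengths are estimated per partition on the fixed unrooted topology
under HKY85+Gamma4 (discrete gamma, 4 equal-weight categories, category
means).  The fitted log-likelihood, its gradient and its Hessian at the
MLE define a second-order Taylor surface which the dating MCMC evaluates
in place of the exact likelihood; that quadratic surface is the standard
approximate-likelihood device for divergence-time estimation.

The likelihood itself is Felsenstein pruning over compressed site
patterns, with an analytic gradient with respect to branch lengths (a
postorder/preorder two-pass).  The stored surface derivatives use central
finite differences (gradient of the log-likelihood; Hessian differencing
the analytic gradient), which doubles as a cross-check of the analytic
gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from .codon_sim import NucleotideAlignment
from .trees import SpeciesTimeTree, _unrooted_branch_map

__all__ = [
    "SubstModelConfig",
    "ApproxLikelihoodSurface",
    "PruningEngine",
    "loglik_unrooted",
    "fit_branch_lengths",
    "taylor_approx_loglik",
    "write_surfaces",
    "read_surfaces",
]


@dataclass(frozen=True)
class SubstModelConfig:
    """Nucleotide substitution model: HKY85 (or GTR) + discrete gamma.

    ``alpha`` is the gamma shape of among-site rate variation with
    ``n_cats`` equal-probability categories (category means); ``alpha=None``
    disables rate variation.  Frequencies are in ACGT order.
    """

    family: str = "HKY85"
    kappa: float = 2.0
    exchangeabilities: tuple[float, ...] | None = None  # GTR: AC,AG,AT,CG,CT,GT
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha: float | None = 1.0
    n_cats: int = 4

    def __post_init__(self) -> None:
        if self.family not in ("HKY85", "GTR"):
            raise ValueError("model family must be HKY85 or GTR")
        if abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")


@dataclass
class ApproxLikelihoodSurface:
    """Per-partition quadratic expansion of the log-likelihood.

    ``bhat`` holds the 2s-3 branch-length MLEs on the unrooted topology
    (edge 0 is the branch into which the two root-adjacent branches of the
    rooted tree collapse), with the gradient and symmetric Hessian at
    ``bhat`` and the maximized log-likelihood.
    """

    partition: int
    bhat: np.ndarray
    gradient: np.ndarray
    hessian: np.ndarray
    loglik: float
    kappa: float = np.nan
    alpha: float = np.nan
    converged: bool = True
    message: str = ""


def discrete_gamma_rates(alpha: float, n_cats: int = 4) -> np.ndarray:
    """Mean rates of ``n_cats`` equal-probability gamma(alpha, alpha) bins."""
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, n_cats + 1), alpha, scale=1.0 / alpha)
    upper = gamma_dist.cdf(edges, alpha + 1, scale=1.0 / alpha)
    rates = n_cats * np.diff(upper)
    return rates / rates.mean()


def _rate_matrix(config: SubstModelConfig, kappa: float | None = None) -> np.ndarray:
    """Reversible Q (ACGT order), scaled to one expected change per unit time."""
    pi = np.asarray(config.freqs, dtype=float)
    if config.family == "HKY85":
        k = config.kappa if kappa is None else kappa
        ex = np.ones((4, 4))
        ex[0, 2] = ex[2, 0] = k  # A<->G
        ex[1, 3] = ex[3, 1] = k  # C<->T
    else:
        ac, ag, at, cg, ct, gt = config.exchangeabilities
        ex = np.array(
            [[0, ac, ag, at], [ac, 0, cg, ct], [ag, cg, 0, gt], [at, ct, gt, 0]],
            dtype=float,
        )
    q = ex * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    return q / scale


class PruningEngine:
    """Pruning likelihood for one partition on a fixed unrooted topology.

    The unrooted tree is traversed with the first root child of the rooted
    reference as virtual root; by reversibility the likelihood is invariant
    to this choice.  Site patterns are compressed once at construction.
    """

    def __init__(
        self,
        alignment: NucleotideAlignment,
        tree: SpeciesTimeTree,
        config: SubstModelConfig,
    ):
        if alignment.taxa != tree.tip_names:
            raise ValueError("alignment taxa must match tree tips (same order)")
        self.tree = tree
        self.config = config
        self.n_edges = tree.n_branches - 1

        mat = np.ascontiguousarray(alignment.matrix, dtype=np.int8)
        cols = mat.T.copy().view([("", np.int8)] * mat.shape[0]).ravel()
        _, first, counts = np.unique(cols, return_index=True, return_counts=True)
        self.patterns = mat[:, first]
        self.weights = counts.astype(float)
        self.n_patterns = self.patterns.shape[1]
        self.n_sites = alignment.n_cols

        # pruning structure: re-hang the second root child under the first
        mapping, edges = _unrooted_branch_map(tree)
        root_kids = tree.children[tree.root_index]
        self.vroot = root_kids[0]
        children = [list(c) for c in tree.children]
        children[self.vroot] = list(children[self.vroot]) + [root_kids[1]]
        parent = {}
        edge_of = {}
        for e, (u, v) in enumerate(edges):
            if e == 0:
                parent[root_kids[1]] = self.vroot
                edge_of[root_kids[1]] = 0
            else:
                parent[v] = u
                edge_of[v] = e
        post: list[int] = []
        stack = [self.vroot]
        while stack:
            v = stack.pop()
            post.append(v)
            stack.extend(children[v])
        post = post[::-1]  # children before parents
        self.children_pruned = children
        self.parent_pruned = parent
        self.edge_of = edge_of
        self.postorder = [v for v in post]
        self.preorder = post[::-1]

    # -- transition matrices ---------------------------------------------

    def _decompose(self, kappa: float):
        q = _rate_matrix(self.config, kappa=kappa)
        pi = np.asarray(self.config.freqs, dtype=float)
        sq = np.sqrt(pi)
        sym = (sq[:, None] * q) / sq[None, :]
        lam, vec = np.linalg.eigh((sym + sym.T) / 2.0)
        left = vec.T * sq[None, :]        # rows: V^T D^{1/2}
        right = vec / sq[:, None]         # D^{-1/2} V
        return q, lam, right, left

    def _transition_mats(self, lengths, rates, lam, right, left) -> np.ndarray:
        """P matrices, shape (n_edges, n_cats, 4, 4)."""
        t = np.asarray(lengths)[:, None] * np.asarray(rates)[None, :]
        expl = np.exp(t[:, :, None] * lam[None, None, :])
        return np.einsum("ij,ecj,jk->ecik", right, expl, left, optimize=True)

    # -- likelihood ------------------------------------------------------

    def _site_likelihoods(self, pmats: np.ndarray) -> np.ndarray:
        """Per-pattern likelihoods averaged over rate categories; also
        caches per-category messages and conditional vectors (lists over
        categories of (n_patterns, 4) arrays) for the gradient pass."""
        n_cats = pmats.shape[1]
        pi = np.asarray(self.config.freqs)
        msg: dict[int, list[np.ndarray]] = {}
        clv: dict[int, list[np.ndarray]] = {}
        f = np.zeros(self.n_patterns)
        for c in range(n_cats):
            for v in self.postorder:
                e = self.edge_of.get(v)
                if not self.children_pruned[v]:
                    pt = np.ascontiguousarray(pmats[e, c].T)
                    msg.setdefault(v, []).append(pt[self.patterns[v]])
                    continue
                parts = [msg[k][c] for k in self.children_pruned[v]]
                out = parts[0] * parts[1]
                for extra in parts[2:]:
                    out *= extra
                clv.setdefault(v, []).append(out)
                if v != self.vroot:
                    msg.setdefault(v, []).append(out @ pmats[e, c].T)
            f += clv[self.vroot][c] @ pi
        self._msg, self._clv = msg, clv
        return f / n_cats  # equal-weight categories

    def loglik(self, lengths: np.ndarray, kappa: float | None = None,
               alpha: float | None = None) -> float:
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (self.n_edges,):
            raise ValueError(f"expected {self.n_edges} branch lengths")
        if np.any(lengths < 0):
            raise ValueError("branch lengths must be non-negative")
        kappa = self.config.kappa if kappa is None else kappa
        alpha = self.config.alpha if alpha is None else alpha
        rates = (
            discrete_gamma_rates(alpha, self.config.n_cats)
            if alpha is not None
            else np.ones(1)
        )
        q, lam, right, left = self._decompose(kappa)
        pmats = self._transition_mats(lengths, rates, lam, right, left)
        site = self._site_likelihoods(pmats)
        return float(np.dot(self.weights, np.log(site)))

    def loglik_and_grad(
        self, lengths: np.ndarray, kappa: float | None = None,
        alpha: float | None = None,
    ) -> tuple[float, np.ndarray]:
        """Log-likelihood and its analytic gradient wrt branch lengths."""
        lengths = np.asarray(lengths, dtype=float)
        kappa = self.config.kappa if kappa is None else kappa
        alpha = self.config.alpha if alpha is None else alpha
        rates = (
            discrete_gamma_rates(alpha, self.config.n_cats)
            if alpha is not None
            else np.ones(1)
        )
        q, lam, right, left = self._decompose(kappa)
        pmats = self._transition_mats(lengths, rates, lam, right, left)
        site = self._site_likelihoods(pmats)  # fills _msg/_clv
        msg, clv = self._msg, self._clv
        pi = np.asarray(self.config.freqs)
        n_cats = len(rates)

        grad = np.zeros(self.n_edges)
        inv_site = self.weights / (site * n_cats)
        for c in range(n_cats):
            # outside (preorder) partials: U[v] = partial at the parent end
            # of v's edge, excluding v's own subtree
            U: dict[int, np.ndarray] = {}
            for v in self.preorder:
                kids = self.children_pruned[v]
                if not kids:
                    continue
                if v == self.vroot:
                    base = np.broadcast_to(pi, (self.n_patterns, 4))
                else:
                    base = U[v] @ pmats[self.edge_of[v], c]
                    # base is the outside partial at v itself
                if len(kids) == 1:
                    U[kids[0]] = np.asarray(base)
                else:
                    msgs = [msg[k][c] for k in kids]
                    for i, k in enumerate(kids):
                        rest = None
                        for j, m in enumerate(msgs):
                            if j == i:
                                continue
                            rest = m if rest is None else rest * m
                        U[k] = base * rest

            for v, e in self.edge_of.items():
                qp = (q @ pmats[e, c]) * rates[c]
                if v in clv:
                    dmsg = clv[v][c] @ qp.T
                else:  # tip: one-hot conditional, gather rows of qp^T
                    dmsg = np.ascontiguousarray(qp.T)[self.patterns[v]]
                df = np.einsum("ni,ni->n", U[v], dmsg)
                grad[e] += float(np.dot(inv_site, df))

        return float(np.dot(self.weights, np.log(site))), grad


def loglik_unrooted(
    alignment_partition: NucleotideAlignment,
    tree: SpeciesTimeTree,
    branch_lengths: np.ndarray,
    config: SubstModelConfig,
) -> float:
    """Felsenstein-pruning log-likelihood on the unrooted topology."""
    engine = PruningEngine(alignment_partition, tree, config)
    return engine.loglik(np.asarray(branch_lengths, dtype=float))


_FD_REL = 1e-4


def _fd_step(b: np.ndarray) -> np.ndarray:
    return _FD_REL * np.maximum(b, 0.01)


def fit_branch_lengths(
    alignment_partition: NucleotideAlignment,
    tree: SpeciesTimeTree,
    config: SubstModelConfig,
    partition: int = 0,
    estimate_kappa: bool = True,
    estimate_alpha: bool = True,
    b0: np.ndarray | None = None,
) -> ApproxLikelihoodSurface:
    """Maximize branch lengths (and optionally kappa, alpha), then expand.

    Branch lengths are optimized jointly with the substitution parameters
    by L-BFGS-B (analytic branch-length gradient, finite-difference
    gradient for kappa and alpha on the log scale).  The surface gradient
    is central finite differences of the log-likelihood and the Hessian
    central differences of the analytic gradient, both at the MLE with
    kappa and alpha held fixed; the Hessian is symmetrized.
    """
    if tree.n_tips < 4:
        raise ValueError("need >= 4 taxa for a nontrivial unrooted tree")
    # For long alignments, profile kappa and alpha on a deterministic
    # column stride first (their estimates stabilize within a few thousand
    # columns), then optimize branch lengths alone with the analytic
    # gradient on the full data.
    n_cols = alignment_partition.n_cols
    if (estimate_kappa or estimate_alpha) and n_cols > 20_000 and b0 is None:
        step = int(np.ceil(n_cols / 4000))
        stage = fit_branch_lengths(
            alignment_partition.columns(np.arange(0, n_cols, step)),
            tree, config,
            estimate_kappa=estimate_kappa, estimate_alpha=estimate_alpha,
        )
        from dataclasses import replace as _replace
        staged = _replace(
            config,
            kappa=stage.kappa,
            alpha=stage.alpha if np.isfinite(stage.alpha) else config.alpha,
        )
        return fit_branch_lengths(
            alignment_partition, tree, staged, partition=partition,
            estimate_kappa=False, estimate_alpha=False, b0=stage.bhat,
        )
    engine = PruningEngine(alignment_partition, tree, config)
    ne = engine.n_edges
    if b0 is None:
        b0 = np.full(ne, 0.1)

    free_k = estimate_kappa and config.family == "HKY85"
    free_a = estimate_alpha and config.alpha is not None

    def unpack(theta):
        b = theta[:ne]
        i = ne
        kappa = np.exp(theta[i]) if free_k else None
        i += free_k
        alpha = np.exp(theta[i]) if free_a else None
        return b, kappa, alpha

    def negloglik_grad(theta):
        b, kappa, alpha = unpack(theta)
        ll, gb = engine.loglik_and_grad(b, kappa=kappa, alpha=alpha)
        extra = []
        h = 1e-4
        if free_k:
            lk = np.log(kappa)
            dp = engine.loglik(b, kappa=np.exp(lk + h), alpha=alpha)
            dm = engine.loglik(b, kappa=np.exp(lk - h), alpha=alpha)
            extra.append((dp - dm) / (2 * h))
        if free_a:
            la = np.log(alpha)
            dp = engine.loglik(b, kappa=kappa, alpha=np.exp(la + h))
            dm = engine.loglik(b, kappa=kappa, alpha=np.exp(la - h))
            extra.append((dp - dm) / (2 * h))
        return -ll, -np.concatenate([gb, np.asarray(extra)])

    theta0 = list(b0)
    if free_k:
        theta0.append(np.log(config.kappa))
    if free_a:
        theta0.append(np.log(config.alpha))
    bounds = [(1e-6, 20.0)] * ne
    if free_k:
        bounds.append((np.log(0.05), np.log(200.0)))
    if free_a:
        bounds.append((np.log(0.02), np.log(1e5)))

    res = minimize(
        negloglik_grad,
        np.asarray(theta0, dtype=float),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-6},
    )
    bhat, kappa_hat, alpha_hat = unpack(res.x)
    bhat = np.asarray(bhat, dtype=float)
    kappa_val = kappa_hat if kappa_hat is not None else config.kappa
    alpha_val = alpha_hat if alpha_hat is not None else config.alpha

    # surface derivatives at the MLE, substitution parameters fixed
    step = _fd_step(bhat)
    grad_fd = np.empty(ne)
    for i in range(ne):
        bp, bm = bhat.copy(), bhat.copy()
        bp[i] += step[i]
        bm[i] = max(bm[i] - step[i], 1e-9)
        lp = engine.loglik(bp, kappa=kappa_val, alpha=alpha_val)
        lm = engine.loglik(bm, kappa=kappa_val, alpha=alpha_val)
        grad_fd[i] = (lp - lm) / (bp[i] - bm[i])

    hess = np.empty((ne, ne))
    for i in range(ne):
        bp, bm = bhat.copy(), bhat.copy()
        bp[i] += step[i]
        bm[i] = max(bm[i] - step[i], 1e-9)
        _, gp = engine.loglik_and_grad(bp, kappa=kappa_val, alpha=alpha_val)
        _, gm = engine.loglik_and_grad(bm, kappa=kappa_val, alpha=alpha_val)
        hess[i] = (gp - gm) / (bp[i] - bm[i])
    hess = (hess + hess.T) / 2.0

    return ApproxLikelihoodSurface(
        partition=partition,
        bhat=bhat,
        gradient=grad_fd,
        hessian=hess,
        loglik=float(-res.fun),
        kappa=float(kappa_val),
        alpha=float(alpha_val) if alpha_val is not None else np.nan,
        converged=bool(res.success),
        message=str(res.message),
    )


def taylor_approx_loglik(
    surface: ApproxLikelihoodSurface, proposed_lengths: np.ndarray
) -> float:
    """Second-order expansion l(b) = l(bhat) + g'd + d'Hd/2, d = b - bhat.

    Proposals below zero are evaluated at the truncated boundary (b = 0),
    mirroring the raw-scale expansion used for dating.
    """
    b = np.asarray(proposed_lengths, dtype=float)
    if b.shape != surface.bhat.shape:
        raise ValueError("dimension mismatch with the fitted surface")
    d = np.maximum(b, 0.0) - surface.bhat
    return float(
        surface.loglik
        + surface.gradient @ d
        + 0.5 * d @ surface.hessian @ d
    )


# -- serialization (in.BV-like bundle, JSON) ------------------------------

def write_surfaces(path, surfaces: list[ApproxLikelihoodSurface], meta: dict | None = None) -> None:
    payload = {
        "meta": meta or {},
        "surfaces": [
            {
                "partition": s.partition,
                "bhat": s.bhat.tolist(),
                "gradient": s.gradient.tolist(),
                "hessian": s.hessian.tolist(),
                "loglik": s.loglik,
                "kappa": s.kappa,
                "alpha": s.alpha,
                "converged": s.converged,
            }
            for s in surfaces
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_surfaces(path) -> list[ApproxLikelihoodSurface]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        ApproxLikelihoodSurface(
            partition=d["partition"],
            bhat=np.asarray(d["bhat"]),
            gradient=np.asarray(d["gradient"]),
            hessian=np.asarray(d["hessian"]),
            loglik=d["loglik"],
            kappa=d.get("kappa", np.nan),
            alpha=d.get("alpha", np.nan),
            converged=d.get("converged", True),
        )
        for d in payload["surfaces"]
    ]
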