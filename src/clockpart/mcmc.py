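"""Bayesian divergence-time MCMC with approximate likelihood.

The model follows the standard relaxed-clock dating setup: node ages get
a prior built from soft-bound fossil calibrations combined with a
birth-death sampling kernel (birth = death = 1, sampling fraction 0 gives
a uniform kernel, under which non-calibrated ages are conditionally
uniform subject to the tree's partial order); locus rates get a
gamma-Dirichlet prior (gamma on the mean rate across loci, uniform
Dirichlet apportionment); branch rates follow either the independent-rates
(IR) log-normal model or the autocorrelated-rates (AR) geometric Brownian
motion.  The sequence likelihood of each partition is the second-order
Taylor surface from :mod:`clockpart.ml`, so one likelihood evaluation is a
quadratic form in the proposed branch lengths.

Sampling is Metropolis-within-Gibbs: sliding-window moves on node ages, a
whole-tree time/rate rescaling move (which leaves branch lengths, hence
the likelihood, unchanged and mixes the time-rate confounding direction),
and multiplicative moves on branch rates, locus rates and rate-drift
variances.  Step sizes are tuned to a 20-40% acceptance rate during
burn-in and frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .ml import ApproxLikelihoodSurface
from .trees import SpeciesTimeTree, _unrooted_branch_map

__all__ = [
    "Calibration",
    "TimePriorConfig",
    "RatePriorConfig",
    "McmcSettings",
    "PosteriorSummary",
    "soft_bound_logpdf",
    "time_prior_logpdf",
    "rate_prior_logpdf",
    "clock_logpdf_ir",
    "clock_logpdf_ar",
    "run_mcmc",
    "hpd_interval",
    "effective_sample_size",
    "convergence_check",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# calibrations and the time prior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Soft-bound calibration B(lower, upper) on one node's age.

    95% of the prior mass is uniform on (lower, upper); the remaining mass
    sits in decaying tails (default 2.5% each side): a power tail toward 0
    on the left and an exponential tail on the right, both matched so the
    density is continuous at the bounds.
    """

    node: int
    lower: float
    upper: float
    tail_left: float = 0.025
    tail_right: float = 0.025

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError("require 0 < lower < upper")
        if not (0 < self.tail_left < 0.5 and 0 < self.tail_right < 0.5):
            raise ValueError("tail probabilities must be in (0, 0.5)")

    @property
    def _interior_density(self) -> float:
        core = 1.0 - self.tail_left - self.tail_right
        return core / (self.upper - self.lower)


def soft_bound_logpdf(t: float, calibration: Calibration) -> float:
    """Log density of the soft-bound calibration at age ``t``."""
    a, b = calibration.lower, calibration.upper
    f_in = calibration._interior_density
    if t <= 0:
        return -np.inf
    if a <= t <= b:
        return math.log(f_in)
    if t < a:
        # power tail: p_L * (theta/a) * (t/a)^(theta-1), continuous at a
        theta = f_in * a / calibration.tail_left
        return (
            math.log(calibration.tail_left)
            + math.log(theta / a)
            + (theta - 1.0) * math.log(t / a)
        )
    lam = f_in / calibration.tail_right  # exponential right tail
    return math.log(f_in) - lam * (t - b)


@dataclass(frozen=True)
class TimePriorConfig:
    """Birth-death-with-calibrations prior on node ages.

    birth = death = 1 with sampling fraction 0 yields the uniform kernel
    used throughout: given the calibrated ages, the non-calibrated ages
    are jointly uniform over the region allowed by the tree's partial
    order.  Other (lambda, mu, rho) values are not implemented.
    """

    birth: float = 1.0
    death: float = 1.0
    rho: float = 0.0
    calibrations: tuple[Calibration, ...] = ()

    def __post_init__(self) -> None:
        if self.birth < 0 or self.death < 0 or not 0 <= self.rho <= 1:
            raise ValueError("invalid birth-death parameters")
        if not (self.birth == self.death and self.rho == 0.0):
            raise NotImplementedError(
                "only the uniform kernel (birth == death, rho == 0) is supported"
            )
        nodes = [c.node for c in self.calibrations]
        if len(set(nodes)) != len(nodes):
            raise ValueError("at most one calibration per node")


def _polymul_list(a: list[float], b: list[float]) -> list[float]:
    out = [0.0] * (len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        if ai == 0.0:
            continue
        for j, bj in enumerate(b):
            out[i + j] += ai * bj
    return out


def _polyval_list(x: float, coeffs: list[float]) -> float:
    val = 0.0
    for c in reversed(coeffs):
        val = val * x + c
    return val


class _UniformKernelVolume:
    """Volume of the free-age polytope given the calibrated ages.

    Under the uniform kernel the conditional density of the non-calibrated
    ages given the calibrated ones is 1/V on the polytope defined by the
    parent-older-than-child order, where V is its volume.  V is computed by
    recursive polynomial integration over the maximal free subtrees
    hanging below calibrated nodes, so the marginal prior of every
    calibrated node is exactly its calibration density.
    """

    def __init__(self, tree: SpeciesTimeTree, calibrated_labels: set[int]):
        self.tree = tree
        self.cal_idx = {tree.node_index(lab) for lab in calibrated_labels}
        root = tree.root_index
        if root not in self.cal_idx:
            raise ValueError("the root must carry a calibration")
        self.n_free = sum(
            1
            for v in range(tree.n_tips, tree.n_nodes)
            if v not in self.cal_idx
        )

    def log_volume(self, ages: np.ndarray) -> float:
        tree = self.tree
        # plain-list polynomial arithmetic: degrees are at most the number
        # of free nodes, so this stays tiny and avoids array overhead
        peval = _polyval_list

        def subtree(v: int) -> tuple[list[float], float]:
            """Polynomial W(u) and validity lower bound for free node v."""
            prod = [1.0]
            lower = 0.0
            for c in tree.children[v]:
                if not tree.children[c]:      # tip, age 0
                    continue
                if c in self.cal_idx:
                    lower = max(lower, float(ages[c]))
                else:
                    pc, lc = subtree(c)
                    prod = _polymul_list(prod, pc)
                    lower = max(lower, lc)
            anti = [0.0] + [coef / (i + 1) for i, coef in enumerate(prod)]
            anti[0] = -peval(lower, anti)
            return anti, lower

        logv = 0.0
        for c_idx in self.cal_idx:
            for ch in tree.children[c_idx]:
                if not tree.children[ch] or ch in self.cal_idx:
                    continue
                poly, lower = subtree(ch)
                val = peval(float(ages[c_idx]), poly)
                if val <= 0:
                    return np.inf  # order infeasible given calibrated ages
                logv += math.log(val)
        return logv


def _ages_vector(tree: SpeciesTimeTree, node_ages) -> np.ndarray:
    """Full per-node age array from either an array or a label->age dict."""
    if isinstance(node_ages, dict):
        ages = np.zeros(tree.n_nodes)
        for lab, a in node_ages.items():
            ages[tree.node_index(lab)] = a
        return ages
    ages = np.asarray(node_ages, dtype=float)
    if ages.shape == (tree.n_nodes,):
        return ages
    if ages.shape == (tree.n_tips - 1,):
        full = np.zeros(tree.n_nodes)
        full[tree.n_tips:] = ages
        return full
    raise ValueError("node_ages must map labels or give one age per node")


def time_prior_logpdf(
    tree: SpeciesTimeTree, node_ages, config: TimePriorConfig
) -> float:
    """Joint log prior of internal node ages.

    Calibration densities on calibrated nodes times the uniform-kernel
    conditional of the remaining ages (1/polytope-volume); -inf whenever a
    child is older than its parent.
    """
    ages = _ages_vector(tree, node_ages)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0 and ages[v] >= ages[p]:
            return -np.inf
    logp = 0.0
    for cal in config.calibrations:
        logp += soft_bound_logpdf(float(ages[tree.node_index(cal.node)]), cal)
    vol = _UniformKernelVolume(tree, {c.node for c in config.calibrations})
    logv = vol.log_volume(ages)
    if not np.isfinite(logv):
        return -np.inf
    return logp - logv


# ---------------------------------------------------------------------------
# rate priors and clock models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatePriorConfig:
    """Gamma-Dirichlet priors for locus rates and rate-drift variances.

    The mean locus rate mubar gets Gamma(rate_shape, rate_rate) (shape/rate,
    default G(2, 4), mean 0.5 per 100 Myr); locus rates are the total rate
    apportioned by a symmetric Dirichlet (concentration 1 = uniform).  The
    mean drift parameter sigma2bar gets Gamma(sigma2_shape, sigma2_rate)
    (default G(2, 20)) with the same Dirichlet apportionment.
    """

    rate_shape: float = 2.0
    rate_rate: float = 4.0
    sigma2_shape: float = 2.0
    sigma2_rate: float = 20.0
    dirichlet_conc: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.rate_shape, self.rate_rate, self.sigma2_shape,
                  self.sigma2_rate, self.dirichlet_conc):
            if v <= 0:
                raise ValueError("prior shapes/rates must be positive")


def _gamma_dirichlet_logpdf(
    values: np.ndarray, shape: float, rate: float, conc: float
) -> float:
    """Joint density of L positive values whose mean is Gamma(shape, rate)
    and whose proportions of the total are Dirichlet(conc, ..., conc)."""
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        return -np.inf
    L = x.size
    total = float(x.sum())
    mean = total / L
    log_gamma = (
        shape * math.log(rate) - gammaln(shape)
        + (shape - 1.0) * math.log(mean) - rate * mean
    )
    if L == 1:
        return log_gamma
    props = x / total
    log_dirichlet = (
        gammaln(conc * L) - L * gammaln(conc)
        + (conc - 1.0) * float(np.log(props).sum())
    )
    # (mean, proportions) -> values has Jacobian total^(L-1) / L
    return log_gamma + log_dirichlet - (L - 1) * math.log(total) - math.log(L)


def rate_prior_logpdf(locus_rates, config: RatePriorConfig) -> float:
    """Gamma-Dirichlet log prior of the per-partition locus rates."""
    return _gamma_dirichlet_logpdf(
        np.atleast_1d(locus_rates), config.rate_shape, config.rate_rate,
        config.dirichlet_conc,
    )


def sigma2_prior_logpdf(sigma2s, config: RatePriorConfig) -> float:
    return _gamma_dirichlet_logpdf(
        np.atleast_1d(sigma2s), config.sigma2_shape, config.sigma2_rate,
        config.dirichlet_conc,
    )


def clock_logpdf_ir(branch_rates, locus_rate: float, sigma2: float) -> float:
    """IR model: branch rates iid log-normal given the locus rate.

    log r_b ~ N(log mu - sigma2/2, sigma2), so E[r_b] = mu.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    r = np.asarray(branch_rates, dtype=float)
    if np.any(r <= 0):
        return -np.inf
    logr = np.log(r)
    mu_log = math.log(locus_rate) - sigma2 / 2.0
    return float(
        np.sum(-logr - 0.5 * (_LOG2PI + math.log(sigma2))
               - (logr - mu_log) ** 2 / (2.0 * sigma2))
    )


def clock_logpdf_ar(
    node_rates,
    root_rate: float,
    sigma2: float,
    durations,
    parent_rates,
) -> float:
    """AR model: log rates follow geometric Brownian motion along the tree.

    For each non-root node, log r_node ~ N(log r_parent - sigma2*dt/2,
    sigma2*dt) where dt is the time from the parent (drift-corrected so
    E[r_node | r_parent] = r_parent); ``parent_rates`` supplies r_parent
    per node (the root's children see ``root_rate``).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    r = np.asarray(node_rates, dtype=float)
    rp = np.asarray(parent_rates, dtype=float)
    dt = np.asarray(durations, dtype=float)
    if np.any(r <= 0) or np.any(rp <= 0):
        return -np.inf
    var = sigma2 * dt
    ok = var > 0
    logr, logrp = np.log(r[ok]), np.log(rp[ok])
    v = var[ok]
    out = np.sum(-logr - 0.5 * (_LOG2PI + np.log(v))
                 - (logr - logrp + v / 2.0) ** 2 / (2.0 * v))
    if np.any(~ok) and np.any(np.abs(np.log(r[~ok] / rp[~ok])) > 1e-12):
        return -np.inf  # dt == 0 collapses the child rate onto the parent
    return float(out)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ceil(mass * n) sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples for an HPD interval")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def effective_sample_size(x) -> float:
    """ESS from the initial positive sequence of autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return float(n)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n] / (n * var)
    s = 0.0
    for k in range(1, min(n, 1000)):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


@dataclass
class PosteriorSummary:
    """Posterior means, 95% HPD intervals and diagnostics per node."""

    node_labels: list[int]
    mean_ages: np.ndarray
    hpd_lo: np.ndarray
    hpd_hi: np.ndarray
    ess: np.ndarray
    age_samples: np.ndarray       # (n_samples, n_internal)
    mean_locus_rate: float
    mean_sigma2: float
    acceptance: dict[str, float]
    settings: "McmcSettings"
    scheme_label: str = ""

    @property
    def hpd_width(self) -> np.ndarray:
        return self.hpd_hi - self.hpd_lo

    def mean_age(self, label: int) -> float:
        return float(self.mean_ages[self.node_labels.index(label)])

    def hpd(self, label: int) -> tuple[float, float]:
        i = self.node_labels.index(label)
        return float(self.hpd_lo[i]), float(self.hpd_hi[i])


@dataclass(frozen=True)
class McmcSettings:
    """Chain-length settings (one step = one full parameter sweep).

    Defaults mirror the reference experimental protocol (burn-in 1e6,
    sample every 500 for 1e4 samples); scaled-down profiles pass shorter
    chains explicitly.
    """

    burn_in: int = 1_000_000
    sample_interval: int = 500
    n_samples: int = 10_000
    seed: int = 0
    clock_model: str = "IR"
    n_chains: int = 1

    def __post_init__(self) -> None:
        if min(self.burn_in, self.sample_interval, self.n_samples, self.n_chains) < 1:
            raise ValueError("chain settings must be positive")
        if self.clock_model not in ("IR", "AR"):
            raise ValueError("clock model must be IR or AR")


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _StepSize:
    """Scalar proposal width with burn-in Robbins-Monro-style tuning."""

    def __init__(self, value: float):
        self.value = value
        self.accepted = 0
        self.tried = 0
        self.total_accepted = 0
        self.total_tried = 0

    def record(self, accepted: int, tried: int) -> None:
        self.accepted += accepted
        self.tried += tried
        self.total_accepted += accepted
        self.total_tried += tried

    def tune(self) -> None:
        if self.tried == 0:
            return
        rate = self.accepted / self.tried
        if rate > 0.4:
            self.value *= 1.4
        elif rate < 0.2:
            self.value /= 1.4
        self.accepted = self.tried = 0

    @property
    def rate(self) -> float:
        return self.total_accepted / max(self.total_tried, 1)


class _DatingSampler:
    def __init__(
        self,
        tree: SpeciesTimeTree,
        surfaces: list[ApproxLikelihoodSurface] | None,
        time_prior: TimePriorConfig,
        rate_prior: RatePriorConfig,
        settings: McmcSettings,
        rng: np.random.Generator,
    ):
        self.tree = tree
        self.time_prior = time_prior
        self.rate_prior = rate_prior
        self.settings = settings
        self.rng = rng
        self.ar = settings.clock_model == "AR"

        self.n_tips = tree.n_tips
        self.n_int = tree.n_tips - 1
        self.child = tree.branch_child                       # (2s-2,)
        self.parent_of_child = tree.parent[self.child]
        self.n_branches = tree.n_branches

        mapping, edges = _unrooted_branch_map(tree)
        self._mapping = mapping
        self.n_edges = len(edges)
        self.fold = np.zeros((self.n_branches, self.n_edges))
        self.fold[np.arange(self.n_branches), mapping] = 1.0

        if surfaces is None:
            self.L = 1
            self.have_data = False
            self.ll0 = np.zeros(1)
            self.g = np.zeros((1, self.n_edges))
            self.h = np.zeros((1, self.n_edges, self.n_edges))
        else:
            self.L = len(surfaces)
            self.have_data = True
            self.ll0 = np.array([s.loglik for s in surfaces])
            self.bhat = np.stack([s.bhat for s in surfaces])
            self.g = np.stack([s.gradient for s in surfaces])
            self.h = np.stack([s.hessian for s in surfaces])
            if self.bhat.shape[1] != self.n_edges:
                raise ValueError("surface dimension does not match the tree")

        self.cal_by_idx = {
            tree.node_index(c.node): c for c in time_prior.calibrations
        }
        self.volume = _UniformKernelVolume(
            tree, {c.node for c in time_prior.calibrations}
        )

        # branch index of each node's parent edge, children-branch lists
        self.branch_of_child = {int(c): b for b, c in enumerate(self.child)}
        self.child_branches = [
            [self.branch_of_child[int(c)] for c in tree.children[v]]
            for v in range(tree.n_nodes)
        ]

        self._init_state()
        self._steps = {
            "age": [_StepSize(0.05) for _ in range(self.n_int)],
            "scale": _StepSize(0.1),
            "brate": _StepSize(0.5),
            "mu": _StepSize(0.3),
            "sigma2": _StepSize(0.5),
        }

    # -- state -----------------------------------------------------------

    def _init_state(self) -> None:
        tree, rng = self.tree, self.rng
        rp = self.rate_prior
        # ages from a prior-style draw: calibrated nodes inside their
        # bounds, free nodes uniform below their parent (preorder)
        ages = np.zeros(tree.n_nodes)
        order = [tree.root_index]
        for v in order:
            order.extend(c for c in tree.children[v] if tree.children[c])
        for v in order:
            p = tree.parent[v]
            upper = float(ages[p]) if p >= 0 else np.inf
            cal = self.cal_by_idx.get(v)
            if cal is not None:
                hi = min(cal.upper, upper) if np.isfinite(upper) else cal.upper
                lo = min(cal.lower, 0.95 * hi)
                ages[v] = rng.uniform(lo, hi)
            else:
                ages[v] = rng.uniform(0.1 * upper, upper)
        self.ages = ages
        # locus rates / sigma2 at their prior means
        self.mu = np.full(self.L, rp.rate_shape / rp.rate_rate)
        self.sigma2 = np.full(self.L, rp.sigma2_shape / rp.sigma2_rate)
        if self.ar:
            self.node_rates = np.tile(self.mu[:, None], (1, self.n_branches))
        else:
            self.rates = np.tile(self.mu[:, None], (1, self.n_branches))
        if self.have_data:
            self._init_state_from_data()
        self._refresh_cached()

    def _rooted_lengths(self, un: np.ndarray) -> np.ndarray:
        """Per-branch lengths from an unrooted vector; the merged root
        edge is split evenly between the two root branches."""
        out = un[self._mapping].astype(float)
        root = self.tree.root_index
        for b in range(self.n_branches):
            if int(self.parent_of_child[b]) == root:
                out[b] = un[0] / 2.0
        return out

    def _init_state_from_data(self) -> None:
        """Start the chain near the fitted branch lengths instead of a
        prior draw: node ages proportional to mean molecular depths with
        the root at its calibration midpoint, branch rates equal to the
        implied fitted rate of each branch.  The data surface is far more
        concentrated than the priors, so a prior draw can need very long
        burn-in; initialization does not change the target distribution."""
        tree = self.tree
        rooted = np.stack([self._rooted_lengths(b) for b in self.bhat])
        mean_len = rooted.mean(axis=0)
        heights = np.zeros(tree.n_nodes)
        order = [tree.root_index]
        for v in order:
            order.extend(tree.children[v])
        for v in reversed(order):
            kids = tree.children[v]
            if kids:
                heights[v] = float(
                    np.mean(
                        [
                            heights[c] + mean_len[self.branch_of_child[int(c)]]
                            for c in kids
                        ]
                    )
                )
        root = tree.root_index
        if heights[root] <= 0:
            return  # degenerate fit; keep the prior-style start
        root_cal = self.cal_by_idx.get(root)
        t1 = (
            0.5 * (root_cal.lower + root_cal.upper)
            if root_cal is not None
            else float(self.ages[root])
        )
        ages = heights * (t1 / heights[root])
        for v in order[1:]:  # enforce strict ordering for tied depths
            if tree.children[v]:
                p = int(tree.parent[v])
                ages[v] = min(max(ages[v], 1e-6 * t1), (1.0 - 1e-6) * ages[p])
        self.ages = ages
        durations = self._durations()
        rates = np.maximum(rooted / durations[None, :], 1e-6)
        self.mu = rates.mean(axis=1)
        self.sigma2 = np.maximum(np.log(rates).var(axis=1), 1e-4)
        if self.ar:
            self.node_rates = rates
        else:
            self.rates = rates

    def _durations(self) -> np.ndarray:
        return self.ages[self.parent_of_child] - self.ages[self.child]

    def _branch_rates(self) -> np.ndarray:
        """(L, 2s-2) effective branch rates."""
        if not self.ar:
            return self.rates
        parent_rates = self._parent_node_rates()
        return 0.5 * (self.node_rates + parent_rates)

    def _parent_node_rates(self) -> np.ndarray:
        """Rate at the parent node of each branch (AR), (L, 2s-2)."""
        out = np.empty((self.L, self.n_branches))
        root = self.tree.root_index
        for b, c in enumerate(self.child):
            p = int(self.parent_of_child[b])
            if p == root:
                out[:, b] = self.mu
            else:
                out[:, b] = self.node_rates[:, self.branch_of_child[p]]
        return out

    def _loglik_all(self, durations=None, branch_rates=None) -> np.ndarray:
        if not self.have_data:
            return np.zeros(self.L)
        if durations is None:
            durations = self._durations()
        if branch_rates is None:
            branch_rates = self._branch_rates()
        lengths = branch_rates * durations[None, :]
        un = lengths @ self.fold                     # (L, n_edges)
        d = un - self.bhat
        hd = np.matmul(self.h, d[:, :, None])[:, :, 0]
        return self.ll0 + (self.g * d).sum(axis=1) + 0.5 * (d * hd).sum(axis=1)

    def _log_time_prior(self, ages) -> float:
        tree = self.tree
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p >= 0 and ages[v] >= ages[p]:
                return -np.inf
        logp = 0.0
        for idx, cal in self.cal_by_idx.items():
            logp += soft_bound_logpdf(float(ages[idx]), cal)
        logv = self.volume.log_volume(ages)
        if not np.isfinite(logv):
            return -np.inf
        return logp - logv

    def _log_clock(self, p: int | None = None) -> float | np.ndarray:
        """Per-partition clock prior (vector), or one partition's value."""
        idx = slice(None) if p is None else slice(p, p + 1)
        if not self.ar:
            r = self.rates[idx]
            mu = self.mu[idx]
            s2 = self.sigma2[idx]
            logr = np.log(r)
            mu_log = np.log(mu) - s2 / 2.0
            terms = (-logr - 0.5 * (_LOG2PI + np.log(s2[:, None]))
                     - (logr - mu_log[:, None]) ** 2 / (2.0 * s2[:, None]))
            out = terms.sum(axis=1)
        else:
            dt = self._durations()[None, :]
            r = self.node_rates[idx]
            rp = self._parent_node_rates()[idx]
            s2 = self.sigma2[idx]
            var = s2[:, None] * dt
            logr = np.log(r)
            out = np.sum(
                -logr - 0.5 * (_LOG2PI + np.log(var))
                - (logr - np.log(rp) + var / 2.0) ** 2 / (2.0 * var),
                axis=1,
            )
        return out if p is None else float(out[0])

    def _refresh_cached(self) -> None:
        self.cur_ll = self._loglik_all()
        self.cur_time = self._log_time_prior(self.ages)
        self.cur_clock = np.atleast_1d(self._log_clock())
        self.cur_mu_prior = rate_prior_logpdf(self.mu, self.rate_prior)
        self.cur_s2_prior = sigma2_prior_logpdf(self.sigma2, self.rate_prior)

    # -- moves -----------------------------------------------------------

    def _move_ages(self) -> None:
        tree, rng = self.tree, self.rng
        for k in range(self.n_int):
            v = self.n_tips + k
            step = self._steps["age"][k]
            lower = max(float(self.ages[c]) for c in tree.children[v])
            p = tree.parent[v]
            upper = float(self.ages[p]) if p >= 0 else np.inf
            t0 = float(self.ages[v])
            t1 = t0 + step.value * (rng.random() - 0.5)
            # reflect at the hard bounds to keep the proposal symmetric
            for _ in range(4):
                if t1 < lower:
                    t1 = 2 * lower - t1
                elif np.isfinite(upper) and t1 > upper:
                    t1 = 2 * upper - t1
                else:
                    break
            if not (lower < t1 and (not np.isfinite(upper) or t1 < upper)) or t1 <= 0:
                step.record(0, 1)
                continue
            old_age = self.ages[v]
            self.ages[v] = t1
            if v in self.cal_by_idx:
                new_time = self._log_time_prior(self.ages)
            else:
                # volume and soft bounds depend only on calibrated ages;
                # the bounds above already keep the order feasible
                new_time = self.cur_time
            if not np.isfinite(new_time):
                self.ages[v] = old_age
                step.record(0, 1)
                continue
            new_ll = self._loglik_all()
            new_clock = (
                np.atleast_1d(self._log_clock()) if self.ar else self.cur_clock
            )
            delta = (
                (new_time - self.cur_time)
                + float(new_ll.sum() - self.cur_ll.sum())
                + float(new_clock.sum() - self.cur_clock.sum())
            )
            if math.log(rng.random() + 1e-300) < delta:
                self.cur_time, self.cur_ll, self.cur_clock = new_time, new_ll, new_clock
                step.record(1, 1)
            else:
                self.ages[v] = old_age
                step.record(0, 1)

    def _move_scale(self) -> None:
        """Rescale all ages by c and all rates by 1/c (likelihood-neutral)."""
        rng = self.rng
        step = self._steps["scale"]
        c = math.exp(step.value * (rng.random() - 0.5))
        ages = self.ages.copy()
        ages[self.n_tips:] *= c
        mu = self.mu / c
        if self.ar:
            rates = self.node_rates / c
        else:
            rates = self.rates / c
        n_rate_params = self.L + rates.size
        log_jac = self.n_int * math.log(c) - n_rate_params * math.log(c)

        new_time = self._log_time_prior(ages)
        if not np.isfinite(new_time):
            step.record(0, 1)
            return
        new_mu_prior = rate_prior_logpdf(mu, self.rate_prior)
        old = self.ages, self.mu
        self.ages = ages
        self.mu = mu
        if self.ar:
            old_r = self.node_rates
            self.node_rates = rates
        else:
            old_r = self.rates
            self.rates = rates
        new_clock = np.atleast_1d(self._log_clock())
        delta = (
            (new_time - self.cur_time)
            + (new_mu_prior - self.cur_mu_prior)
            + float(new_clock.sum() - self.cur_clock.sum())
            + log_jac
        )
        if math.log(rng.random() + 1e-300) < delta:
            self.cur_time, self.cur_mu_prior, self.cur_clock = (
                new_time, new_mu_prior, new_clock,
            )
            step.record(1, 1)
        else:
            self.ages, self.mu = old
            if self.ar:
                self.node_rates = old_r
            else:
                self.rates = old_r
            step.record(0, 1)

    def _move_branch_rates(self) -> None:
        """Multiplicative moves, vectorized across partitions per branch.

        Partition likelihoods and clock densities are conditionally
        independent given the ages, so each partition accepts or rejects
        its own proposal and rejected entries keep their cached values.
        """
        rng = self.rng
        step = self._steps["brate"]
        durations = self._durations()
        if not self.ar:
            mu_log = np.log(self.mu) - self.sigma2 / 2.0
        acc = tried = 0
        for b in range(self.n_branches):
            eps = step.value * (rng.random(self.L) - 0.5)
            if self.ar:
                old_col = self.node_rates[:, b].copy()
                self.node_rates[:, b] = old_col * np.exp(eps)
            else:
                old_col = self.rates[:, b].copy()
                self.rates[:, b] = old_col * np.exp(eps)
            new_ll = self._loglik_all(durations=durations)
            if self.ar:
                dclock = np.atleast_1d(self._log_clock()) - self.cur_clock
            else:
                # closed-form IR delta: log r' = log r + eps
                z = np.log(old_col) - mu_log
                dclock = -eps - (eps * eps + 2.0 * eps * z) / (2.0 * self.sigma2)
            delta = (new_ll - self.cur_ll) + dclock + eps
            accept = np.log(rng.random(self.L) + 1e-300) < delta
            if not np.all(accept):
                if self.ar:
                    self.node_rates[~accept, b] = old_col[~accept]
                else:
                    self.rates[~accept, b] = old_col[~accept]
            self.cur_ll = np.where(accept, new_ll, self.cur_ll)
            self.cur_clock = self.cur_clock + np.where(accept, dclock, 0.0)
            acc += int(accept.sum())
            tried += self.L
        step.record(acc, tried)

    def _move_mu(self) -> None:
        rng = self.rng
        step = self._steps["mu"]
        acc = 0
        for p in range(self.L):
            eps = step.value * (rng.random() - 0.5)
            old = self.mu[p]
            self.mu[p] = old * math.exp(eps)
            new_prior = rate_prior_logpdf(self.mu, self.rate_prior)
            new_clock_p = self._log_clock(p)
            delta = (new_prior - self.cur_mu_prior) + (
                new_clock_p - float(self.cur_clock[p])
            ) + eps
            if math.log(rng.random() + 1e-300) < delta:
                self.cur_mu_prior = new_prior
                self.cur_clock[p] = new_clock_p
                acc += 1
            else:
                self.mu[p] = old
        step.record(acc, self.L)

    def _move_sigma2(self) -> None:
        rng = self.rng
        step = self._steps["sigma2"]
        acc = 0
        for p in range(self.L):
            eps = step.value * (rng.random() - 0.5)
            old = self.sigma2[p]
            self.sigma2[p] = old * math.exp(eps)
            new_prior = sigma2_prior_logpdf(self.sigma2, self.rate_prior)
            new_clock_p = self._log_clock(p)
            delta = (new_prior - self.cur_s2_prior) + (
                new_clock_p - float(self.cur_clock[p])
            ) + eps
            if math.log(rng.random() + 1e-300) < delta:
                self.cur_s2_prior = new_prior
                self.cur_clock[p] = new_clock_p
                acc += 1
            else:
                self.sigma2[p] = old
        step.record(acc, self.L)

    def sweep(self) -> None:
        self._move_ages()
        self._move_scale()
        self._move_branch_rates()
        self._move_mu()
        self._move_sigma2()
        self._sweeps = getattr(self, "_sweeps", 0) + 1
        if self._sweeps % 1000 == 0:  # guard against incremental drift
            self._refresh_cached()

    # -- driver ----------------------------------------------------------

    def run(self) -> PosteriorSummary:
        st = self.settings
        tune_every = 100
        for i in range(st.burn_in):
            self.sweep()
            if (i + 1) % tune_every == 0:
                for s in self._steps["age"]:
                    s.tune()
                for key in ("scale", "brate", "mu", "sigma2"):
                    self._steps[key].tune()
        n = st.n_samples
        ages_out = np.empty((n, self.n_int))
        mu_out = np.empty(n)
        s2_out = np.empty(n)
        for j in range(n):
            for _ in range(st.sample_interval):
                self.sweep()
            ages_out[j] = self.ages[self.n_tips:]
            mu_out[j] = self.mu.mean()
            s2_out[j] = self.sigma2.mean()

        lo = np.empty(self.n_int)
        hi = np.empty(self.n_int)
        ess = np.empty(self.n_int)
        for k in range(self.n_int):
            lo[k], hi[k] = hpd_interval(ages_out[:, k])
            ess[k] = effective_sample_size(ages_out[:, k])
        acceptance = {
            "age": float(np.mean([s.rate for s in self._steps["age"]])),
            "scale": self._steps["scale"].rate,
            "brate": self._steps["brate"].rate,
            "mu": self._steps["mu"].rate,
            "sigma2": self._steps["sigma2"].rate,
        }
        return PosteriorSummary(
            node_labels=list(self.tree.internal_labels),
            mean_ages=ages_out.mean(axis=0),
            hpd_lo=lo,
            hpd_hi=hi,
            ess=ess,
            age_samples=ages_out,
            mean_locus_rate=float(mu_out.mean()),
            mean_sigma2=float(s2_out.mean()),
            acceptance=acceptance,
            settings=st,
        )


def run_mcmc(
    tree: SpeciesTimeTree,
    surfaces: list[ApproxLikelihoodSurface] | None,
    time_prior: TimePriorConfig,
    rate_prior: RatePriorConfig,
    settings: McmcSettings,
    scheme_label: str = "",
) -> PosteriorSummary:
    """Sample node ages (and rate parameters) from the dating posterior.

    ``surfaces`` holds one approximate-likelihood surface per partition;
    ``surfaces=None`` runs without data (likelihood identically 0), which
    samples the time prior and is the standard check that calibrated-node
    marginals match their calibration densities.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence((settings.seed, 982451653))
    )
    sampler = _DatingSampler(tree, surfaces, time_prior, rate_prior, settings, rng)
    summary = sampler.run()
    summary.scheme_label = scheme_label
    return summary


@dataclass
class ConvergenceReport:
    passed: bool
    max_diff: float
    node_diffs: dict[int, float]
    flagged: list[int]


def convergence_check(
    summary_a: PosteriorSummary, summary_b: PosteriorSummary, tol: float = 0.01
) -> ConvergenceReport:
    """Compare posterior mean ages of two independent runs.

    Nodes whose means differ by more than ``tol`` x (mean root age) are
    flagged; the check passes when no node is flagged.
    """
    if summary_a.node_labels != summary_b.node_labels:
        raise ValueError("summaries come from different configurations")
    root_age = 0.5 * (summary_a.mean_ages[0] + summary_b.mean_ages[0])
    diffs = {
        lab: float(abs(a - b))
        for lab, a, b in zip(
            summary_a.node_labels, summary_a.mean_ages, summary_b.mean_ages
        )
    }
    flagged = [lab for lab, d in diffs.items() if d > tol * root_age]
    return ConvergenceReport(
        passed=not flagged,
        max_diff=max(diffs.values()),
        node_diffs=diffs,
        flagged=flagged,
    )
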