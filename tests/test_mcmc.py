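import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from clockpart.mcmc import (
    Calibration,
    McmcSettings,
    RatePriorConfig,
    TimePriorConfig,
    _gamma_dirichlet_logpdf,
    _UniformKernelVolume,
    clock_logpdf_ar,
    clock_logpdf_ir,
    convergence_check,
    effective_sample_size,
    hpd_interval,
    rate_prior_logpdf,
    run_mcmc,
    soft_bound_logpdf,
    time_prior_logpdf,
)

ROOT_CAL = Calibration(node=1, lower=0.8, upper=1.2)
NODE3_CAL = Calibration(node=3, lower=0.525, upper=0.575)


# -- soft bounds -----------------------------------------------------------

def test_soft_bound_masses():
    cal = ROOT_CAL
    f = lambda t: math.exp(soft_bound_logpdf(t, cal))
    core, _ = quad(f, cal.lower, cal.upper)
    left, _ = quad(f, 0.0, cal.lower)
    right, _ = quad(f, cal.upper, 50.0)
    assert np.isclose(core, 0.95, atol=1e-6)
    assert np.isclose(left, 0.025, atol=1e-6)
    assert np.isclose(right, 0.025, atol=1e-6)


def test_soft_bound_density_continuity_and_tails():
    cal = Calibration(node=1, lower=0.5, upper=0.9)
    f = lambda t: math.exp(soft_bound_logpdf(t, cal))
    interior = 0.95 / (0.9 - 0.5)
    assert np.isclose(f(0.5 - 1e-9), interior, rtol=1e-5)
    assert np.isclose(f(0.9 + 1e-9), interior, rtol=1e-5)
    # tails decay monotonically away from the bounds
    xs_left = np.linspace(0.05, 0.499, 50)
    assert np.all(np.diff([f(x) for x in xs_left]) > 0)
    xs_right = np.linspace(0.901, 5.0, 50)
    assert np.all(np.diff([f(x) for x in xs_right]) < 0)
    assert soft_bound_logpdf(-0.1, cal) == -np.inf


def test_calibration_validation():
    with pytest.raises(ValueError):
        Calibration(node=1, lower=1.2, upper=0.8)
    with pytest.raises(ValueError):
        Calibration(node=1, lower=0.0, upper=1.0)
    with pytest.raises(ValueError):
        TimePriorConfig(calibrations=(ROOT_CAL, ROOT_CAL))
    with pytest.raises(NotImplementedError):
        TimePriorConfig(birth=2.0, death=1.0)


# -- time prior ------------------------------------------------------------

def test_time_prior_rejects_order_violations(tree):
    cfg = TimePriorConfig(calibrations=(ROOT_CAL,))
    good = {lab: float(tree.ages[tree.node_index(lab)]) for lab in tree.internal_labels}
    assert np.isfinite(time_prior_logpdf(tree, good, cfg))
    bad = dict(good)
    bad[7] = 0.2  # node 7 older than its parent node 6 (0.15)
    assert time_prior_logpdf(tree, bad, cfg) == -np.inf


def test_time_prior_requires_calibrated_root(tree):
    with pytest.raises(ValueError):
        time_prior_logpdf(
            tree,
            {lab: float(tree.ages[tree.node_index(lab)]) for lab in tree.internal_labels},
            TimePriorConfig(calibrations=(NODE3_CAL,)),
        )


def test_polytope_volume_root_only(tree):
    """With only the root calibrated, the seven free caterpillar/clade ages
    occupy volume t1^7 / 720 (a 6-chain times one unconstrained age)."""
    vol = _UniformKernelVolume(tree, {1})
    for t1 in (0.9, 1.0, 1.17):
        ages = tree.ages * t1  # rescaling keeps the interior ages valid
        got = vol.log_volume(ages)
        want = math.log(t1**7 / 720.0)
        assert np.isclose(got, want)


def test_polytope_volume_two_calibrations(tree):
    """Root and node 3 calibrated: V = (t1 - t3) * t1 * t3^4 / 24."""
    vol = _UniformKernelVolume(tree, {1, 3})
    rng = np.random.default_rng(2)
    for _ in range(10):
        t1 = rng.uniform(0.8, 1.2)
        t3 = rng.uniform(0.3, 0.7)
        ages = tree.ages.copy()
        ages[tree.root_index] = t1
        ages[tree.node_index(2)] = (t1 + t3) / 2
        ages[tree.node_index(3)] = t3
        for lab in (4, 5, 6, 7):
            ages[tree.node_index(lab)] = t3 * tree.ages[tree.node_index(lab)]
        got = vol.log_volume(ages)
        want = math.log((t1 - t3) * t1 * t3**4 / 24.0)
        assert np.isclose(got, want)


def test_polytope_volume_homogeneity(tree):
    vol = _UniformKernelVolume(tree, {1})
    ages = tree.ages.copy()
    c = 1.7
    assert np.isclose(
        vol.log_volume(ages * c), vol.log_volume(ages) + vol.n_free * math.log(c)
    )


def test_time_prior_equals_calibration_minus_volume(tree):
    cfg = TimePriorConfig(calibrations=(ROOT_CAL,))
    ages = {lab: float(tree.ages[tree.node_index(lab)]) for lab in tree.internal_labels}
    lp = time_prior_logpdf(tree, ages, cfg)
    want = soft_bound_logpdf(1.0, ROOT_CAL) - math.log(1.0 / 720.0)
    assert np.isclose(lp, want)


# -- rate priors and clock densities --------------------------------------

def test_gamma_dirichlet_single_locus_is_gamma():
    for x in (0.1, 0.5, 2.0):
        got = _gamma_dirichlet_logpdf(np.array([x]), 2.0, 4.0, 1.0)
        want = stats.gamma.logpdf(x, 2.0, scale=1.0 / 4.0)
        assert np.isclose(got, want)


def test_gamma_dirichlet_two_loci_integrates_to_one():
    from scipy.integrate import dblquad

    f = lambda y, x: math.exp(_gamma_dirichlet_logpdf(np.array([x, y]), 2.0, 4.0, 1.0))
    total, err = dblquad(f, 1e-6, 12.0, 1e-6, 12.0, epsabs=1e-6)
    assert np.isclose(total, 1.0, atol=5e-4)


def test_rate_prior_negative_values():
    assert rate_prior_logpdf(np.array([0.5, -0.1]), RatePriorConfig()) == -np.inf


def test_ir_clock_matches_lognormal():
    mu, s2 = 0.6, 0.25
    r = np.array([0.2, 0.6, 1.1])
    got = clock_logpdf_ir(r, mu, s2)
    want = stats.lognorm.logpdf(
        r, np.sqrt(s2), scale=np.exp(np.log(mu) - s2 / 2.0)
    ).sum()
    assert np.isclose(got, want)
    # the drift correction makes the mean equal mu
    assert np.isclose(
        stats.lognorm.mean(np.sqrt(s2), scale=np.exp(np.log(mu) - s2 / 2.0)), mu
    )


def test_ar_clock_variance_additivity():
    """Integrating out the midpoint rate of a two-step geometric Brownian
    path gives the one-step density over the summed duration."""
    s2, rp, rc = 0.3, 0.8, 0.5
    dt1, dt2 = 0.4, 0.7

    def one_step(r, r_parent, dt):
        return math.exp(
            clock_logpdf_ar(
                np.array([r]), r_parent, s2, np.array([dt]), np.array([r_parent])
            )
        )

    marginal, _ = quad(
        lambda rm: one_step(rm, rp, dt1) * one_step(rc, rm, dt2), 1e-9, 50.0,
        limit=200,
    )
    direct = one_step(rc, rp, dt1 + dt2)
    assert np.isclose(marginal, direct, rtol=1e-6)


# -- posterior summaries ---------------------------------------------------

def test_hpd_interval_normal_oracle(rng):
    x = rng.normal(3.0, 2.0, size=20000)
    lo, hi = hpd_interval(x)
    assert abs(lo - (3.0 - 1.96 * 2.0)) < 0.15
    assert abs(hi - (3.0 + 1.96 * 2.0)) < 0.15
    inside = ((x >= lo) & (x <= hi)).mean()
    assert inside >= 0.95
    with pytest.raises(ValueError):
        hpd_interval(np.arange(50))


def test_hpd_interval_is_shortest_window(rng):
    x = np.sort(rng.gamma(2.0, 1.0, size=500))
    lo, hi = hpd_interval(x, mass=0.9)
    m = math.ceil(0.9 * x.size)
    widths = x[m - 1:] - x[: x.size - m + 1]
    assert np.isclose(hi - lo, widths.min())


def test_effective_sample_size():
    rng = np.random.default_rng(6)
    iid = rng.normal(size=5000)
    assert abs(effective_sample_size(iid) - 5000) / 5000 < 0.2
    # AR(1): ESS ~= n (1 - rho) / (1 + rho)
    rho = 0.9
    n = 20000
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.normal(size=n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    ess = effective_sample_size(x)
    want = n * (1 - rho) / (1 + rho)
    assert 0.5 * want < ess < 2.0 * want
    assert effective_sample_size(np.ones(100)) == 100.0


# -- the sampler -----------------------------------------------------------

def test_settings_validation():
    with pytest.raises(ValueError):
        McmcSettings(burn_in=0)
    with pytest.raises(ValueError):
        McmcSettings(clock_model="strict")


@pytest.fixture(scope="module")
def short_run(tree, small_surface):
    settings = McmcSettings(burn_in=500, sample_interval=2, n_samples=400, seed=99)
    return run_mcmc(
        tree,
        [small_surface],
        TimePriorConfig(calibrations=(ROOT_CAL,)),
        RatePriorConfig(),
        settings,
        scheme_label="C",
    )


def test_sampler_state_is_valid(tree, short_run):
    s = short_run
    assert s.scheme_label == "C"
    assert s.node_labels == tree.internal_labels
    assert np.all(np.isfinite(s.age_samples))
    assert np.all(s.age_samples > 0)
    # every retained sample respects the tree's partial order
    col = {lab: k for k, lab in enumerate(s.node_labels)}
    for child, parent in ((2, 1), (3, 2), (4, 3), (5, 4), (6, 5), (7, 6), (8, 1)):
        assert np.all(s.age_samples[:, col[child]] < s.age_samples[:, col[parent]])
    assert np.all(s.ess > 0)
    assert np.all(s.hpd_lo < s.hpd_hi)
    assert 0 < s.mean_locus_rate
    assert 0 < s.mean_sigma2
    for rate in s.acceptance.values():
        assert 0 <= rate <= 1


def test_sampler_reproducible(tree, small_surface, short_run):
    settings = McmcSettings(burn_in=500, sample_interval=2, n_samples=400, seed=99)
    again = run_mcmc(
        tree,
        [small_surface],
        TimePriorConfig(calibrations=(ROOT_CAL,)),
        RatePriorConfig(),
        settings,
    )
    np.testing.assert_array_equal(again.age_samples, short_run.age_samples)


def test_convergence_check(short_run):
    import copy

    report = convergence_check(short_run, short_run)
    assert report.passed
    assert report.max_diff == 0.0
    other = copy.deepcopy(short_run)
    other.mean_ages = other.mean_ages + 0.1
    report = convergence_check(short_run, other, tol=0.01)
    assert not report.passed
    assert set(report.flagged) == set(short_run.node_labels)
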