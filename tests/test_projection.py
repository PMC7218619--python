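"""Random-walk extrapolation and projected-rate credible bands."""

import numpy as np
import pytest

from painapc import (
    APCModelSpec,
    APCParams,
    debug_truth,
    extend_random_walk,
    generate_apc_table,
    project_rates,
    projection_delta,
    sample_posterior,
    MCMCConfig,
)
from painapc.inference import PosteriorSamples
from painapc.projection import ProjectionResult, projection_frame

from conftest import make_table

HUGE_TAU = 1e12  # effectively deterministic random walk


def _frozen_samples(mu, alpha, beta, gamma, copies=400, tau=HUGE_TAU, z_tau=None):
    """Identical draws: lets the deterministic RW limit be checked exactly."""
    effects = {"age": np.tile(alpha, (copies, 1)),
               "period": np.tile(beta, (copies, 1)),
               "cohort": np.tile(gamma, (copies, 1))}
    taus = {k: np.full(copies, tau) for k in effects}
    return PosteriorSamples(
        spec=APCModelSpec(overdispersion=z_tau is not None),
        mu=np.full(copies, mu),
        effects=effects,
        taus=taus,
        z=None if z_tau is None else np.zeros((copies, len(alpha), len(beta))),
        tau_z=None if z_tau is None else np.full(copies, z_tau),
        chain=np.zeros(copies, dtype=int),
        acceptance_rates={},
        seed=0,
    )


def test_rw2_deterministic_limit_continues_linearly():
    u = np.array([[0.0, 0.1, 0.2]])
    out = extend_random_walk(u, np.array([HUGE_TAU]), order=2, horizon=3,
                             rng=np.random.default_rng(0))
    assert np.allclose(out[0, 3:], [0.3, 0.4, 0.5], atol=1e-5)


def test_rw1_deterministic_limit_continues_constantly():
    u = np.array([[0.4, 0.1, -0.2]])
    out = extend_random_walk(u, np.array([HUGE_TAU]), order=1, horizon=4,
                             rng=np.random.default_rng(0))
    assert np.allclose(out[0, 3:], -0.2, atol=1e-5)


def test_zero_horizon_returns_input_unchanged():
    u = np.array([[1.0, 2.0]])
    out = extend_random_walk(u, np.array([1.0]), 1, 0, np.random.default_rng(0))
    assert np.array_equal(out, u)


def test_rw1_hstep_variance_grows_linearly():
    """Var of the h-step increment is h/tau (independent Gaussian steps)."""
    tau = 4.0
    S = 100_000
    u = np.zeros((S, 2))
    out = extend_random_walk(u, np.full(S, tau), 1, 3, np.random.default_rng(7))
    for h in (1, 2, 3):
        inc = out[:, 1 + h] - out[:, 1]
        target = h / tau
        se = target * np.sqrt(2.0 / S)  # MC standard error of a chi-square variance
        assert abs(inc.var() - target) < 3 * se, h


def test_flat_truth_projects_the_same_rate_everywhere(debug_table):
    samples = _frozen_samples(np.log(0.4), np.zeros(4), np.zeros(3), np.zeros(6))
    results = project_rates(samples, debug_table, horizon_periods=2)
    assert len(results) == 4 * 2
    for r in results:
        assert r.mean == pytest.approx(0.4, abs=1e-5)
        for lo, hi in r.bands.values():
            assert lo == pytest.approx(0.4, abs=1e-4) and hi == pytest.approx(0.4, abs=1e-4)


def test_rw2_projection_continues_log_linear_period_trend():
    """Data from a log-linear period truth: the stochastic RW2 projection is
    centred on the linear continuation of the fitted trend — the per-draw
    deterministic continuation falls inside the 50% band in >= 90% of cells."""
    import painapc.simulate as sim

    hits = total = 0
    for rep in range(10):
        truth = sim.APCTruth(
            mu_true=float(np.log(0.4)),
            alpha_true=np.zeros(4),
            beta_true=np.linspace(-0.08, 0.08, 3),
            gamma_true=np.zeros(6),
            overdispersion_sd=0.0,
            n_pattern=np.full((4, 3), 50_000, dtype=np.int64),
            stratum="lin",
            seed=500 + rep,
        )
        table = sim.generate_apc_table(truth)
        spec = APCModelSpec(effects=("age", "period"), rw_order={"age": 2, "period": 2},
                            overdispersion=False)
        cfg = MCMCConfig(n_iterations=2000, n_burnin=800, thinning=2, n_chains=1, seed=rep)
        fit = sample_posterior(table, spec, cfg)
        results = project_rates(fit, table, horizon_periods=2, seed=rep)
        beta = fit.effects["period"]
        step = beta[:, -1] - beta[:, -2]
        for r in results:
            h = r.period.index - 3
            i = int((r.age_start - 31) // 5)
            det = np.exp(fit.mu + fit.effects["age"][:, i] + beta[:, -1] + step * h)
            target = float(np.median(det))
            lo, hi = r.bands[50]
            hits += lo <= target <= hi
            total += 1
    assert hits / total >= 0.9
    # and the fitted period slope itself tracks the truth closely at these counts
    assert abs(np.median(step) - 0.08) < 0.02


def test_bands_nested_on_real_fit(debug_fit, debug_table):
    results = project_rates(debug_fit, debug_table, horizon_periods=3,
                            band_levels=(10, 25, 50, 75, 95))
    for r in results:
        levels = sorted(r.bands)
        for a, b in zip(levels, levels[1:]):
            assert r.bands[b][0] <= r.bands[a][0] <= r.bands[a][1] <= r.bands[b][1]
        assert 0 <= r.bands[95][0] and r.bands[10][0] <= r.median <= r.bands[10][1]


def test_band_nesting_enforced_by_result_type():
    with pytest.raises(ValueError, match="nested"):
        ProjectionResult("s", "31-35", 31, 35, period=debug_truth().grid()[1][0],
                         n_at_risk=10, mean=0.4, median=0.4,
                         bands={10: (0.3, 0.5), 95: (0.35, 0.45)})


def test_insufficient_draws_raise_with_minimum_named(debug_table):
    samples = _frozen_samples(np.log(0.4), np.zeros(4), np.zeros(3), np.zeros(6), copies=50)
    with pytest.raises(ValueError, match="at least 200"):
        project_rates(samples, debug_table, horizon_periods=1, band_levels=(95,))


def test_projection_median_stable_under_thinning(female_fit, female_table):
    full = project_rates(female_fit, female_table, horizon_periods=2, seed=2)
    half = PosteriorSamples(
        spec=female_fit.spec,
        mu=female_fit.mu[::2],
        effects={k: v[::2] for k, v in female_fit.effects.items()},
        taus={k: v[::2] for k, v in female_fit.taus.items()},
        z=None if female_fit.z is None else female_fit.z[::2],
        tau_z=None if female_fit.tau_z is None else female_fit.tau_z[::2],
        chain=female_fit.chain[::2],
        acceptance_rates=female_fit.acceptance_rates,
        seed=female_fit.seed,
    )
    thinned = project_rates(half, female_table, horizon_periods=2, seed=2)
    for a, b in zip(full, thinned):
        assert b.median == pytest.approx(a.median, rel=0.01)


def test_projection_delta_identities(debug_table):
    samples = _frozen_samples(np.log(0.4), np.zeros(4), np.zeros(3), np.zeros(6))
    results = project_rates(samples, debug_table, horizon_periods=1)
    delta = projection_delta(results, debug_table)
    observed = debug_table.y[:, -1] / debug_table.n[:, -1]
    assert np.allclose(delta["delta_rate"], 0.4 - observed, atol=1e-4)
    assert np.allclose(delta["delta_percentage_points"], 100 * delta["delta_rate"])


def test_projection_delta_simple_arithmetic():
    t = make_table([[100]], [[40]])  # baseline rate 0.40
    res = [ProjectionResult("s", "31-35", 31, 35,
                            period=type(t.periods[0])(2, 1996, 2000),
                            n_at_risk=100, mean=0.55, median=0.55, bands={50: (0.5, 0.6)})]
    d = projection_delta(res, t)
    assert d["delta_rate"].iloc[0] == pytest.approx(0.15)
    assert d["delta_percentage_points"].iloc[0] == pytest.approx(15.0)


def test_rising_period_truth_projects_increases(female_fit, female_table):
    """Qualitative direction on the reference truth: projected rates exceed the
    last observed rates for (essentially all) age groups; the oldest groups,
    where the period rise dominates, must all increase."""
    results = project_rates(female_fit, female_table, horizon_periods=2, seed=5)
    delta = projection_delta(results, female_table)
    # cell-level overdispersion perturbs the observed baseline by a few percent,
    # so single cells may dip; the rise must dominate overall and at old ages
    assert (delta["delta_rate"] > 0).sum() >= 11
    assert delta["delta_rate"].mean() > 0.01
    assert (delta["delta_rate"].iloc[-4:] > 0).all()  # ages 81+ unambiguous


def test_projection_frame_schema(debug_fit, debug_table):
    results = project_rates(debug_fit, debug_table, horizon_periods=1)
    df = projection_frame(results)
    assert list(df.columns) == ["stratum", "age_start", "age_end", "period_start",
                                "period_end", "n_at_risk", "mean", "median", "level",
                                "lower", "upper"]
    assert set(df["level"]) == {10, 25, 50, 75, 95}
    assert (df["period_start"] > debug_table.periods[-1].end_year).all()
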