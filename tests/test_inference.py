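"""Sampler correctness, DIC, model selection and effect summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from painapc import (
    APCModelSpec,
    MCMCConfig,
    compute_dic,
    gibbs_update_precision,
    generate_apc_table,
    intercept_only_truth,
    sample_posterior,
    select_model,
    split_rhat,
    summarize_effects,
)
from painapc.inference import PosteriorSamples
from painapc.model import rw_quadratic_form

from _oracles import oracle_dic
from conftest import make_table
from painapc.model import poisson_loglik


# --- conjugate precision updates -------------------------------------------------

def test_precision_draws_positive_and_match_gamma_mean():
    rng = np.random.default_rng(0)
    u = np.arange(8.0)  # linear: RW2 quadratic form is 0
    draws = np.array([gibbs_update_precision(u, 2, (1.0, 0.00005), rng) for _ in range(100_000)])
    assert np.all(draws > 0)
    r = u.size - 2
    shape, rate = 1.0 + r / 2, 0.00005
    se = np.sqrt(shape) / rate / np.sqrt(draws.size)
    assert abs(draws.mean() - shape / rate) < 3 * se


def test_precision_draws_follow_conjugate_gamma():
    rng = np.random.default_rng(1)
    u = np.array([0.0, 0.3, 0.1, 0.6, 0.2])
    order, hyper = 1, (1.0, 0.5)
    draws = np.array([gibbs_update_precision(u, order, hyper, rng) for _ in range(10_000)])
    shape = hyper[0] + (u.size - order) / 2
    rate = hyper[1] + rw_quadratic_form(u, order) / 2
    _, p = stats.kstest(draws, stats.gamma(a=shape, scale=1 / rate).cdf)
    assert p > 0.01


def test_precision_update_rejects_short_vector():
    with pytest.raises(ValueError, match="at least"):
        gibbs_update_precision(np.array([1.0, 2.0]), 2, (1.0, 1.0), np.random.default_rng(0))


# --- sampler ---------------------------------------------------------------------

def test_chains_are_deterministic_under_fixed_seed(debug_table, short_config):
    a = sample_posterior(debug_table, APCModelSpec(), short_config)
    b = sample_posterior(debug_table, APCModelSpec(), short_config)
    assert np.array_equal(a.mu, b.mu)
    for name in a.effects:
        assert np.array_equal(a.effects[name], b.effects[name])
    assert np.array_equal(a.z, b.z)
    assert a.acceptance_rates == b.acceptance_rates


def test_draws_satisfy_sum_to_zero(debug_fit):
    for name, arr in debug_fit.effects.items():
        assert np.max(np.abs(arr.mean(axis=1))) < 1e-10, name


def test_intercept_recovery_on_flat_data():
    """With no true structure the posterior of mu centres on log(sum y / sum n)."""
    table = generate_apc_table(intercept_only_truth(rate=0.445, n_per_cell=20_000))
    spec = APCModelSpec(overdispersion=False)
    cfg = MCMCConfig(n_iterations=2500, n_burnin=1000, thinning=3, n_chains=1, seed=9)
    fit = sample_posterior(table, spec, cfg)
    target = np.log(table.y.sum() / table.n.sum())
    assert abs(fit.mu.mean() - target) < 3 * fit.mu.std()


def test_acceptance_rates_in_adapted_range(debug_fit):
    for block, rate in debug_fit.acceptance_rates.items():
        assert 0.1 < rate < 0.7, (block, rate)


def test_split_rhat_near_one_on_debug_table(debug_table):
    cfg = MCMCConfig(n_iterations=3000, n_burnin=1000, thinning=2, n_chains=2, seed=33)
    fit = sample_posterior(debug_table, APCModelSpec(), cfg)
    rhat = split_rhat(fit)
    assert all(v < 1.05 for v in rhat.values()), rhat


def test_sampler_matches_grid_quadrature_on_reduced_model():
    """Desk-scale validation: a 2x2 age-period model with precisions pinned by a
    near-degenerate hyperprior, compared against dense-grid numerical posterior."""
    tau0 = 100.0
    rng = np.random.default_rng(12)
    n = np.full((2, 2), 500)
    y = rng.binomial(n, [[0.35, 0.38], [0.40, 0.44]])
    table = make_table(n, y)
    spec = APCModelSpec(
        effects=("age", "period"),
        rw_order={"age": 1, "period": 1},
        effect_hyperprior=(1e6, 1e6 / tau0),  # tau concentrated at tau0
        overdispersion=False,
    )
    # brute-force posterior on (mu, a, b) with alpha=(-a, a), beta=(-b, b)
    mu_g = np.linspace(-1.3, -0.5, 121)
    a_g = np.linspace(-0.12, 0.12, 101)
    b_g = np.linspace(-0.12, 0.12, 101)
    MU, A, B = np.meshgrid(mu_g, a_g, b_g, indexing="ij")
    ll = np.zeros_like(MU)
    for i, si in enumerate((-1, 1)):
        for j, sj in enumerate((-1, 1)):
            eta = MU + si * A + sj * B
            mean = n[i, j] * np.exp(eta)
            ll += y[i, j] * np.log(mean) - mean
    ll += -tau0 / 2 * (4 * A**2) - tau0 / 2 * (4 * B**2)
    w = np.exp(ll - ll.max())
    w /= w.sum()
    quad = {
        "mu": float((w * MU).sum()),
        "a": float((w * A).sum()),
        "b": float((w * B).sum()),
    }
    sd = {
        "mu": float(np.sqrt((w * (MU - quad["mu"]) ** 2).sum())),
        "a": float(np.sqrt((w * (A - quad["a"]) ** 2).sum())),
        "b": float(np.sqrt((w * (B - quad["b"]) ** 2).sum())),
    }
    cfg = MCMCConfig(n_iterations=120_000, n_burnin=20_000, thinning=10, n_chains=1, seed=4)
    fit = sample_posterior(table, spec, cfg)
    est = {
        "mu": fit.mu.mean(),
        "a": fit.effects["age"][:, 1].mean(),
        "b": fit.effects["period"][:, 1].mean(),
    }
    for k in quad:
        assert abs(est[k] - quad[k]) < 0.02 * max(abs(quad[k]), sd[k]), (k, est[k], quad[k])


# --- DIC -------------------------------------------------------------------------

def _degenerate_samples(params_like, spec, copies=6):
    """A PosteriorSamples whose draws are all identical to one parameter set."""
    mu = np.full(copies, params_like.mu)
    effects = {"age": np.tile(params_like.alpha, (copies, 1))}
    taus = {"age": np.full(copies, params_like.tau_alpha)}
    if params_like.beta is not None:
        effects["period"] = np.tile(params_like.beta, (copies, 1))
        taus["period"] = np.full(copies, params_like.tau_beta)
    if params_like.gamma is not None:
        effects["cohort"] = np.tile(params_like.gamma, (copies, 1))
        taus["cohort"] = np.full(copies, params_like.tau_gamma)
    return PosteriorSamples(
        spec=spec, mu=mu, effects=effects, taus=taus, z=None, tau_z=None,
        chain=np.zeros(copies, dtype=int), acceptance_rates={}, seed=0,
    )


def test_dic_degenerate_draws_give_zero_pd(debug_table):
    from conftest import random_params

    spec = APCModelSpec(overdispersion=False)
    p = random_params(np.random.default_rng(5), debug_table.I, debug_table.J, spec)
    samples = _degenerate_samples(p, spec)
    dic = compute_dic(samples, debug_table)
    assert dic.p_d == pytest.approx(0.0, abs=1e-8)
    assert dic.dic == pytest.approx(-2 * poisson_loglik(debug_table, p), rel=1e-10)
    # thinning a deterministic repeated-draw list changes nothing
    thinned = _degenerate_samples(p, spec, copies=3)
    assert compute_dic(thinned, debug_table).dic == pytest.approx(dic.dic, rel=1e-10)


def test_dic_matches_independent_recomputation(debug_fit, debug_table):
    dic = compute_dic(debug_fit, debug_table)
    lls = [poisson_loglik(debug_table, debug_fit[s]) for s in range(len(debug_fit))]
    ll_at_mean = poisson_loglik(debug_table, debug_fit.posterior_mean_params())
    odic, opd, omean = oracle_dic(lls, ll_at_mean)
    assert dic.dic == pytest.approx(odic, rel=1e-8)
    assert dic.p_d == pytest.approx(opd, rel=1e-8)
    assert dic.mean_deviance == pytest.approx(omean, rel=1e-8)


# --- model selection -------------------------------------------------------------

def test_select_model_single_candidate(debug_table, short_config):
    spec = APCModelSpec(overdispersion=False)
    sel = select_model(debug_table, [spec], short_config)
    assert sel.chosen == spec
    assert len(sel.dic_table) == 1 and sel.dic_table["selected"].all()


def test_select_model_prefers_full_rw2_on_near_tie(debug_table, monkeypatch):
    """DICs 100.0 vs 100.5 within the threshold: the full APC/RW2 model wins."""
    import painapc.inference as inf

    full = APCModelSpec()
    ap = APCModelSpec(effects=("age", "period"), rw_order={"age": 2, "period": 2})
    fixed = {ap.label: 100.0, full.label: 100.5}
    monkeypatch.setattr(inf, "sample_posterior", lambda table, spec, config: spec)
    monkeypatch.setattr(
        inf, "compute_dic", lambda fit, table: inf.DICResult(fixed[fit.label], 1.0, fixed[fit.label] - 1)
    )
    sel = inf.select_model(debug_table, [ap, full], MCMCConfig())
    assert sel.chosen == full
    # outside the threshold the minimum wins
    fixed[full.label] = 103.0
    sel = inf.select_model(debug_table, [ap, full], MCMCConfig())
    assert sel.chosen == ap


def test_select_model_flags_failed_fit(debug_table, monkeypatch):
    import painapc.inference as inf

    good = APCModelSpec(effects=("age", "period"), rw_order={"age": 1, "period": 1})
    bad = APCModelSpec(effects=("age", "cohort"), rw_order={"age": 1, "cohort": 1})

    def fake_fit(table, spec, config):
        if spec == bad:
            raise RuntimeError("boom")
        return spec

    monkeypatch.setattr(inf, "sample_posterior", fake_fit)
    monkeypatch.setattr(inf, "compute_dic", lambda fit, table: inf.DICResult(50.0, 1.0, 49.0))
    with pytest.warns(UserWarning, match="failed"):
        sel = inf.select_model(debug_table, [good, bad], MCMCConfig())
    assert sel.chosen == good
    assert sel.dic_table["failed"].tolist() == [False, True]


def test_select_model_rejects_empty_candidates(debug_table):
    with pytest.raises(ValueError, match="empty"):
        select_model(debug_table, [])


# --- summaries -------------------------------------------------------------------

def test_summaries_of_zero_draws_give_unit_rate_ratios(debug_table):
    spec = APCModelSpec(overdispersion=False)
    from painapc import APCParams

    p = APCParams(mu=0.0, alpha=np.zeros(4), beta=np.zeros(3), gamma=np.zeros(6),
                  tau_beta=1.0, tau_gamma=1.0)
    samples = _degenerate_samples(p, spec)
    for summ in summarize_effects(samples):
        assert np.allclose(summ.mean_rr, 1.0)
        assert np.allclose(summ.lower_rr, 1.0)


def test_rate_ratio_products_and_quantile_equivariance(debug_fit, debug_table):
    """Sum-to-zero makes per-draw RR products 1; medians commute with exp."""
    for name, arr in debug_fit.effects.items():
        prod = np.exp(arr).prod(axis=1)
        assert np.allclose(prod, 1.0, atol=1e-8), name
    summaries = {s.effect: s for s in summarize_effects(debug_fit, table=debug_table)}
    for name, s in summaries.items():
        assert np.allclose(s.median_rr, np.exp(s.median_log), rtol=1e-12)
    assert summaries["age"].labels[0] == "31-35"
    for s in summaries.values():
        assert np.all(s.lower_log <= s.median_log) and np.all(s.median_log <= s.upper_log)
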