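"""Posterior sampling, DIC model selection and effect summaries for the APC model.

Inference is by Metropolis-within-Gibbs: conjugate Gamma draws for the
random-walk and overdispersion precisions, Gaussian random-walk Metropolis for
the intercept and for each level of the age, period and cohort effects, and a
vectorised Metropolis sweep for the cell-level overdispersion effects (which
are conditionally independent given the rest).  Proposal scales are adapted
toward a 20-40% acceptance rate during burn-in and frozen afterwards.

Identifiability.  The three time scales are linearly dependent
(cohort = period - age), so each effect vector is hard re-centred to sum to
zero after every sweep, with the subtracted mean absorbed into the intercept.
When the full APC model carries RW2 priors on all three effects the posterior
is additionally flat along the exact reparametrisation
(alpha_i + g*M*i, beta_j - g*j, gamma_k + g*k), because RW2 does not penalise
linear trends; each retained state is therefore renormalised onto the
canonical section where the cohort effect has zero linear trend.  Both
operations leave the likelihood and the prior density unchanged; they fix the
reported parametrisation, under which per-level summaries are well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .lexis import APCTable, birth_interval, count_cohorts
from .model import (
    APCModelSpec,
    APCParams,
    eta_matrix,
    poisson_loglik,
    rw_quadratic_form,
)

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "EffectSummary",
    "DICResult",
    "ModelSelection",
    "gibbs_update_precision",
    "sample_posterior",
    "compute_dic",
    "select_model",
    "summarize_effects",
    "split_rhat",
]

_DEFAULT_SCALES = {"mu": 0.01, "age": 0.05, "period": 0.05, "cohort": 0.05, "z": 0.1}


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings: chain length, burn-in, thinning, proposal scales, seed."""

    n_iterations: int = 50_000
    n_burnin: int = 10_000
    thinning: int = 10
    n_chains: int = 2
    seed: int = 0
    proposal_scales: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SCALES))
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.n_burnin < 0 or self.thinning <= 0 or self.n_chains <= 0:
            raise ValueError("iteration counts, thinning and chains must be positive")
        if self.n_burnin >= self.n_iterations:
            raise ValueError(
                f"n_burnin ({self.n_burnin}) must be < n_iterations ({self.n_iterations})"
            )
        scales = dict(_DEFAULT_SCALES)
        scales.update(self.proposal_scales)
        if any(s <= 0 for s in scales.values()):
            raise ValueError("proposal scales must be positive")
        object.__setattr__(self, "proposal_scales", scales)

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin + self.thinning - 1) // self.thinning


@dataclass
class PosteriorSamples:
    """Ordered posterior draws (all chains concatenated) with chain metadata."""

    spec: APCModelSpec
    mu: np.ndarray                      # (S,)
    effects: dict[str, np.ndarray]      # name -> (S, m)
    taus: dict[str, np.ndarray]         # name -> (S,)
    z: np.ndarray | None                # (S, I, J) or None
    tau_z: np.ndarray | None            # (S,) or None
    chain: np.ndarray                   # (S,) chain id of each draw
    acceptance_rates: dict[str, float]
    seed: int

    def __len__(self) -> int:
        return self.mu.size

    def __getitem__(self, s: int) -> APCParams:
        eff = self.effects
        return APCParams(
            mu=float(self.mu[s]),
            alpha=eff["age"][s],
            beta=eff["period"][s] if "period" in eff else None,
            gamma=eff["cohort"][s] if "cohort" in eff else None,
            z=None if self.z is None else self.z[s],
            tau_alpha=float(self.taus["age"][s]),
            tau_beta=float(self.taus["period"][s]) if "period" in self.taus else None,
            tau_gamma=float(self.taus["cohort"][s]) if "cohort" in self.taus else None,
            tau_z=None if self.tau_z is None else float(self.tau_z[s]),
        )

    @property
    def draws(self) -> list[APCParams]:
        return [self[s] for s in range(len(self))]

    def posterior_mean_params(self) -> APCParams:
        """Plug-in parameter estimate: element-wise posterior mean, re-centred."""
        eff_mean = {}
        for name, arr in self.effects.items():
            m = arr.mean(axis=0)
            eff_mean[name] = m - m.mean()
        return APCParams(
            mu=float(self.mu.mean() + sum(a.mean(axis=0).mean() for a in self.effects.values())),
            alpha=eff_mean["age"],
            beta=eff_mean.get("period"),
            gamma=eff_mean.get("cohort"),
            z=None if self.z is None else self.z.mean(axis=0),
            tau_alpha=float(self.taus["age"].mean()),
            tau_beta=float(self.taus["period"].mean()) if "period" in self.taus else None,
            tau_gamma=float(self.taus["cohort"].mean()) if "cohort" in self.taus else None,
            tau_z=None if self.tau_z is None else float(self.tau_z.mean()),
        )


def gibbs_update_precision(
    u: np.ndarray, order: int, hyper: tuple[float, float], rng: np.random.Generator
) -> float:
    """Conjugate Gamma draw for a random-walk precision.

    Full conditional: Gamma(shape + r/2, rate + q/2) with r = len(u) - order
    and q the RW quadratic form of u.
    """
    shape, rate = hyper
    q = rw_quadratic_form(u, order)  # validates length
    r = u.size - order
    return float(rng.gamma(shape + 0.5 * r, 1.0 / (rate + 0.5 * q)))


class _ChainState:
    """Mutable sampler state for one chain, with the exposure cache E = n*exp(eta)."""

    def __init__(self, table: APCTable, spec: APCModelSpec):
        self.table = table
        self.spec = spec
        I, J = table.I, table.J
        self.sizes = {"age": I}
        self.level_cells: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        self.level_y: dict[str, np.ndarray] = {}
        # age levels = rows, period levels = columns, cohort levels = diagonals
        self.level_cells["age"] = [
            (np.full(J, i), np.arange(J)) for i in range(I)
        ]
        self.level_y["age"] = table.y.sum(axis=1).astype(float)
        if "period" in spec.effects:
            self.sizes["period"] = J
            self.level_cells["period"] = [(np.arange(I), np.full(I, j)) for j in range(J)]
            self.level_y["period"] = table.y.sum(axis=0).astype(float)
        if "cohort" in spec.effects:
            M = table._require_m()
            K = count_cohorts(I, J, M)
            self.sizes["cohort"] = K
            i = np.arange(1, I + 1)[:, None]
            j = np.arange(1, J + 1)[None, :]
            self.kmap = M * (I - i) + j - 1  # 0-based
            self.level_cells["cohort"] = [
                tuple(np.nonzero(self.kmap == k)) for k in range(K)
            ]
            self.level_y["cohort"] = np.bincount(
                self.kmap.ravel(), weights=table.y.ravel(), minlength=K
            )
            self.M = M
        self.y_total = float(table.y.sum())

        ytot, ntot = table.y.sum(), table.n.sum()
        self.mu = float(np.log((ytot + 0.5) / (ntot + 1.0)))
        self.u: dict[str, np.ndarray] = {}
        for name in spec.effects:
            self.u[name] = self._margin_init(name)
        self.z = np.zeros((I, J)) if spec.overdispersion else None
        self.tau: dict[str, float] = {}
        for name in spec.effects:
            q = rw_quadratic_form(self.u[name], spec.rw_order[name])
            r = self.u[name].size - spec.rw_order[name]
            shape, rate = spec.effect_hyperprior
            self.tau[name] = (shape + 0.5 * r) / (rate + 0.5 * q)  # conditional mean
        self.tau_z = (
            spec.overdispersion_hyperprior[0] / spec.overdispersion_hyperprior[1]
            if spec.overdispersion
            else None
        )
        self.refresh_exposure()
        if not np.all(np.isfinite(self.E)):
            raise RuntimeError("non-finite log posterior at initialisation; re-initialise")

    def _margin_init(self, name: str) -> np.ndarray:
        """Rough data-driven start: centred marginal log rates (0 where empty)."""
        t = self.table
        if name == "age":
            num, den = t.y.sum(axis=1), t.n.sum(axis=1)
        elif name == "period":
            num, den = t.y.sum(axis=0), t.n.sum(axis=0)
        else:
            K = self.sizes["cohort"]
            num = np.bincount(self.kmap.ravel(), weights=t.y.ravel(), minlength=K)
            den = np.bincount(self.kmap.ravel(), weights=t.n.ravel(), minlength=K)
        logr = np.where(den > 0, np.log((num + 0.5) / (den + 1.0)), self.mu)
        u = logr - self.mu
        return u - u.mean()

    def params(self) -> APCParams:
        u = {n: v - v.mean() for n, v in self.u.items()}  # guard fp drift
        return APCParams(
            mu=self.mu + sum(float(v.mean()) for v in self.u.values()),
            alpha=u["age"],
            beta=u.get("period"),
            gamma=u.get("cohort"),
            z=None if self.z is None else self.z.copy(),
            tau_alpha=self.tau["age"],
            tau_beta=self.tau.get("period"),
            tau_gamma=self.tau.get("cohort"),
            tau_z=self.tau_z,
        )

    def eta(self) -> np.ndarray:
        t = self.table
        eta = np.full((t.I, t.J), self.mu) + self.u["age"][:, None]
        if "period" in self.u:
            eta += self.u["period"][None, :]
        if "cohort" in self.u:
            eta += self.u["cohort"][self.kmap]
        if self.z is not None:
            eta += self.z
        return eta

    def refresh_exposure(self) -> None:
        self.E = self.table.n * np.exp(self.eta())


def _run_chain(
    table: APCTable,
    spec: APCModelSpec,
    config: MCMCConfig,
    rng: np.random.Generator,
) -> tuple[dict, dict[str, float]]:
    st = _ChainState(table, spec)
    scales = dict(config.proposal_scales)
    blocks = ["mu"] + list(spec.effects) + (["z"] if spec.overdispersion else [])
    prop = {b: 0 for b in blocks}
    acc = {b: 0 for b in blocks}
    win_prop = {b: 0 for b in blocks}
    win_acc = {b: 0 for b in blocks}

    full_rw2 = set(spec.effects) == {"age", "period", "cohort"} and all(
        spec.rw_order[e] == 2 for e in spec.effects
    )

    S = config.n_retained_per_chain
    out = {
        "mu": np.empty(S),
        "effects": {n: np.empty((S, st.sizes[n])) for n in spec.effects},
        "taus": {n: np.empty(S) for n in spec.effects},
        "z": np.empty((S, table.I, table.J)) if spec.overdispersion else None,
        "tau_z": np.empty(S) if spec.overdispersion else None,
    }
    s_out = 0
    eshape, erate = spec.effect_hyperprior

    for t_iter in range(config.n_iterations):
        burnin = t_iter < config.n_burnin

        # --- intercept (flat prior) ---
        d = rng.normal(0.0, scales["mu"])
        dll = st.y_total * d - (np.expm1(d)) * st.E.sum()
        prop["mu"] += not burnin
        win_prop["mu"] += 1
        if np.log(rng.uniform()) < dll:
            st.mu += d
            st.E *= np.exp(d)
            acc["mu"] += not burnin
            win_acc["mu"] += 1

        # --- effect levels, single-site Metropolis ---
        for name in spec.effects:
            u = st.u[name]
            order = spec.rw_order[name]
            tau = st.tau[name]
            q_old = rw_quadratic_form(u, order)
            cells = st.level_cells[name]
            ylev = st.level_y[name]
            deltas = rng.normal(0.0, scales[name], size=u.size)
            logus = np.log(rng.uniform(size=u.size))
            n_acc = 0
            for lev in range(u.size):
                d = deltas[lev]
                rows, cols = cells[lev]
                esum = st.E[rows, cols].sum()
                old = u[lev]
                u[lev] = old + d
                q_new = rw_quadratic_form(u, order)
                dlp = ylev[lev] * d - np.expm1(d) * esum - 0.5 * tau * (q_new - q_old)
                if logus[lev] < dlp:
                    st.E[rows, cols] *= np.exp(d)
                    q_old = q_new
                    n_acc += 1
                else:
                    u[lev] = old
            prop[name] += 0 if burnin else u.size
            acc[name] += 0 if burnin else n_acc
            win_prop[name] += u.size
            win_acc[name] += n_acc
            # re-centre; mean absorbed into the intercept (eta unchanged)
            mbar = u.mean()
            u -= mbar
            st.mu += mbar

        # --- overdispersion: conditionally independent cells, vectorised ---
        if spec.overdispersion:
            d = rng.normal(0.0, scales["z"], size=st.z.shape)
            dlp = (
                table.y * d
                - st.E * np.expm1(d)
                - 0.5 * st.tau_z * ((st.z + d) ** 2 - st.z**2)
            )
            accept = np.log(rng.uniform(size=st.z.shape)) < dlp
            st.z[accept] += d[accept]
            st.E[accept] *= np.exp(d[accept])
            n_acc = int(accept.sum())
            prop["z"] += 0 if burnin else st.z.size
            acc["z"] += 0 if burnin else n_acc
            win_prop["z"] += st.z.size
            win_acc["z"] += n_acc

        # --- precisions: conjugate Gibbs ---
        for name in spec.effects:
            st.tau[name] = gibbs_update_precision(
                st.u[name], spec.rw_order[name], (eshape, erate), rng
            )
        if spec.overdispersion:
            zshape, zrate = spec.overdispersion_hyperprior
            st.tau_z = float(
                rng.gamma(zshape + 0.5 * st.z.size, 1.0 / (zrate + 0.5 * float(np.sum(st.z**2))))
            )

        # --- canonical section for the RW2-flat APC direction ---
        if full_rw2:
            _normalize_linear_trend(st)

        # --- proposal adaptation during burn-in ---
        if config.adapt and burnin and (t_iter + 1) % 50 == 0:
            for b in blocks:
                if win_prop[b]:
                    rate = win_acc[b] / win_prop[b]
                    scales[b] = float(np.clip(scales[b] * np.exp(rate - 0.3), 1e-4, 5.0))
                win_prop[b] = 0
                win_acc[b] = 0

        if (t_iter + 1) % 1000 == 0:  # guard against multiplicative fp drift in E
            st.refresh_exposure()

        if not burnin and (t_iter - config.n_burnin) % config.thinning == 0:
            out["mu"][s_out] = st.mu + sum(float(v.mean()) for v in st.u.values())
            for name in spec.effects:
                out["effects"][name][s_out] = st.u[name] - st.u[name].mean()
                out["taus"][name][s_out] = st.tau[name]
            if spec.overdispersion:
                out["z"][s_out] = st.z
                out["tau_z"][s_out] = st.tau_z
            s_out += 1

    rates = {b: (acc[b] / prop[b] if prop[b] else float("nan")) for b in blocks}
    return out, rates


def _normalize_linear_trend(st: _ChainState) -> None:
    """Project the state onto the section where gamma has zero linear trend.

    Applies the likelihood-invariant reparametrisation
    (alpha_i + g*M*i, beta_j - g*j, gamma_k + g*k, mu - g*M*I) with g chosen to
    zero gamma's least-squares slope; the RW2 prior is flat along it.
    """
    gam = st.u["cohort"]
    K = gam.size
    kc = np.arange(1, K + 1, dtype=float)
    kc -= kc.mean()
    g = -float(kc @ gam) / float(kc @ kc)
    I = st.table.I
    M = st.M
    st.u["age"] += g * M * np.arange(1, I + 1)
    st.u["period"] -= g * np.arange(1, st.table.J + 1)
    st.u["cohort"] += g * np.arange(1, K + 1)
    st.mu -= g * M * I
    for name in ("age", "period", "cohort"):
        mbar = st.u[name].mean()
        st.u[name] -= mbar
        st.mu += mbar


def sample_posterior(
    table: APCTable, spec: APCModelSpec, config: MCMCConfig | None = None
) -> PosteriorSamples:
    """Draw posterior samples for the APC model on one table.

    Runs ``config.n_chains`` independent chains (seeded from ``config.seed``),
    discards burn-in, thins, and concatenates the retained draws.  Identical
    (table, spec, config) always yields identical draws.
    """
    config = config or MCMCConfig()
    if np.any((table.n == 0) & (table.y > 0)):
        raise ValueError("table has events in cells with no subjects at risk")
    chains = []
    rates_acc: dict[str, list[float]] = {}
    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        out, rates = _run_chain(table, spec, config, rng)
        chains.append(out)
        for b, r in rates.items():
            rates_acc.setdefault(b, []).append(r)
    cat = lambda key: np.concatenate([ch[key] for ch in chains], axis=0)  # noqa: E731
    S = config.n_retained_per_chain
    return PosteriorSamples(
        spec=spec,
        mu=cat("mu"),
        effects={n: np.concatenate([ch["effects"][n] for ch in chains]) for n in spec.effects},
        taus={n: np.concatenate([ch["taus"][n] for ch in chains]) for n in spec.effects},
        z=cat("z") if spec.overdispersion else None,
        tau_z=cat("tau_z") if spec.overdispersion else None,
        chain=np.repeat(np.arange(config.n_chains), S),
        acceptance_rates={b: float(np.mean(v)) for b, v in rates_acc.items()},
        seed=config.seed,
    )


class DICResult(NamedTuple):
    dic: float
    p_d: float
    mean_deviance: float


def compute_dic(samples: PosteriorSamples, table: APCTable) -> DICResult:
    """Deviance information criterion from posterior draws.

    D(theta) = -2 * log likelihood; DIC = mean deviance + pD with
    pD = mean deviance - D(posterior mean).  pD is reported even if negative.
    """
    dev = np.array([-2.0 * poisson_loglik(table, samples[s]) for s in range(len(samples))])
    mean_dev = float(dev.mean())
    d_hat = -2.0 * poisson_loglik(table, samples.posterior_mean_params())
    p_d = mean_dev - d_hat
    return DICResult(dic=mean_dev + p_d, p_d=p_d, mean_deviance=mean_dev)


@dataclass
class ModelSelection:
    """Outcome of DIC-based model comparison."""

    chosen: APCModelSpec
    dic_table: pd.DataFrame
    fits: dict[str, PosteriorSamples]


def select_model(
    table: APCTable,
    candidates: Sequence[APCModelSpec],
    config: MCMCConfig | None = None,
    near_tie_threshold: float = 2.0,
) -> ModelSelection:
    """Fit every candidate and pick the lowest-DIC specification.

    If a full-APC candidate with RW2 priors on all effects comes within
    ``near_tie_threshold`` of the minimum DIC it is chosen instead — on a near
    tie the complete model with RW2 priors is the preferred smoothing target.
    Failed fits are flagged with a warning and excluded from the comparison.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    config = config or MCMCConfig()
    rows = []
    fits: dict[str, PosteriorSamples] = {}
    for idx, spec in enumerate(candidates):
        label = spec.label
        try:
            fit = sample_posterior(table, spec, config)
            dic = compute_dic(fit, table)
            fits[label] = fit
            rows.append((label, spec, dic.dic, dic.p_d, dic.mean_deviance, False))
        except Exception as exc:  # noqa: BLE001 - flagged, selection proceeds
            warnings.warn(f"candidate {label} failed to fit: {exc}", stacklevel=2)
            rows.append((label, spec, np.nan, np.nan, np.nan, True))
    ok = [r for r in rows if not r[5]]
    if not ok:
        raise RuntimeError("all candidate fits failed")
    best = min(ok, key=lambda r: r[2])
    chosen = best[1]
    full_rw2 = [
        r
        for r in ok
        if set(r[1].effects) == set(("age", "period", "cohort"))
        and all(r[1].rw_order[e] == 2 for e in r[1].effects)
    ]
    if full_rw2:
        near = [r for r in full_rw2 if r[2] - best[2] <= near_tie_threshold]
        if near:
            chosen = min(near, key=lambda r: r[2])[1]
    df = pd.DataFrame(
        [
            {
                "spec_id": label,
                "effects": "+".join(spec.effects),
                "rw_order": "/".join(str(spec.rw_order[e]) for e in spec.effects),
                "DIC": dic,
                "pD": pd_,
                "mean_deviance": mdev,
                "selected": (spec is chosen),
                "failed": failed,
            }
            for label, spec, dic, pd_, mdev, failed in rows
        ]
    )
    return ModelSelection(chosen=chosen, dic_table=df, fits=fits)


@dataclass
class EffectSummary:
    """Posterior summary of one effect, per level, on log and rate-ratio scales."""

    effect: str
    labels: list[str]
    mean_log: np.ndarray
    median_log: np.ndarray
    lower_log: np.ndarray
    upper_log: np.ndarray
    mean_rr: np.ndarray
    median_rr: np.ndarray
    lower_rr: np.ndarray
    upper_rr: np.ndarray
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": self.effect,
                "level_label": self.labels,
                "mean_log": self.mean_log,
                "median_log": self.median_log,
                "lower_log": self.lower_log,
                "upper_log": self.upper_log,
                "mean_RR": self.mean_rr,
                "median_RR": self.median_rr,
                "lower_RR": self.lower_rr,
                "upper_RR": self.upper_rr,
            }
        )


def _effect_labels(name: str, m: int, table: APCTable | None) -> list[str]:
    if table is None:
        return [str(i + 1) for i in range(m)]
    if name == "age":
        return [a.label for a in table.age_groups]
    if name == "period":
        return [p.label for p in table.periods]
    return ["{}-{}".format(*birth_interval(table, k)) for k in range(1, m + 1)]


def summarize_effects(
    samples: PosteriorSamples, level: float = 0.95, table: APCTable | None = None
) -> list[EffectSummary]:
    """Per-level posterior mean, median and central credible interval.

    Rate ratios RR = exp(effect) are computed per draw and then summarised, so
    the RR median equals exp(log-scale median) and, per draw, the product of
    RR over an effect's levels is 1 (the sum-to-zero constraint).
    """
    if len(samples) == 0:
        raise ValueError("no posterior draws to summarise")
    qlo, qhi = 0.5 - level / 2, 0.5 + level / 2
    out = []
    for name, arr in samples.effects.items():
        rr = np.exp(arr)
        out.append(
            EffectSummary(
                effect=name,
                labels=_effect_labels(name, arr.shape[1], table),
                mean_log=arr.mean(axis=0),
                median_log=np.median(arr, axis=0),
                lower_log=np.quantile(arr, qlo, axis=0),
                upper_log=np.quantile(arr, qhi, axis=0),
                mean_rr=rr.mean(axis=0),
                median_rr=np.median(rr, axis=0),
                lower_rr=np.quantile(rr, qlo, axis=0),
                upper_rr=np.quantile(rr, qhi, axis=0),
                level=level,
            )
        )
    return out


def split_rhat(samples: PosteriorSamples, variables: Sequence[str] | None = None) -> dict[str, float]:
    """Split-R-hat convergence diagnostic (via arviz) for scalar chain quantities.

    Defaults to the intercept and every precision.
    """
    import arviz as az

    n_chains = int(samples.chain.max()) + 1
    per = len(samples) // n_chains
    if variables is None:
        variables = ["mu"] + [f"tau_{n}" for n in samples.taus] + (
            ["tau_z"] if samples.tau_z is not None else []
        )
    series: dict[str, np.ndarray] = {"mu": samples.mu}
    for n, arr in samples.taus.items():
        series[f"tau_{n}"] = arr
    if samples.tau_z is not None:
        series["tau_z"] = samples.tau_z
    data = {v: series[v].reshape(n_chains, per) for v in variables}
    rhat = az.rhat(az.convert_to_dataset(data))
    return {v: float(rhat[v].values) for v in variables}
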