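"""Rate projections by random-walk extrapolation of period and cohort effects.

Projections propagate each posterior draw forward: the period effect is
extended by H future periods, and the cohort effect by the new birth-cohort
diagonals entering the Lexis grid, using the predictive distribution of the
fitted random walk —

    RW1:  u_{m+h} ~ Normal(u_{m+h-1}, 1/tau)
    RW2:  u_{m+h} ~ Normal(2 u_{m+h-1} - u_{m+h-2}, 1/tau)

so RW2 continues the local linear trend of the log rate while RW1 continues
the last level.  The extended portion is not re-centred (the constraint binds
over the observed range only).  Rates for every (age group, future period)
cell are computed per draw and summarised with nested central credible bands;
at-risk counts are carried forward from the last observed period by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .lexis import APCTable, Period, count_cohorts, observed_rates
from .inference import PosteriorSamples

__all__ = [
    "ProjectionResult",
    "extend_random_walk",
    "project_rates",
    "projection_delta",
    "projection_frame",
    "write_projection_csv",
]

DEFAULT_BAND_LEVELS = (10, 25, 50, 75, 95)


@dataclass
class ProjectionResult:
    """Predictive rate summary for one (age group, future period) cell."""

    stratum: str
    age_label: str
    age_start: int
    age_end: int
    period: Period
    n_at_risk: int
    mean: float
    median: float
    bands: dict[int, tuple[float, float]]

    def __post_init__(self) -> None:
        levels = sorted(self.bands)
        for lo_lev, hi_lev in zip(levels, levels[1:]):
            lo1, hi1 = self.bands[lo_lev]
            lo2, hi2 = self.bands[hi_lev]
            if not (lo2 <= lo1 and hi1 <= hi2):
                raise ValueError(f"credible bands not nested at levels {lo_lev} < {hi_lev}")


def extend_random_walk(
    u_draws: np.ndarray,
    tau_draws: np.ndarray,
    order: int,
    horizon: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Extend each draw's effect vector by ``horizon`` RW-predictive steps.

    ``u_draws`` has shape (S, m); returns shape (S, m + horizon).  Step h draws
    from Normal(u_{m+h-1}, 1/tau) for RW1 and Normal(2u_{m+h-1} - u_{m+h-2},
    1/tau) for RW2, per draw, using that draw's precision.
    """
    u_draws = np.atleast_2d(np.asarray(u_draws, dtype=float))
    tau_draws = np.asarray(tau_draws, dtype=float)
    if order not in (1, 2):
        raise ValueError(f"RW order must be 1 or 2, got {order}")
    if u_draws.shape[1] < order:
        raise ValueError(f"need at least {order} observed values to extend an RW{order}")
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if horizon == 0:
        return u_draws.copy()
    S, m = u_draws.shape
    out = np.concatenate([u_draws, np.empty((S, horizon))], axis=1)
    sd = 1.0 / np.sqrt(tau_draws)
    for h in range(horizon):
        t = m + h
        mean = out[:, t - 1] if order == 1 else 2.0 * out[:, t - 1] - out[:, t - 2]
        out[:, t] = mean + sd * rng.standard_normal(S)
    return out


def _future_periods(table: APCTable, horizon: int) -> list[Period]:
    last = table.periods[-1]
    w = table.period_width
    return [
        Period(last.index + h, last.start_year + w * h, last.end_year + w * h)
        for h in range(1, horizon + 1)
    ]


def project_rates(
    samples: PosteriorSamples,
    table: APCTable,
    horizon_periods: int = 2,
    band_levels: Sequence[int] = DEFAULT_BAND_LEVELS,
    at_risk_policy: Literal["carry_forward"] | np.ndarray = "carry_forward",
    include_overdispersion: bool = True,
    seed: int = 0,
) -> list[ProjectionResult]:
    """Project rates ``horizon_periods`` periods beyond the observed table.

    Per posterior draw the period effect is extended by the horizon and the
    cohort effect by the new diagonals entering the grid; the projected rate of
    cell (i, J+h) is exp(mu + alpha_i + beta_{J+h} + gamma_k (+ fresh z)).
    Draws are summarised into the predictive mean, median and central credible
    bands at ``band_levels`` (percent).  At-risk counts are carried forward
    from the last observed period, or supplied as a length-I array.
    """
    if horizon_periods < 1:
        raise ValueError("horizon_periods must be >= 1")
    S = len(samples)
    max_level = max(band_levels)
    # at least 5 draws beyond each tail of the widest band
    min_draws = int(np.ceil(10.0 / (1.0 - max_level / 100.0)))
    if S < min_draws:
        raise ValueError(
            f"{S} draws cannot resolve a {max_level}% band; need at least {min_draws}"
        )
    rng = np.random.default_rng(seed)
    I, J = table.I, table.J
    H = horizon_periods
    spec = samples.spec

    if "period" in samples.effects:
        beta_ext = extend_random_walk(
            samples.effects["period"], samples.taus["period"], spec.rw_order["period"], H, rng
        )
    else:
        beta_ext = None
    if "cohort" in samples.effects:
        M = table._require_m()
        K_obs = count_cohorts(I, J, M)
        K_new = M * (I - 1) + (J + H)  # largest diagonal on the extended grid
        gamma_ext = extend_random_walk(
            samples.effects["cohort"], samples.taus["cohort"], spec.rw_order["cohort"],
            K_new - K_obs, rng,
        )
    else:
        gamma_ext = None

    if isinstance(at_risk_policy, str):
        if at_risk_policy != "carry_forward":
            raise ValueError(f"unknown at_risk_policy {at_risk_policy!r}")
        n_future = table.n[:, -1]
    else:
        n_future = np.asarray(at_risk_policy, dtype=np.int64)
        if n_future.shape != (I,):
            raise ValueError(f"at-risk array must have length I={I}")

    periods = _future_periods(table, H)
    results = []
    for h in range(1, H + 1):
        eta = samples.mu[:, None] + samples.effects["age"]  # (S, I)
        if beta_ext is not None:
            eta = eta + beta_ext[:, J + h - 1][:, None]
        if gamma_ext is not None:
            i_idx = np.arange(1, I + 1)
            k_idx = M * (I - i_idx) + (J + h)  # 1-based diagonal per age group
            eta = eta + gamma_ext[:, k_idx - 1]
        if include_overdispersion and samples.tau_z is not None:
            eta = eta + rng.standard_normal((S, I)) / np.sqrt(samples.tau_z)[:, None]
        lam = np.exp(eta)  # (S, I) predictive rate draws
        for i in range(I):
            draws = lam[:, i]
            bands = {}
            for lev in sorted(band_levels):
                qlo, qhi = 0.5 - lev / 200.0, 0.5 + lev / 200.0
                bands[int(lev)] = (float(np.quantile(draws, qlo)), float(np.quantile(draws, qhi)))
            a = table.age_groups[i]
            results.append(
                ProjectionResult(
                    stratum=table.stratum,
                    age_label=a.label,
                    age_start=a.start_age,
                    age_end=a.end_age,
                    period=periods[h - 1],
                    n_at_risk=int(n_future[i]),
                    mean=float(draws.mean()),
                    median=float(np.median(draws)),
                    bands=bands,
                )
            )
    return results


def projection_delta(
    results: Sequence[ProjectionResult],
    table: APCTable,
    baseline_period: str | None = None,
) -> pd.DataFrame:
    """Change from the observed baseline rate to the final projected period.

    Returns, per age group, the projected median and mean rate at the last
    horizon, the observed baseline rate, and the difference in absolute rate
    points and in percentage points.
    """
    labels = [p.label for p in table.periods]
    baseline_period = baseline_period or labels[-1]
    if baseline_period not in labels:
        raise ValueError(f"baseline period {baseline_period!r} not among observed {labels}")
    j = labels.index(baseline_period)
    final = max(r.period.index for r in results)
    rows = []
    for r in results:
        if r.period.index != final:
            continue
        i = next(ix for ix, a in enumerate(table.age_groups) if a.label == r.age_label)
        base = table.y[i, j] / table.n[i, j] if table.n[i, j] > 0 else np.nan
        rows.append(
            {
                "age_group": r.age_label,
                "baseline_period": baseline_period,
                "projected_period": r.period.label,
                "baseline_rate": base,
                "projected_median": r.median,
                "projected_mean": r.mean,
                "delta_rate": r.median - base,
                "delta_percentage_points": 100.0 * (r.median - base),
            }
        )
    return pd.DataFrame(rows)


def projection_frame(results: Iterable[ProjectionResult]) -> pd.DataFrame:
    """Long-format frame, one row per band level per cell (the projection CSV schema)."""
    rows = []
    for r in results:
        for lev, (lo, hi) in sorted(r.bands.items()):
            rows.append(
                {
                    "stratum": r.stratum,
                    "age_start": r.age_start,
                    "age_end": r.age_end,
                    "period_start": r.period.start_year,
                    "period_end": r.period.end_year,
                    "n_at_risk": r.n_at_risk,
                    "mean": r.mean,
                    "median": r.median,
                    "level": lev,
                    "lower": lo,
                    "upper": hi,
                }
            )
    return pd.DataFrame(rows)


def write_projection_csv(results: Iterable[ProjectionResult], path: str | Path) -> None:
    projection_frame(results).to_csv(path, index=False)
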