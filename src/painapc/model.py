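"""Poisson age-period-cohort model with random-walk smoothing priors.

The event count in cell (i, j) — age group i, period j, cohort diagonal
k = M(I-i)+j — is modelled as

    y_ijk ~ Poisson(n_ijk * lambda_ijk),
    log(lambda_ijk) = mu + alpha_i + beta_j + gamma_k (+ z_ij),

where mu is the general level, alpha/beta/gamma are age, period and cohort
random effects, each constrained to sum to zero over the observed range, and
z is an optional iid Gaussian overdispersion effect per cell.

Each effect vector u carries an intrinsic random-walk prior of order 1 or 2:

    p(u | tau_u) ∝ tau_u^(r/2) * exp(-tau_u/2 * sum (Δ^order u)^2),  r = len(u) - order,

penalising squared first (RW1) or second (RW2) differences; RW2's null space
contains linear trends, making it the natural smoothing target for
extrapolation.  Precisions tau_u receive deliberately vague Gamma(1, 0.00005)
hyperpriors (log-gamma on the log precision), and the overdispersion precision
a Gamma(1, 0.005) hyperprior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import gammaln

from .lexis import APCTable, cohort_index_grid, count_cohorts

__all__ = [
    "EFFECTS",
    "APCModelSpec",
    "APCParams",
    "rw_quadratic_form",
    "linear_predictor",
    "eta_matrix",
    "poisson_loglik",
    "log_prior",
    "log_posterior",
]

EFFECTS = ("age", "period", "cohort")

#: default vague Gamma(shape, rate) hyperprior on each effect precision
DEFAULT_EFFECT_HYPERPRIOR = (1.0, 0.00005)
#: default Gamma(shape, rate) hyperprior on the overdispersion precision
DEFAULT_OVERDISPERSION_HYPERPRIOR = (1.0, 0.005)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class APCModelSpec:
    """Which effects are included, the RW order of each, and the hyperpriors.

    ``effects`` may be the full triple ("age", "period", "cohort"), the
    age-period pair, or the age-cohort pair; age is always included.
    """

    effects: tuple[str, ...] = EFFECTS
    rw_order: Mapping[str, int] = field(default_factory=lambda: {e: 2 for e in EFFECTS})
    effect_hyperprior: tuple[float, float] = DEFAULT_EFFECT_HYPERPRIOR
    overdispersion: bool = True
    overdispersion_hyperprior: tuple[float, float] = DEFAULT_OVERDISPERSION_HYPERPRIOR

    def __post_init__(self) -> None:
        if "age" not in self.effects:
            raise ValueError("the age effect is always included")
        if len(self.effects) < 2:
            raise ValueError("at least two effects must be included")
        unknown = set(self.effects) - set(EFFECTS)
        if unknown:
            raise ValueError(f"unknown effects {sorted(unknown)}")
        orders = {e: self.rw_order[e] for e in self.effects}
        if any(o not in (1, 2) for o in orders.values()):
            raise ValueError(f"RW orders must be 1 or 2, got {orders}")
        object.__setattr__(self, "rw_order", dict(orders))
        for name, (shape, rate) in (
            ("effect_hyperprior", self.effect_hyperprior),
            ("overdispersion_hyperprior", self.overdispersion_hyperprior),
        ):
            if shape <= 0 or rate <= 0:
                raise ValueError(f"{name} shape/rate must be positive")

    @property
    def label(self) -> str:
        eff = "".join(e[0].upper() for e in EFFECTS if e in self.effects)
        rw = "/".join(f"RW{self.rw_order[e]}" for e in self.effects)
        od = "+od" if self.overdispersion else ""
        return f"{eff}({rw}){od}"

    def to_dict(self) -> dict:
        return {
            "effects": list(self.effects),
            "rw_order": dict(self.rw_order),
            "effect_hyperprior": list(self.effect_hyperprior),
            "overdispersion": self.overdispersion,
            "overdispersion_hyperprior": list(self.overdispersion_hyperprior),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "APCModelSpec":
        return cls(
            effects=tuple(d.get("effects", EFFECTS)),
            rw_order=dict(d.get("rw_order", {e: 2 for e in EFFECTS})),
            effect_hyperprior=tuple(d.get("effect_hyperprior", DEFAULT_EFFECT_HYPERPRIOR)),
            overdispersion=bool(d.get("overdispersion", True)),
            overdispersion_hyperprior=tuple(
                d.get("overdispersion_hyperprior", DEFAULT_OVERDISPERSION_HYPERPRIOR)
            ),
        )


@dataclass
class APCParams:
    """One realisation of the model parameters.

    Effect vectors for excluded effects are ``None``; included vectors satisfy
    the sum-to-zero constraint to 1e-10.
    """

    mu: float
    alpha: np.ndarray
    beta: np.ndarray | None
    gamma: np.ndarray | None
    z: np.ndarray | None = None
    tau_alpha: float = 1.0
    tau_beta: float | None = None
    tau_gamma: float | None = None
    tau_z: float | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
        for name, u in self.effect_items():
            if abs(float(u.mean())) > 1e-10:
                raise ValueError(f"{name} effect violates sum-to-zero: mean={u.mean():.3e}")
        for name, tau in (
            ("tau_alpha", self.tau_alpha),
            ("tau_beta", self.tau_beta),
            ("tau_gamma", self.tau_gamma),
            ("tau_z", self.tau_z),
        ):
            if tau is not None and tau <= 0:
                raise ValueError(f"{name} must be positive, got {tau}")

    def effect_items(self) -> list[tuple[str, np.ndarray]]:
        out = [("age", self.alpha)]
        if self.beta is not None:
            out.append(("period", self.beta))
        if self.gamma is not None:
            out.append(("cohort", self.gamma))
        return out

    def effect(self, name: str) -> np.ndarray:
        return {"age": self.alpha, "period": self.beta, "cohort": self.gamma}[name]

    def tau(self, name: str) -> float:
        return {"age": self.tau_alpha, "period": self.tau_beta, "cohort": self.tau_gamma}[name]

    def copy(self) -> "APCParams":
        return replace(
            self,
            alpha=self.alpha.copy(),
            beta=None if self.beta is None else self.beta.copy(),
            gamma=None if self.gamma is None else self.gamma.copy(),
            z=None if self.z is None else self.z.copy(),
        )


def rw_quadratic_form(u: np.ndarray, order: int) -> float:
    """Sum of squared ``order``-th differences of ``u`` (the RW prior penalty).

    Order 1: sum (u_t - u_{t-1})^2; order 2: sum (u_t - 2 u_{t-1} + u_{t-2})^2.
    """
    u = np.asarray(u, dtype=float)
    if order not in (1, 2):
        raise ValueError(f"RW order must be 1 or 2, got {order}")
    if u.size < order + 1:
        raise ValueError(
            f"effect vector of length {u.size} too short for RW{order}; need at least {order + 1}"
        )
    return float(np.sum(np.diff(u, n=order) ** 2))


def _gamma_map(table: APCTable) -> np.ndarray:
    """0-based cohort index of every cell, shape (I, J)."""
    return cohort_index_grid(table) - 1


def eta_matrix(params: APCParams, table: APCTable) -> np.ndarray:
    """Linear predictor mu + alpha_i + beta_j + gamma_k (+ z_ij) over the grid."""
    eta = np.full((table.I, table.J), params.mu)
    eta += params.alpha[:, None]
    if params.beta is not None:
        eta += params.beta[None, :]
    if params.gamma is not None:
        eta += params.gamma[_gamma_map(table)]
    if params.z is not None:
        eta += params.z
    return eta


def linear_predictor(params: APCParams, i: int, j: int, table: APCTable) -> float:
    """Log rate of the single cell (i, j); 1-based indices as in the model notation."""
    if not 1 <= i <= table.I:
        raise IndexError(f"age index i={i} outside 1..{table.I}")
    if not 1 <= j <= table.J:
        raise IndexError(f"period index j={j} outside 1..{table.J}")
    eta = params.mu + params.alpha[i - 1]
    if params.beta is not None:
        eta += params.beta[j - 1]
    if params.gamma is not None:
        eta += params.gamma[_gamma_map(table)[i - 1, j - 1]]
    if params.z is not None:
        eta += params.z[i - 1, j - 1]
    return float(eta)


def poisson_loglik(table: APCTable, params: APCParams) -> float:
    """Poisson log likelihood sum_cells [y log(n*lambda) - n*lambda - log y!].

    Cells with n = 0 carry no exposure and contribute nothing; such a cell with
    y > 0 is impossible under the model and raises.
    """
    n = table.n
    y = table.y
    if np.any((n == 0) & (y > 0)):
        raise ValueError("cell with y > 0 but n = 0 has zero likelihood under the model")
    mask = n > 0
    mean = n[mask] * np.exp(eta_matrix(params, table)[mask])
    ym = y[mask]
    return float(np.sum(ym * np.log(mean) - mean - gammaln(ym + 1.0)))


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return float(shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x)


def log_prior(params: APCParams, spec: APCModelSpec, table: APCTable | None = None) -> float:
    """Joint log prior of effects, overdispersion and precisions.

    For each included effect u of length m with RW order o and precision tau:
    (r/2)(log tau - log 2pi) - (tau/2) * rw_quadratic_form(u, o) with rank
    r = m - o (intrinsic prior, made proper in effect space by the sum-to-zero
    constraint), plus a Gamma(shape, rate) log density on tau.  Overdispersion
    adds iid Normal(0, 1/tau_z) terms and the Gamma hyperprior on tau_z.
    Normalising constants are retained so densities are comparable across
    specifications; the intercept mu is flat.
    """
    shape, rate = spec.effect_hyperprior
    lp = 0.0
    for name in spec.effects:
        u = params.effect(name)
        tau = params.tau(name)
        if u is None or tau is None:
            raise ValueError(f"spec includes effect {name!r} but params lack it")
        order = spec.rw_order[name]
        r = u.size - order
        q = rw_quadratic_form(u, order)
        lp += 0.5 * r * (np.log(tau) - _LOG_2PI) - 0.5 * tau * q
        lp += _gamma_logpdf(tau, shape, rate)
    if spec.overdispersion:
        if params.z is None or params.tau_z is None:
            raise ValueError("spec includes overdispersion but params lack z / tau_z")
        zshape, zrate = spec.overdispersion_hyperprior
        m = params.z.size
        lp += 0.5 * m * (np.log(params.tau_z) - _LOG_2PI) - 0.5 * params.tau_z * float(
            np.sum(params.z**2)
        )
        lp += _gamma_logpdf(params.tau_z, zshape, zrate)
    return float(lp)


def log_posterior(params: APCParams, table: APCTable, spec: APCModelSpec) -> float:
    """Unnormalised log posterior: Poisson log likelihood plus log prior."""
    return poisson_loglik(table, params) + log_prior(params, spec, table)


def expected_params_shapes(table: APCTable, spec: APCModelSpec) -> dict[str, int]:
    """Length of each included effect vector on this table."""
    K = count_cohorts(table.I, table.J, table._require_m()) if "cohort" in spec.effects else 0
    out = {"age": table.I}
    if "period" in spec.effects:
        out["period"] = table.J
    if "cohort" in spec.effects:
        out["cohort"] = K
    return out
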