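"""Synthetic APC count tables with known ground truth.

The generator draws tables from the same Poisson model the package fits:
per cell, log(lambda) = mu + alpha_i + beta_j + gamma_k (+ z), y ~
Poisson(n * lambda).  The default truths emulate the structure of a large
multi-cohort ageing survey of self-reported pain: 14 five-year age groups
(31-35 ... 96-100), 5 five-year periods (1991-1995 ... 2011-2015), 18 cohort
diagonals, rates around 0.26-0.55, higher among females than males, rising
across periods, a mildly increasing age effect and a parabolic cohort effect
peaking for the cohorts born near the middle of the observed birth range
(~1920s-1950s).  At-risk counts are in the 10^3-10^4 per cell range.

The cohort truth is built as a symmetric parabola and therefore carries no
linear trend, so it lives in the same canonical parametrisation the sampler
reports (zero-linear-trend cohort section) and recovery experiments can
compare estimates to truth level by level.

Every fixture ships with a truth manifest so tests never hard-code true
values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lexis import AgeGroup, APCTable, Period, count_cohorts, write_table_csv
from .model import APCParams, eta_matrix

__all__ = [
    "APCTruth",
    "default_truth",
    "debug_truth",
    "intercept_only_truth",
    "generate_apc_table",
    "expected_rates",
    "truth_to_params",
    "make_fixture_suite",
]

logger = logging.getLogger(__name__)


@dataclass
class APCTruth:
    """Generative ground truth for one stratum's APC table."""

    mu_true: float
    alpha_true: np.ndarray
    beta_true: np.ndarray
    gamma_true: np.ndarray
    overdispersion_sd: float
    n_pattern: np.ndarray
    stratum: str
    seed: int
    age_start: int = 31
    period_start: int = 1991
    width: int = 5

    def __post_init__(self) -> None:
        self.alpha_true = np.asarray(self.alpha_true, dtype=float)
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        self.n_pattern = np.asarray(self.n_pattern, dtype=np.int64)
        for name, u in (("alpha", self.alpha_true), ("beta", self.beta_true),
                        ("gamma", self.gamma_true)):
            if abs(float(u.mean())) > 1e-10:
                raise ValueError(f"{name}_true must sum to zero, mean={u.mean():.3e}")
        if self.overdispersion_sd < 0:
            raise ValueError("overdispersion_sd must be non-negative")
        I, J = self.n_pattern.shape
        if self.alpha_true.size != I or self.beta_true.size != J:
            raise ValueError("effect lengths inconsistent with n_pattern shape")
        if self.gamma_true.size != count_cohorts(I, J, 1):
            raise ValueError("gamma_true length must be K = (I-1) + J")
        lam = expected_rates(self)
        if lam.min() <= 0 or lam.max() >= 1:
            raise ValueError(
                f"implied rates must lie in (0, 1); got [{lam.min():.3f}, {lam.max():.3f}]"
            )

    @property
    def I(self) -> int:  # noqa: E743
        return self.n_pattern.shape[0]

    @property
    def J(self) -> int:
        return self.n_pattern.shape[1]

    def grid(self) -> tuple[list[AgeGroup], list[Period]]:
        ages = [
            AgeGroup(i + 1, self.age_start + self.width * i, self.age_start + self.width * (i + 1) - 1)
            for i in range(self.I)
        ]
        periods = [
            Period(j + 1, self.period_start + self.width * j, self.period_start + self.width * (j + 1) - 1)
            for j in range(self.J)
        ]
        return ages, periods

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "seed": self.seed,
            "mu_true": self.mu_true,
            "alpha_true": self.alpha_true.tolist(),
            "beta_true": self.beta_true.tolist(),
            "gamma_true": self.gamma_true.tolist(),
            "overdispersion_sd": self.overdispersion_sd,
            "n_pattern": self.n_pattern.tolist(),
            "age_start": self.age_start,
            "period_start": self.period_start,
            "width": self.width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "APCTruth":
        return cls(
            mu_true=d["mu_true"],
            alpha_true=np.array(d["alpha_true"]),
            beta_true=np.array(d["beta_true"]),
            gamma_true=np.array(d["gamma_true"]),
            overdispersion_sd=d["overdispersion_sd"],
            n_pattern=np.array(d["n_pattern"]),
            stratum=d["stratum"],
            seed=d["seed"],
            age_start=d.get("age_start", 31),
            period_start=d.get("period_start", 1991),
            width=d.get("width", 5),
        )


def _blank_table(truth: APCTruth) -> APCTable:
    ages, periods = truth.grid()
    return APCTable(truth.stratum, ages, periods, truth.n_pattern, np.zeros_like(truth.n_pattern))


def truth_to_params(truth: APCTruth) -> APCParams:
    """The truth as an APCParams (no overdispersion realisation)."""
    return APCParams(
        mu=truth.mu_true,
        alpha=truth.alpha_true,
        beta=truth.beta_true,
        gamma=truth.gamma_true,
    )


def expected_rates(truth: APCTruth) -> np.ndarray:
    """Cell rates exp(mu + alpha_i + beta_j + gamma_k) with z = 0, shape (I, J)."""
    return np.exp(eta_matrix(truth_to_params(truth), _blank_table(truth)))


def default_truth(stratum: str = "female") -> APCTruth:
    """The reference truth for one gender stratum of the pain-rate structure.

    Female intercept above male; log-linear increasing period effect; mildly
    increasing age effect; symmetric parabolic cohort effect peaking for the
    mid-range birth cohorts.  At-risk counts echo survey scale: thousands of
    observations per cell, concentrated at ages 51-70.
    """
    if stratum not in ("male", "female"):
        raise ValueError("stratum must be 'male' or 'female'")
    I, J = 14, 5
    K = count_cohorts(I, J, 1)
    alpha = np.linspace(-0.10, 0.12, I)
    alpha -= alpha.mean()
    beta = np.linspace(-0.09, 0.09, J)
    beta -= beta.mean()
    k = np.arange(1, K + 1)
    gamma = 0.18 * (1.0 - ((k - (K + 1) / 2) / ((K - 1) / 2)) ** 2)
    gamma -= gamma.mean()
    mu = np.log(0.36) if stratum == "male" else np.log(0.44)
    base = np.array([1000] * 4 + [9000] * 4 + [3500] * 6)
    if stratum == "female":
        base = (1.3 * base).astype(np.int64)
    n = np.tile(base[:, None], (1, J))
    return APCTruth(
        mu_true=float(mu),
        alpha_true=alpha,
        beta_true=beta,
        gamma_true=gamma,
        overdispersion_sd=0.03,
        n_pattern=n,
        stratum=stratum,
        seed=101 if stratum == "male" else 102,
    )


def debug_truth() -> APCTruth:
    """A tiny 4x3 table (K = 6 cohorts) for fast end-to-end smoke runs."""
    I, J = 4, 3
    alpha = np.linspace(-0.05, 0.05, I)
    alpha -= alpha.mean()
    beta = np.linspace(-0.04, 0.04, J)
    beta -= beta.mean()
    k = np.arange(1, count_cohorts(I, J, 1) + 1)
    gamma = 0.06 * (1.0 - ((k - 3.5) / 2.5) ** 2)
    gamma -= gamma.mean()
    return APCTruth(
        mu_true=float(np.log(0.4)),
        alpha_true=alpha,
        beta_true=beta,
        gamma_true=gamma,
        overdispersion_sd=0.0,
        n_pattern=np.full((I, J), 2000, dtype=np.int64),
        stratum="debug",
        seed=103,
        age_start=31,
        period_start=2001,
    )


def intercept_only_truth(rate: float = 0.445, n_per_cell: int = 20_000) -> APCTruth:
    """All effects exactly zero: a pure-intercept table at the given rate."""
    I, J = 4, 3
    return APCTruth(
        mu_true=float(np.log(rate)),
        alpha_true=np.zeros(I),
        beta_true=np.zeros(J),
        gamma_true=np.zeros(count_cohorts(I, J, 1)),
        overdispersion_sd=0.0,
        n_pattern=np.full((I, J), n_per_cell, dtype=np.int64),
        stratum="intercept_only",
        seed=104,
        age_start=31,
        period_start=2001,
    )


def generate_apc_table(truth: APCTruth, seed: int | None = None) -> APCTable:
    """Draw one table: z ~ N(0, sd^2) per cell, y ~ Poisson(n * exp(eta + z)).

    The Poisson draw can exceed the at-risk count with small probability; such
    cells are capped at y = n (logged) so the table stays valid.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    lam = expected_rates(truth)
    if truth.overdispersion_sd > 0:
        lam = lam * np.exp(rng.normal(0.0, truth.overdispersion_sd, size=lam.shape))
    mean = truth.n_pattern * lam
    if not np.all(np.isfinite(mean)) or mean.max() > 1e12:
        raise ValueError("n * lambda overflow; use smaller effects or counts")
    y = rng.poisson(mean)
    over = y > truth.n_pattern
    if over.any():
        logger.warning(
            "capping %d cell(s) where the Poisson draw exceeded the at-risk count", over.sum()
        )
        y = np.minimum(y, truth.n_pattern)
    ages, periods = truth.grid()
    return APCTable(truth.stratum, ages, periods, truth.n_pattern, y)


def make_fixture_suite(out_dir: str | Path) -> dict[str, dict]:
    """Write the deterministic fixture set: default male + female tables, a 4x3
    debug table and an intercept-only table, each with a truth-manifest sidecar.

    Running twice produces byte-identical files.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = {
        "synthetic_male_female.csv": [default_truth("male"), default_truth("female")],
        "synthetic_debug_4x3.csv": [debug_truth()],
        "synthetic_intercept_only.csv": [intercept_only_truth()],
    }
    manifest: dict[str, dict] = {}
    for fname, truths in fixtures.items():
        tables = [generate_apc_table(t) for t in truths]
        write_table_csv(tables, out / fname)
        sidecar = {t.stratum: t.to_dict() for t in truths}
        spath = out / (fname[:-4] + ".truth.json")
        spath.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        manifest[fname] = {"truth_manifest": spath.name, "strata": [t.stratum for t in truths]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
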