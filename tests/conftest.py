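import numpy as np
import pytest

from painapc import (
    APCModelSpec,
    APCParams,
    APCTable,
    AgeGroup,
    MCMCConfig,
    Period,
    debug_truth,
    default_truth,
    generate_apc_table,
    sample_posterior,
)


def make_table(n, y, stratum="s", age_start=31, period_start=1991, width=5):
    """Small helper: build an APCTable from count matrices with 5-year intervals."""
    n = np.asarray(n)
    I, J = n.shape
    ages = [AgeGroup(i + 1, age_start + width * i, age_start + width * (i + 1) - 1) for i in range(I)]
    periods = [
        Period(j + 1, period_start + width * j, period_start + width * (j + 1) - 1) for j in range(J)
    ]
    return APCTable(stratum, ages, periods, n, np.asarray(y))


def random_params(rng, I, J, spec, table=None):
    """Random APCParams consistent with a spec on an I x J grid (M = 1)."""
    K = (I - 1) + J

    def centered(m):
        u = rng.normal(0, 0.3, m)
        return u - u.mean()

    return APCParams(
        mu=float(rng.normal(-1, 0.5)),
        alpha=centered(I),
        beta=centered(J) if "period" in spec.effects else None,
        gamma=centered(K) if "cohort" in spec.effects else None,
        z=rng.normal(0, 0.1, (I, J)) if spec.overdispersion else None,
        tau_alpha=float(rng.gamma(2, 10)),
        tau_beta=float(rng.gamma(2, 10)) if "period" in spec.effects else None,
        tau_gamma=float(rng.gamma(2, 10)) if "cohort" in spec.effects else None,
        tau_z=float(rng.gamma(2, 10)) if spec.overdispersion else None,
    )


@pytest.fixture(scope="session")
def debug_table():
    return generate_apc_table(debug_truth())


@pytest.fixture(scope="session")
def female_table():
    return generate_apc_table(default_truth("female"))


@pytest.fixture(scope="session")
def short_config():
    return MCMCConfig(n_iterations=2000, n_burnin=800, thinning=2, n_chains=1, seed=11)


@pytest.fixture(scope="session")
def debug_fit(debug_table, short_config):
    """A quick full-model fit on the 4x3 debug table, shared across tests."""
    return sample_posterior(debug_table, APCModelSpec(), short_config)


@pytest.fixture(scope="session")
def female_fit(female_table):
    """A moderate full-model fit on the 14x5 female table, shared across tests."""
    cfg = MCMCConfig(n_iterations=3000, n_burnin=1200, thinning=3, n_chains=1, seed=21)
    return sample_posterior(female_table, APCModelSpec(), cfg)
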