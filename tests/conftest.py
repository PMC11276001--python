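import numpy as np
import pandas as pd
import pytest

from chipewas import simulate_cohort
from chipewas.io import summary_stats_frame


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with planted effects, shared across tests."""
    return simulate_cohort(n_samples=400, n_cpgs=300, rng_seed=42)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no CHIP effect on methylation (δ = 0)."""
    return simulate_cohort(
        n_samples=400, n_cpgs=500, effect_size=0.0, rng_seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_summary_frame(rng, n_probes=20, cohort="FHS", stratum="White"):
    """Random but internally consistent cohort summary statistics."""
    from scipy import stats

    beta = rng.normal(0, 0.05, n_probes)
    se = rng.uniform(0.005, 0.05, n_probes)
    p = 2 * stats.norm.sf(np.abs(beta / se))
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:06d}" for i in range(n_probes)],
            "cohort": cohort,
            "stratum": stratum,
            "beta": beta,
            "se": se,
            "p": np.clip(p, 1e-300, 1.0),
            "n": 1000,
        }
    )
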