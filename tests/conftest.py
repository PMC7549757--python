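import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from cloq import CategorySpec, SyntheticConfig, generate_pattern


def random_instance(rng, n, categories=("A", "B", "C")):
    """A random labeled lon/lat instance for oracle comparisons."""
    lon = rng.uniform(-100.0, -95.0, size=n)
    lat = rng.uniform(35.0, 40.0, size=n)
    labels = rng.choice(categories, size=n)
    return lon, lat, labels


@pytest.fixture(scope="session")
def clustered_pattern():
    """A mixed pattern with built-in attraction of LTCH toward acute_care."""
    config = SyntheticConfig(
        categories=(
            CategorySpec("acute_care", 80, cluster_fraction=0.6, sigma_km=6.0),
            CategorySpec("crit_care", 40, cluster_fraction=0.0),
            CategorySpec("NH", 120, cluster_fraction=0.4, sigma_km=10.0),
            CategorySpec("LTCH", 40, sigma_km=2.0),
        ),
        cross_attraction={("acute_care", "LTCH"): 0.8},
        seed=42,
    )
    return generate_pattern(config)


@pytest.fixture(scope="session")
def csr_pvalue_sample():
    """Monte Carlo p-values under the CSR null, shared across tests.

    Session-scoped because the 500-replicate study is the most expensive
    fixture in the suite; both the type-I-error and the uniformity checks
    read from it.
    """
    from cloq.calibration import csr_pvalues

    return csr_pvalues(n_points=300, k=4, n_permutations=199,
                       n_replicates=500, seed=0)
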