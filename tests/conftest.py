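import numpy as np
import pytest

import phenofactor as pf


@pytest.fixture(scope="session")
def default_pop():
    """Default 26-indicator population at the study's sample size."""
    return pf.make_default_population(n=1337, maf=0.3)


@pytest.fixture(scope="session")
def null_items_and_genotype(default_pop):
    """One complete cohort with no SNP effect (shared across read-only tests)."""
    g = pf.simulate_genotypes(default_pop.n, default_pop.maf, seed=101)
    items = pf.simulate_item_responses(default_pop, g, seed=102)
    return items, g


@pytest.fixture(scope="session")
def bifactor_spec(default_pop):
    return pf.MeasurementModelSpec(kind="bifactor", dim_map=default_pop.dim_map)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
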