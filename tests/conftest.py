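import numpy as np
import pandas as pd
import pytest

from panelgwas import simulate, tables


@pytest.fixture(scope="session")
def panel():
    return tables.load_panel()


@pytest.fixture(scope="session")
def printed_assoc():
    """The published per-cohort tag-SNP association table."""
    return tables.load_tagsnp_assoc()


@pytest.fixture(scope="session")
def pizarra_sim():
    """One simulated rural-cohort dataset (n=869), fixed seed."""
    cfg = simulate.cohort_config("PIZARRA", seed=11)
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def two_cohort_sim():
    """One simulated two-cohort study (n=2294), fixed seed."""
    return simulate.generate_two_cohort_study(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
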