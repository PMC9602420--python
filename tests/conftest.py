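import numpy as np
import pytest

import polyscore as ps


@pytest.fixture(scope="session")
def panel():
    return ps.load_walkpace_panel()


@pytest.fixture(scope="session")
def table2_counts():
    """Integer genotype counts reconstructed from the packaged percentage table."""
    return ps.table2_genotype_counts()


@pytest.fixture(scope="session")
def hswa_freqs():
    """Observed favorable-allele percentages per group (rsid-indexed frame)."""
    return ps.load_walkpace_frequencies()


@pytest.fixture(scope="session")
def study_cohort(panel):
    """One simulated cohort at the study scale (137 cases / 126 controls)."""
    model = ps.table2_group_model()
    return ps.simulate_from_distributions(model, panel, seed=20220923)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
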