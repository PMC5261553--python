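import numpy as np
import pytest

from triomr import SimScenario, SNPPanel, default_panel, simulate_cohort


@pytest.fixture(scope="session")
def panel32():
    return default_panel(n_snps=32, seed=7)


@pytest.fixture
def small_panel():
    return SNPPanel(["rs1", "rs2"], ["A", "G"], ["C", "T"],
                    np.array([0.1, 0.3]), np.array([0.3, 0.6]))


@pytest.fixture(scope="session")
def cohort_factory(panel32):
    """Simulated trio cohorts under the default study conditions
    (rho2_m = 0.022, moderate shared confounding), overridable per test."""

    def make(n_families=5000, seed=0, **kwargs):
        scenario = SimScenario(n_families=n_families, panel=panel32,
                               seed=seed, **kwargs)
        return simulate_cohort(scenario)

    return make
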