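import numpy as np
import pytest
from hypothesis import settings

from svpanel.synthetic import SimulationConfig, simulate_truth_panel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_panel():
    """A compact trio cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_families=8, n_unrelated=2, genome=(("1", 2_000_000),),
        snp_density=100.0,
        sv_counts={"DEL": {"short": 30, "mid": 20, "large": 20},
                   "INS": {"short": 15},
                   "MEI": {"large": 10},
                   "COMPLEX_INDEL": {"short": 10}},
        seed=7)
    return simulate_truth_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
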