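import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ntcpval as nv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def table2():
    """The published 29-patient cohort, events as printed (6)."""
    return nv.table2_cohort("as_printed")


@pytest.fixture
def table2_seven():
    """The published cohort with the documented seventh event added."""
    return nv.table2_cohort("seven_events")


@pytest.fixture(scope="session")
def cohort5000():
    """One large synthetic cohort shared across end-to-end tests."""
    return nv.generate_cohort(nv.SimulationConfig(n_patients=5000, seed=7))


def random_dvh(rng, structure="s", dose_scale="physical"):
    """A random valid cumulative DVH on an irregular grid."""
    n = int(rng.integers(3, 20))
    doses = np.concatenate([[0.0], np.cumsum(rng.uniform(0.2, 6.0, n - 1))])
    drops = rng.uniform(0.0, 1.0, n - 1)
    fracs = np.concatenate([[1.0], 1.0 - np.cumsum(drops) / max(drops.sum(), 1e-9)
                            * rng.uniform(0.3, 1.0)])
    fracs = np.clip(fracs, 0.0, 1.0)
    return nv.DoseVolumeHistogram(structure, doses, fracs,
                                  float(rng.uniform(1.0, 6.0)), dose_scale)
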