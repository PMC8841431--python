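import numpy as np
import pytest

import pk2dose as pk
from pk2dose.compartmental import ErrorModel


def zero_noise_config(n_subjects=3, **kw):
    """Cohort settings with every randomness source switched off, so each
    subject's curve is exactly the typical model curve."""
    defaults = dict(
        n_subjects=n_subjects,
        blood_iiv_cv=0.0,
        organ_iiv_cv=0.0,
        error=ErrorModel("constant", a=0.0),
        injected_cv=0.0,
        body_mass_cv=0.0,
        seed=0,
    )
    defaults.update(kw)
    return pk.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return pk.simulate_cohort(zero_noise_config())


@pytest.fixture(scope="session")
def dense_times():
    return np.linspace(0.0, 500.0, 400)


@pytest.fixture()
def two_organ_phantom():
    vol, mask = pk.simulate_phantom(
        [
            ("liver", (10.0, 8.0, 8.0), (6.0, 5.0, 4.0), 8.0),
            ("heart", (24.0, 8.0, 8.0), (3.0, 3.0, 3.0), 3.0),
        ],
        grid_shape=(120, 64, 64),
        voxel_um=251.0,
        noise_cv_percent=0.0,
        seed=0,
    )
    return vol, mask
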