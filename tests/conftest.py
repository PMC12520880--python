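import logging

import numpy as np
import pytest

from habitatmri.preprocess import preprocess_patient
from habitatmri.synthetic import (
    HabitatParams,
    PhantomSpec,
    default_phantom_spec,
    generate_phantom,
)
from habitatmri.voxel_features import assemble_voxel_features

logging.getLogger("habitatmri").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast default-style phantom (3-habitat, 3 mm grid)."""
    return default_phantom_spec(
        grid_shape=(16, 15, 13),
        tumor_semiaxes_mm=(18.0, 15.0, 13.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_patient(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_preprocessed(small_patient):
    return preprocess_patient(small_patient)


@pytest.fixture(scope="session")
def small_voxel_table(small_preprocessed):
    return assemble_voxel_features(small_preprocessed)


@pytest.fixture(scope="session")
def well_separated_two_habitat_spec():
    """Iso-peak two-habitat phantom: habitats share peak-phase intensity
    but have opposite kinetics — the well-separated configuration used for
    planted-label recovery checks."""
    params = (
        HabitatParams(mean=430.0, sd=5.0, corr_length_mm=2.0, s0=100.0,
                      ttp_phase=2, washout_slope=-0.35),
        HabitatParams(mean=490.0, sd=5.0, corr_length_mm=2.0, s0=400.0,
                      ttp_phase=8, washout_slope=0.0),
    )
    return default_phantom_spec(
        n_habitats=2, habitat_params=params, noise_sd=8.0,
        bias_amplitude=0.0, boundary_smooth_mm=0.0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
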