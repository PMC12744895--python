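import logging

import numpy as np
import pytest

import kmcdce as K

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-size mirrored phantom, homogeneous bands, no noise: exact
    ground truth for fit-recovery tests."""
    spec = K.PhantomSpec(dispersion_sigma=0.0)
    series, labels, truth = K.generate_phantom(spec)
    return series, labels, truth


@pytest.fixture(scope="session")
def uptake_only_phantom():
    """Noiseless homogeneous phantom whose voxels follow the two-parameter
    uptake model exactly (washout beta = 0 everywhere): the exact-recovery
    reference for the voxelwise fit."""
    spec = K.PhantomSpec(
        dispersion_sigma=0.0,
        parenchyma_bands={**K.phantom.PARENCHYMA_BANDS, "beta": (0.0,) * 5},
        tumor_bands={**K.phantom.TUMOR_BANDS, "beta": (0.0,) * 5},
    )
    series, labels, truth = K.generate_phantom(spec)
    return series, labels, truth


@pytest.fixture(scope="session")
def small_phantom():
    """Small, fast phantom with within-band heterogeneity."""
    spec = K.PhantomSpec(shape=(16, 32, 8), seed=3, dispersion_sigma=0.15)
    series, labels, truth = K.generate_phantom(spec)
    return series, labels, truth


@pytest.fixture(scope="session")
def small_cohort():
    return K.generate_cohort(K.CohortSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
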