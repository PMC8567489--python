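import numpy as np
import pytest

from cortbs.pores import (
    DiameterMixtureParams,
    PorePopulation,
    baseline_only,
    sample_pore_population,
)
from cortbs.rf import AcousticsConfig, AcquisitionGeometry, synthesize_rf


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced scan geometry: enough lines/tilts for stable spectra, fast."""
    return AcquisitionGeometry.small()


@pytest.fixture(scope="session")
def default_mixture():
    return baseline_only(areal_density=15.0)


def make_slab(geom, margin_mm=6.5, depth_mm=4.0):
    return (geom.n_lines * geom.pitch_mm + margin_mm, 5.0, depth_mm)


@pytest.fixture(scope="session")
def small_population(small_geometry, default_mixture):
    return sample_pore_population(default_mixture, make_slab(small_geometry), seed=11)


@pytest.fixture(scope="session")
def empty_population(small_geometry):
    return PorePopulation(
        slab_extent=make_slab(small_geometry),
        centers=np.empty((0, 2)),
        diameters_um=np.empty(0),
    )


@pytest.fixture(scope="session")
def noiseless_acoustics():
    return AcousticsConfig(alpha0_db_mm=2.0, alphaf_db_mhz_mm=0.10, snr_db=np.inf)


@pytest.fixture(scope="session")
def small_rf(small_population, small_geometry):
    ac = AcousticsConfig(alpha0_db_mm=2.0, alphaf_db_mhz_mm=0.10, snr_db=30.0)
    return synthesize_rf(small_population, small_geometry, ac, seed=11)
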