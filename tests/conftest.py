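import numpy as np
import pytest

from perfopt.drs_inverse import ExtinctionTable, load_extinction_table
from perfopt.mc_forward import ProbeGeometry, ReflectanceLUT, build_lut

# reduced study grid for inversion work: spans the physiologic mu_a range of
# hemoglobin at ~19 uM across 500-650 nm and the mu_s' range of the scattering
# power law defaults
REDUCED_MUA_GRID = np.array([0.04, 0.5, 1.0, 2.0, 4.0, 6.0])
REDUCED_MUSP_GRID = np.array([4.0, 12.0, 20.0, 28.0, 36.0])
LUT_SEED = 20124
LUT_PHOTONS = 100_000


@pytest.fixture(scope="session")
def eps_table() -> ExtinctionTable:
    return load_extinction_table()


@pytest.fixture(scope="session")
def probe_geometry() -> ProbeGeometry:
    return ProbeGeometry()


@pytest.fixture(scope="session")
def mc_lut(probe_geometry) -> ReflectanceLUT:
    """Monte Carlo LUT on the reduced 6x5 study grid (built once per run)."""
    return build_lut(
        REDUCED_MUA_GRID,
        REDUCED_MUSP_GRID,
        probe_geometry,
        n_photons=LUT_PHOTONS,
        seed=LUT_SEED,
    )


def _analytic_reflectance(mua, musp):
    """Smooth diffusion-flavored surrogate reflectance used where tests need
    a noiseless, monotone forward model rather than Monte Carlo output."""
    mua = np.asarray(mua, dtype=float)[:, None]
    musp = np.asarray(musp, dtype=float)[None, :]
    return 0.05 * (musp / (musp + 15.0)) * np.exp(-2.2 * np.sqrt(mua) - 0.12 * mua)


@pytest.fixture(scope="session")
def analytic_lut(probe_geometry) -> ReflectanceLUT:
    """Dense synthetic-valued LUT (no Monte Carlo noise) for interpolation
    and inversion unit tests."""
    mua = np.linspace(0.01, 8.0, 80)
    musp = np.linspace(2.0, 40.0, 39)
    return ReflectanceLUT(
        mua_grid=mua,
        musp_grid=musp,
        reflectance=_analytic_reflectance(mua, musp),
        geometry=probe_geometry,
        n_photons_per_cell=0,
        seed=0,
        meta={"synthetic": True},
    )
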