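import numpy as np
import pytest
from scipy.special import spherical_jn, spherical_yn

from perfopt.exceptions import LUTRangeError
from perfopt.mc_forward import (
    OpticalProperties,
    ProbeGeometry,
    ReflectanceLUT,
    _mie_q_g,
    build_lut,
    cell_seed,
    diffusion_reflectance,
    load_lut,
    lut_lookup,
    mc_reflectance,
    mie_properties,
    standard_mua_grid,
    standard_musp_grid,
    sample_hg_cosines,
    save_lut,
)


class TestHenyeyGreenstein:
    def test_mean_cosine_equals_g(self):
        cosines = sample_hg_cosines(0.9, 10**6, seed=42)
        assert cosines.mean() == pytest.approx(0.900, abs=0.001)
        assert cosines.min() >= -1 and cosines.max() <= 1

    def test_isotropic_limit(self):
        cosines = sample_hg_cosines(0.0, 10**5, seed=1)
        assert cosines.mean() == pytest.approx(0.0, abs=0.01)


class TestTransport:
    def test_absorbing_limit(self, probe_geometry):
        props = OpticalProperties(mua=1000.0, mus=100.0, g=0.9)
        refl, _ = mc_reflectance(props, probe_geometry, 5_000, seed=1)
        assert refl < 1e-4

    def test_energy_conservation(self, probe_geometry):
        props = OpticalProperties.from_musp(1.0, 10.0)
        n = 20_000
        _, _, budget = mc_reflectance(props, probe_geometry, n, seed=2, return_budget=True)
        total = budget["absorbed"] + budget["exited"] + budget["roulette_net"]
        assert total / n == pytest.approx(1.0, abs=0.01)

    def test_reciprocity_under_fiber_swap(self):
        """Swapping source and detector fibers preserves the etendue-
        normalized throughput: collected fraction divided by detector area
        is invariant under exchanging the two (equal-NA) fiber roles."""
        props = OpticalProperties.from_musp(1.0, 10.0)
        a = ProbeGeometry(source_radius_mm=0.1, detector_radius_mm=0.15)
        b = ProbeGeometry(source_radius_mm=0.15, detector_radius_mm=0.1)
        ra, sa = mc_reflectance(props, a, 60_000, seed=3)
        rb, sb = mc_reflectance(props, b, 60_000, seed=4)
        na, nb = ra / 0.15**2, rb / 0.1**2
        assert abs(na - nb) < 4 * np.hypot(sa / 0.15**2, sb / 0.1**2)

    def test_determinism(self, probe_geometry):
        props = OpticalProperties.from_musp(2.0, 12.0)
        r1 = mc_reflectance(props, probe_geometry, 10_000, seed=7)
        r2 = mc_reflectance(props, probe_geometry, 10_000, seed=7)
        assert r1 == r2

    def test_nonphysical_properties_rejected(self):
        with pytest.raises(ValueError):
            OpticalProperties(mua=-1.0, mus=10.0)
        with pytest.raises(ValueError):
            OpticalProperties(mua=1.0, mus=10.0, g=1.5)


class TestGrids:
    def test_study_grid_cardinality(self):
        assert standard_mua_grid().size == 12
        assert standard_musp_grid().size == 21
        assert standard_mua_grid().size * standard_musp_grid().size == 252

    def test_mua_grid_values(self):
        grid = standard_mua_grid()
        assert grid[0] == 0.01 and grid[1] == 0.5
        np.testing.assert_allclose(grid[2:], np.arange(1.0, 20.0, 2.0))

    def test_musp_grid_span(self):
        grid = standard_musp_grid()
        assert grid[0] == 0.0 and grid[-1] == 40.0
        np.testing.assert_allclose(np.diff(grid), 2.0)


class TestBuildLut:
    def test_composition_and_determinism(self, probe_geometry):
        mua = np.array([2.0, 6.0])
        musp = np.array([10.0, 20.0])
        lut = build_lut(mua, musp, probe_geometry, n_photons=2_000, seed=5)
        lut2 = build_lut(mua, musp, probe_geometry, n_photons=2_000, seed=5)
        np.testing.assert_array_equal(lut.reflectance, lut2.reflectance)
        # each cell matches a standalone run with the same sub-seed
        props = OpticalProperties.from_musp(mua[1], musp[0])
        standalone, _ = mc_reflectance(props, probe_geometry, 2_000, seed=cell_seed(5, 1, 0))
        assert lut.reflectance[1, 0] == standalone

    def test_zero_musp_column_is_zero(self, probe_geometry):
        lut = build_lut([1.0], [0.0, 10.0], probe_geometry, n_photons=2_000, seed=1)
        assert lut.reflectance[0, 0] == 0.0

    def test_hdf5_round_trip(self, tmp_path, probe_geometry):
        lut = build_lut([1.0, 3.0], [8.0, 16.0], probe_geometry, n_photons=2_000, seed=9)
        path = tmp_path / "lut.h5"
        save_lut(lut, path)
        back = load_lut(path)
        np.testing.assert_array_equal(back.reflectance, lut.reflectance)
        assert back.geometry == lut.geometry
        assert back.n_photons_per_cell == lut.n_photons_per_cell


class TestLookup:
    def test_grid_node_identity(self, analytic_lut):
        i, j = 10, 20
        got = lut_lookup(analytic_lut, analytic_lut.mua_grid[i], analytic_lut.musp_grid[j])
        assert got == pytest.approx(analytic_lut.reflectance[i, j], rel=1e-12)

    def test_cell_center_is_corner_mean(self, analytic_lut):
        a = 0.5 * (analytic_lut.mua_grid[3] + analytic_lut.mua_grid[4])
        s = 0.5 * (analytic_lut.musp_grid[5] + analytic_lut.musp_grid[6])
        corners = analytic_lut.reflectance[3:5, 5:7]
        assert lut_lookup(analytic_lut, a, s) == pytest.approx(corners.mean(), rel=1e-12)

    def test_out_of_hull_names_axis(self, analytic_lut):
        with pytest.raises(LUTRangeError) as err:
            lut_lookup(analytic_lut, 1e4, 10.0)
        assert err.value.axis == "mua"
        with pytest.raises(LUTRangeError) as err:
            lut_lookup(analytic_lut, 1.0, 1e4)
        assert err.value.axis == "musp"

    def test_clip_mode_clamps(self, analytic_lut):
        edge = lut_lookup(analytic_lut, analytic_lut.mua_grid[-1], 10.0)
        assert lut_lookup(analytic_lut, 1e4, 10.0, clip=True) == pytest.approx(edge)

    def test_monotone_in_mua_along_dense_queries(self, analytic_lut):
        mua = np.linspace(0.05, 7.9, 200)
        vals = lut_lookup(analytic_lut, mua, np.full(200, 20.0))
        assert np.all(np.diff(vals) <= 1e-15)


class TestDiffusionOracle:
    def test_monotone_decreasing_in_mua(self):
        r = [
            diffusion_reflectance(OpticalProperties.from_musp(mua, 10.0), 5.0)
            for mua in (0.05, 0.1, 0.2, 0.4)
        ]
        assert np.all(np.diff(r) < 0)

    def test_monotone_decreasing_in_distance(self):
        props = OpticalProperties.from_musp(0.1, 10.0)
        r = [diffusion_reflectance(props, d) for d in (2.0, 4.0, 8.0)]
        assert np.all(np.diff(r) < 0)

    def test_warns_outside_diffusive_regime(self):
        with pytest.warns(UserWarning, match="diffusion"):
            diffusion_reflectance(OpticalProperties.from_musp(5.0, 10.0), 5.0)


class TestMie:
    def test_against_independent_bessel_route(self):
        """Cross-check the log-derivative recurrence against coefficients
        assembled directly from scipy's spherical Bessel functions."""
        x = np.pi * 1.0e3 * 1.33 / 600.0  # 1-um sphere in water at 600 nm
        m = 1.59 / 1.33

        nmax = int(np.ceil(x + 4 * x ** (1 / 3) + 2))
        ns = np.arange(1, nmax + 1)
        mx = m * x
        psi = lambda n, z: z * spherical_jn(n, z)  # noqa: E731
        dpsi = lambda n, z: spherical_jn(n, z) + z * spherical_jn(n, z, derivative=True)  # noqa: E731
        chi = lambda n, z: -z * spherical_yn(n, z)  # noqa: E731
        dchi = lambda n, z: -spherical_yn(n, z) - z * spherical_yn(n, z, derivative=True)  # noqa: E731
        xi = psi(ns, x) - 1j * chi(ns, x)
        dxi = dpsi(ns, x) - 1j * dchi(ns, x)
        a = (m * psi(ns, mx) * dpsi(ns, x) - psi(ns, x) * dpsi(ns, mx)) / (
            m * psi(ns, mx) * dxi - xi * dpsi(ns, mx)
        )
        b = (psi(ns, mx) * dpsi(ns, x) - m * psi(ns, x) * dpsi(ns, mx)) / (
            psi(ns, mx) * dxi - m * xi * dpsi(ns, mx)
        )
        qsca_ref = (2 / x**2) * np.sum((2 * ns + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
        n1 = ns[:-1]
        t1 = np.sum(
            n1 * (n1 + 2) / (n1 + 1)
            * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:]))
        )
        t2 = np.sum((2 * ns + 1) / (ns * (ns + 1)) * np.real(a * np.conj(b)))
        g_ref = (4 / x**2) * (t1 + t2) / qsca_ref

        qsca, g = _mie_q_g(x, m)
        assert qsca == pytest.approx(qsca_ref, rel=1e-4)
        assert g == pytest.approx(g_ref, rel=1e-4)

    def test_rayleigh_limit(self):
        q1, g1 = _mie_q_g(0.02, 1.2)
        q2, _ = _mie_q_g(0.01, 1.2)
        assert abs(g1) < 0.01
        assert q1 / q2 == pytest.approx(16.0, rel=0.05)  # Q ~ x^4 scaling

    def test_mus_linear_in_volume_fraction(self):
        p1 = mie_properties(1.0, 1.59, 1.33, 600.0, 0.01)
        p2 = mie_properties(1.0, 1.59, 1.33, 600.0, 0.02)
        assert p2.mus == pytest.approx(2 * p1.mus, rel=1e-12)
        assert p1.mua == 0.0
        assert p2.g == p1.g

    def test_physical_scale_for_polystyrene_phantom(self):
        props = mie_properties(1.0, 1.59, 1.33, 600.0, 0.01)
        # forward-peaked scattering and a mus' in the tissue-mimicking range
        assert 0.85 < props.g < 0.95
        assert 5.0 < props.musp < 60.0

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            mie_properties(0.0, 1.59, 1.33, 600.0, 0.01)
        with pytest.raises(ValueError):
            mie_properties(1.0, 1.59, 1.33, 600.0, 0.5)


def test_lut_invariant_enforced(probe_geometry):
    with pytest.raises(ValueError, match="increasing"):
        ReflectanceLUT(
            mua_grid=np.array([1.0, 0.5]),
            musp_grid=np.array([1.0, 2.0]),
            reflectance=np.zeros((2, 2)),
            geometry=probe_geometry,
            n_photons_per_cell=0,
            seed=0,
        )
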