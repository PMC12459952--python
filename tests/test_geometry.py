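import numpy as np
import pytest

from nanodome.averaging import AveragedShape
from nanodome.geometry import (
    bending_energy,
    crossover_length,
    excess_area,
    radial_mean_curvature_profile,
)
from nanodome.synthetic import ParametricSurface


def plane(c=0.0):
    return AveragedShape.from_function(
        lambda x, y: np.full(np.shape(x), c, dtype=float), a=1.0, d_m=50.0)


def sphere_cap(R=20.0, base_radius=8.0):
    off = np.sqrt(R**2 - base_radius**2)
    return AveragedShape.from_function(
        lambda x, y: np.sqrt(R**2 - (x**2 + y**2)) - off,
        a=1.0, d_m=2 * base_radius)


def catenoid(c=5.0, d_m=50.0):
    def fn(x, y):
        r = np.maximum(np.hypot(x, y), c)
        return c * np.arccosh(r / c)
    return AveragedShape.from_function(fn, a=1.0, d_m=d_m)


@pytest.fixture(scope="module")
def gauss_surface():
    return ParametricSurface(sigma=5.0)


class TestExcessArea:
    @pytest.mark.parametrize("c", [0.0, 3.7])
    def test_plane_has_zero_excess_area(self, c):
        assert excess_area(plane(c)) == 0.0

    def test_tilted_plane_closed_form_per_site(self):
        # slope 3/4: sqrt(1 + 0.5625) - 1 = 0.25 exactly at interior sites
        tilt = AveragedShape.from_function(lambda x, y: 0.75 * x,
                                           a=1.0, d_m=50.0)
        X, Y = np.meshgrid(tilt.coords, tilt.coords, indexing="ij")
        n_sites = int(((X**2 + Y**2) <= 23.0**2).sum())
        assert excess_area(tilt, r_max=23.0) == pytest.approx(
            0.25 * n_sites, rel=1e-12)

    def test_gaussian_dome_matches_fine_quadrature(self, gauss_surface):
        dome = AveragedShape.from_function(gauss_surface.height_fn(4.0),
                                           a=1.0, d_m=50.0)
        oracle = gauss_surface.quad_excess_area(4.0, 25.0, step=0.05)
        assert excess_area(dome) == pytest.approx(oracle, rel=0.01)

    def test_invariant_under_shift_and_rotation(self, gauss_surface):
        base = AveragedShape.from_function(gauss_surface.height_fn(4.0),
                                           a=1.0, d_m=50.0)
        shifted = base.with_offset(11.0)
        th = np.radians(33.0)
        fn = gauss_surface.height_fn(4.0)
        rot = AveragedShape.from_function(
            lambda x, y: fn(np.cos(th) * x + np.sin(th) * y,
                            -np.sin(th) * x + np.cos(th) * y),
            a=1.0, d_m=50.0)
        ref = excess_area(base)
        assert excess_area(shifted) == pytest.approx(ref, rel=1e-12)
        assert excess_area(rot) == pytest.approx(ref, rel=1e-6)

    def test_truncation_monotone_and_core_dominated(self):
        # paper-like nanodome: protein-scale core plus catenoidal far field
        surf = ParametricSurface(sigma=6.0, tail="catenoid",
                                 tail_amplitude=0.1)
        dome = AveragedShape.from_function(surf.height_fn(5.0),
                                           a=1.0, d_m=50.0)
        r_maxes = [6.0, 12.0, 18.0, 25.0]
        vals = [excess_area(dome, r_max=r) for r in r_maxes]
        assert all(v2 >= v1 for v1, v2 in zip(vals, vals[1:]))
        assert vals[1] / vals[-1] >= 0.85  # core within 12 nm dominates

    def test_lattice_constant_insensitivity(self, gauss_surface):
        d1 = AveragedShape.from_function(gauss_surface.height_fn(4.0),
                                         a=1.0, d_m=50.0)
        d2 = AveragedShape.from_function(gauss_surface.height_fn(4.0),
                                         a=2.0, d_m=50.0)
        assert excess_area(d2) == pytest.approx(excess_area(d1), rel=0.05)

    def test_non_finite_heights_rejected(self):
        bad = AveragedShape.from_function(
            lambda x, y: np.where(np.hypot(x, y) < 1, np.nan, 0.0),
            a=1.0, d_m=20.0)
        with pytest.raises(ValueError, match="finite"):
            excess_area(bad)


class TestBendingEnergy:
    def test_plane_and_tilted_plane_are_energy_free(self):
        assert bending_energy(plane(1.0)) == 0.0
        tilt = AveragedShape.from_function(lambda x, y: 0.75 * x + 0.2 * y,
                                           a=1.0, d_m=50.0)
        assert bending_energy(tilt) == pytest.approx(0.0, abs=1e-20)

    def test_spherical_cap_closed_form(self):
        cap = sphere_cap()
        h = 20.0 - np.sqrt(400.0 - 64.0)
        oracle = 4 * np.pi * h / 20.0  # int 2 kappa H^2 dA with H = 1/R
        assert bending_energy(cap) == pytest.approx(oracle, rel=0.03)

    def test_catenoid_is_minimal(self):
        assert abs(bending_energy(catenoid(), r_min=7.0)) < 0.02

    def test_scale_invariance(self):
        surf = ParametricSurface(sigma=6.0)
        base = AveragedShape.from_function(surf.height_fn(4.0),
                                           a=1.0, d_m=50.0)
        lam = 2.0
        fn = surf.height_fn(4.0)
        scaled = AveragedShape.from_function(
            lambda x, y: lam * fn(x / lam, y / lam), a=lam, d_m=lam * 50.0)
        assert bending_energy(scaled) == pytest.approx(bending_energy(base),
                                                       rel=1e-9)
        assert excess_area(scaled) == pytest.approx(
            lam**2 * excess_area(base), rel=1e-9)

    def test_density_weighting_reduces_energy(self, gauss_surface):
        fn = gauss_surface.height_fn(4.0)
        rho_fn = lambda x, y: (np.hypot(x, y) >= 3.0).astype(float)  # noqa: E731
        with_rho = AveragedShape.from_function(fn, a=1.0, d_m=50.0,
                                               rho_fn=rho_fn)
        assert bending_energy(with_rho) < bending_energy(with_rho,
                                                         use_density=False)

    def test_r_max_floor(self):
        with pytest.raises(ValueError, match="lattice steps"):
            bending_energy(plane(), r_max=1.0)


class TestCurvatureProfile:
    def test_sphere_cap_profile_is_flat_at_inverse_radius(self):
        _, curv, _ = radial_mean_curvature_profile(sphere_cap())
        sel = curv.r < 6.0
        np.testing.assert_allclose(curv.M[sel], 0.05, atol=0.002)

    def test_catenoid_profile_is_zero(self):
        _, curv, _ = radial_mean_curvature_profile(catenoid())
        sel = (curv.r > 8.0) & (curv.r < 22.0)
        assert np.abs(curv.M[sel]).max() < 0.002

    @pytest.mark.parametrize("sigma", [6.0, 8.0])
    def test_profile_energy_matches_lattice_energy(self, sigma):
        surf = ParametricSurface(sigma=sigma)
        dome = AveragedShape.from_function(surf.height_fn(4.0),
                                           a=1.0, d_m=50.0)
        e3d = bending_energy(dome)
        _, _, e2d = radial_mean_curvature_profile(dome)
        assert e2d == pytest.approx(e3d, rel=0.05)

    def test_coarse_bin_width_rejected(self):
        with pytest.raises(ValueError, match="bin width"):
            radial_mean_curvature_profile(plane(), radial_bin_width=15.0)


class TestCrossoverLength:
    def test_thermal_crossover_lengths(self):
        # kappa = 25 kBT at 310 K: ~10 nm at 1 mN/m, ~5 nm at 4 mN/m
        assert crossover_length(25.0, 310.0, 1.0) == pytest.approx(10.0,
                                                                  rel=0.05)
        assert crossover_length(25.0, 310.0, 4.0) == pytest.approx(5.0,
                                                                  rel=0.05)

    def test_unit_identity(self):
        from nanodome.geometry import kbt_pn_nm
        gamma = 25.0 * kbt_pn_nm(310.0)  # numerically kappa*kBT per nm^2
        assert crossover_length(25.0, 310.0, gamma) == pytest.approx(1.0,
                                                                     rel=1e-12)

    def test_nonpositive_tension_rejected(self):
        with pytest.raises(ValueError):
            crossover_length(25.0, 310.0, 0.0)
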