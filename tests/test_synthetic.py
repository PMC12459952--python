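import dataclasses

import numpy as np
import pytest

from nanodome.averaging import average_shapes
from nanodome.geometry import excess_area, kbt_pn_nm
from nanodome.pipeline import aligned_shapes_for_frames
from nanodome.surface import assign_leaflets, midplane_grid
from nanodome.synthetic import (
    ParametricSurface,
    SurfaceSpec,
    _undulation_field,
    calibrate_spring,
    make_surface,
    make_topology,
    make_trajectory,
    measure_noiseless,
    sample_bilayer_frame,
)


class TestMakeSurface:
    def test_flat_limit(self):
        sp = SurfaceSpec(dome_height=0.0)
        _, truth = make_surface(sp, quadrature_step=0.2)
        assert truth.excess_area == pytest.approx(0.0, abs=1e-12)
        assert truth.bending_energy == pytest.approx(0.0, abs=1e-12)

    def test_truth_against_independent_numerical_gradient(self, spec):
        """Quadrature truth (analytic gradients) vs an oracle built from
        finite differences of the height field alone."""
        surf, truth = make_surface(spec, quadrature_step=0.1)
        h, R = spec.dome_height, spec.patch_size / 2.0
        step = 0.05
        c = np.arange(-R, R + step / 2, step)
        X, Y = np.meshgrid(c, c, indexing="ij")
        Z = surf.z(X, Y, h)
        gx, gy = np.gradient(Z, step, edge_order=2)
        inside = X**2 + Y**2 <= R**2
        dA = (np.sqrt(1 + gx**2 + gy**2) - 1.0)[inside].sum() * step**2
        assert truth.excess_area == pytest.approx(dA, rel=5e-3)

    def test_quadrature_convergence(self, spec):
        surf, _ = make_surface(spec)
        h, R = spec.dome_height, spec.patch_size / 2.0
        a1 = surf.quad_excess_area(h, R, step=0.1)
        a2 = surf.quad_excess_area(h, R, step=0.05)
        assert abs(a2 - a1) / a2 < 1e-3
        e1 = surf.quad_bending_energy(h, R, step=0.1)
        e2 = surf.quad_bending_energy(h, R, step=0.05)
        assert abs(e2 - e1) / e2 < 1e-3

    def test_catenoid_tail_is_minimal_far_from_the_dome(self):
        surf = ParametricSurface(sigma=5.0, tail="catenoid",
                                 tail_amplitude=0.5)
        r, M = surf.curvature_profile(h=5.0, R=25.0)
        far = r > 17.0
        assert np.abs(M[far]).max() < 0.003

    def test_invalid_tail_spec(self):
        with pytest.raises(ValueError, match="tail"):
            SurfaceSpec(tail="spline")
        with pytest.raises(ValueError, match="amplitude"):
            SurfaceSpec(tail="catenoid", tail_amplitude=30.0)


class TestSampling:
    def test_same_seed_bit_identical(self, spec, surface_and_truth):
        surf, _ = surface_and_truth
        f1, l1 = sample_bilayer_frame(surf, spec, seed=99)
        f2, l2 = sample_bilayer_frame(surf, spec, seed=99)
        np.testing.assert_array_equal(f1.positions, f2.positions)
        np.testing.assert_array_equal(f1.molecule_id, f2.molecule_id)
        np.testing.assert_array_equal(l1, l2)

    def test_flat_noiseless_frame_has_negligible_excess_area(self, topology):
        sp = SurfaceSpec(dome_height=0.0, marker_jitter=0.0)
        surf, _ = make_surface(sp, quadrature_step=0.2)
        frames = [sample_bilayer_frame(surf, sp, seed=s,
                                       with_undulations=False)[0]
                  for s in range(3)]
        shapes, _ = aligned_shapes_for_frames(frames, topology)
        avg = average_shapes(shapes, a=1.0)
        assert excess_area(avg) < 0.5

    def test_undulation_spectrum_through_reconstruction(self, spec):
        """Reconstructed protein-free membranes carry the Helfrich
        spectrum ~ kBT/(kappa q^4 + gamma q^2) at long wavelengths."""
        sp = dataclasses.replace(spec, dome_height=0.0, gamma_gen=0.0)
        surf = ParametricSurface(sigma=sp.dome_sigma)
        n_frames, n_bins = 200, 25
        L = sp.patch_size
        acc = None
        for s in range(n_frames):
            fr, _ = sample_bilayer_frame(surf, sp, seed=s, h=0.0,
                                         with_protein=False)
            grid = midplane_grid(fr, assign_leaflets(fr), n_bins)
            z = grid.z_midplane - grid.z_midplane.mean()
            p = np.abs(np.fft.fft2(z)) ** 2
            acc = p if acc is None else acc + p
        power = acc / n_frames
        q1 = 2 * np.pi * np.fft.fftfreq(n_bins, d=L / n_bins)
        # lowest non-zero modes, where binning attenuation is negligible
        for (i, j) in [(1, 0), (0, 1), (1, 1)]:
            q2 = q1[i] ** 2 + q1[j] ** 2
            S = 1.0 / (sp.kappa_gen * q2**2)
            expected = n_bins**4 * S / L**2
            se = expected / np.sqrt(n_frames)
            assert abs(power[i, j] - expected) < 3 * se

    def test_pressure_synthesis_inverts_exactly(self, spec,
                                                surface_and_truth):
        from nanodome.elasticity import tension_from_pressures
        surf, _ = surface_and_truth
        fr, _ = sample_bilayer_frame(surf, spec, seed=0, gamma=10.8)
        Px, Py, Pz = fr.pressures
        assert tension_from_pressures(Px, Py, Pz, fr.box[2]) == pytest.approx(
            10.8, rel=1e-12)

    def test_ensemble_excess_area_matches_observable_truth(
            self, spec, topology, surface_and_truth):
        """A 50-frame dome ensemble reproduces the generator's observable
        ground truth (the noiseless infinite-density measurement) within
        5%."""
        surf, truth = surface_and_truth
        frames = [sample_bilayer_frame(surf, spec, seed=5000 + s)[0]
                  for s in range(50)]
        shapes, _ = aligned_shapes_for_frames(frames, topology)
        avg = average_shapes(shapes, a=1.0)
        measured = excess_area(avg)
        oracle, _ = measure_noiseless(surf, spec, spec.dome_height)
        assert measured == pytest.approx(oracle, rel=0.05)
        # and stays within ~10% of the continuous-surface quadrature truth
        assert measured == pytest.approx(truth.excess_area, rel=0.12)


class TestTrajectory:
    def test_calibration_embeds_the_spring_noiselessly(self, spec):
        cal = calibrate_spring(spec)
        # measured E_b is linear in dz with slope -F0*/(kappa kBT)
        assert cal["s_E"] * spec.kappa_gen * kbt_pn_nm(spec.T) == \
            pytest.approx(-spec.F0_star, rel=1e-9)
        dz = np.linspace(0.0, 1.5, 6)
        dA_t = spec.dA_inf + spec.dA_ddz_star * dz
        h_t = np.interp(dA_t, cal["dA_table"], cal["h_table"])
        eb_t = np.interp(h_t, cal["h_table"], cal["eb_table"])
        slope = np.polyfit(dz, eb_t, 1)[0]
        assert slope == pytest.approx(cal["s_E"], rel=0.05)

    def test_stationary_vs_relaxing_windows(self, spec, topology):
        relaxing = dataclasses.replace(spec, relax_c=600.0)
        runs, truth = make_trajectory(relaxing, [0.0], n_runs=1, n_frames=6,
                                      seed=3)
        heights = truth.extras["heights"][(0.0, 0)]
        assert heights[0] > heights[-1]  # 1/t relaxation of the dome
        runs0, truth0 = make_trajectory(spec, [0.0], n_runs=1, n_frames=6,
                                        seed=3)
        h0 = truth0.extras["heights"][(0.0, 0)]
        assert np.ptp(h0) == pytest.approx(0.0, abs=1e-12)

    def test_trajectory_reproducible_and_runs_independent(self, spec):
        r1, _ = make_trajectory(spec, [0.0], n_runs=2, n_frames=2, seed=9)
        r2, _ = make_trajectory(spec, [0.0], n_runs=2, n_frames=2, seed=9)
        a = r1[0.0][0][0].positions
        b = r2[0.0][0][0].positions
        np.testing.assert_array_equal(a, b)
        # different runs draw different lipid clouds
        assert r1[0.0][0][0].n_particles != r1[0.0][1][0].n_particles or \
            not np.array_equal(r1[0.0][0][0].positions,
                               r1[0.0][1][0].positions)

    def test_empty_tensions_rejected(self, spec):
        with pytest.raises(ValueError):
            make_trajectory(spec, [], seed=0)
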