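import dataclasses

import numpy as np
import pytest

from nanodome.frame_io import Role
from nanodome.surface import assign_leaflets, midplane_grid, recenter_and_wrap
from nanodome.synthetic import sample_bilayer_frame

from test_frame_io import tiny_frame


def flat_bilayer(n_side=20, L=20.0, head_z=2.0, tail_z=0.5, z0=10.0):
    """Regular flat bilayer: heads at z0 +- head_z, tails at z0 +- tail_z."""
    c = (np.arange(n_side) + 0.5) * (L / n_side)
    X, Y = np.meshgrid(c, c, indexing="ij")
    xy = np.column_stack([X.ravel(), Y.ravel()])
    n = len(xy)
    rows_pos, rows_mol, rows_role, rows_part = [], [], [], []
    mol = 1
    for sign in (+1, -1):
        for k in range(n):
            x, y = xy[k]
            rows_pos += [(x, y, z0 + sign * head_z),
                         (x, y, z0 + sign * tail_z)]
            rows_mol += [mol, mol]
            rows_role += [int(Role.lipid_head), int(Role.lipid_tail)]
            rows_part += ["PO4", "C1A"]
            mol += 1
    from nanodome.frame_io import BeadFrame
    return BeadFrame(
        particle_id=np.arange(1, len(rows_pos) + 1),
        molecule_id=np.array(rows_mol),
        residue=np.full(len(rows_pos), "POPC"),
        particle=np.array(rows_part),
        role=np.array(rows_role, dtype=np.int8),
        positions=np.array(rows_pos),
        box=np.array([L, L, 2 * z0]),
    )


class TestRecenter:
    def test_identity_when_already_centered(self, spec, topology,
                                            surface_and_truth):
        surf, _ = surface_and_truth
        nojit = dataclasses.replace(spec, marker_jitter=0.0)
        fr, _ = sample_bilayer_frame(surf, nojit, seed=3,
                                     with_undulations=False)
        rec = recenter_and_wrap(fr, topology)
        # channel markers are centered in xy by construction
        np.testing.assert_allclose(rec.positions[:, :2], fr.positions[:, :2],
                                   atol=1e-9)

    def test_shift_recover(self, spec, topology, surface_and_truth):
        surf, _ = surface_and_truth
        nojit = dataclasses.replace(spec, marker_jitter=0.0)
        fr, _ = sample_bilayer_frame(surf, nojit, seed=4,
                                     with_undulations=False)
        ref = recenter_and_wrap(fr, topology)
        shifted = dataclasses.replace(
            fr, positions=np.mod(fr.positions + np.array([7.3, -11.1, 2.9]),
                                 fr.box))
        back = recenter_and_wrap(shifted, topology)
        # identical particle-wise positions up to periodic images
        diff = back.positions - ref.positions
        diff -= fr.box * np.round(diff / fr.box)
        assert np.abs(diff).max() < 1e-9

    def test_missing_channel_is_informative(self, topology):
        fr = tiny_frame()
        with pytest.raises(ValueError, match="channel"):
            recenter_and_wrap(fr, topology)


class TestLeaflets:
    def test_flat_bilayer_labels_follow_head_sign(self):
        fr = flat_bilayer()
        labels = assign_leaflets(fr)
        heads_z = fr.positions[fr.role == Role.lipid_head, 2]
        np.testing.assert_array_equal(labels, np.where(heads_z > 10.0, 1, -1))

    def test_inverted_lipid_is_lower(self):
        fr = flat_bilayer(n_side=2)
        # invert one lipid: head below its own tails, still in upper leaflet z
        is_head = fr.role == Role.lipid_head
        idx = np.flatnonzero(is_head)[0]
        mol = fr.molecule_id[idx]
        fr.positions[idx, 2] = 11.0
        fr.positions[(fr.molecule_id == mol) & (fr.role == Role.lipid_tail), 2] = 11.5
        labels = assign_leaflets(fr)
        assert labels[0] == -1

    def test_curved_dome_matches_generator_labels(self, spec, dome_frames):
        agree = []
        for fr, truth_labels in dome_frames[:4]:
            labels = assign_leaflets(fr)
            agree.append(np.mean(labels == truth_labels))
        assert min(agree) >= 0.99

    def test_lipid_without_tails_is_reported(self):
        fr = flat_bilayer(n_side=2)
        keep = ~((fr.molecule_id == 1) & (fr.role == Role.lipid_tail))
        fr = fr.select(keep)
        with pytest.raises(ValueError, match="1"):
            assign_leaflets(fr)


class TestMidplaneGrid:
    def test_flat_bilayer_midplane_is_zero(self):
        fr = flat_bilayer(n_side=40, z0=10.0)
        labels = assign_leaflets(fr)
        grid = midplane_grid(fr, labels, n_bins=10)
        assert grid.valid.all()
        np.testing.assert_allclose(grid.z_midplane, 10.0, atol=1e-12)

    def test_noiseless_dome_within_bin_variation(self, spec, topology,
                                                 surface_and_truth):
        surf, _ = surface_and_truth
        vert = dataclasses.replace(spec, head_placement="vertical",
                                   lipid_density=6.0, marker_jitter=0.0)
        fr, labels = sample_bilayer_frame(surf, vert, seed=11,
                                          with_undulations=False,
                                          with_protein=False)
        grid = midplane_grid(fr, assign_leaflets(fr), n_bins=25)
        L = spec.patch_size
        c = grid.centers - L / 2
        X, Y = np.meshgrid(c, c, indexing="ij")
        z_true = surf.z(X, Y, spec.dome_height)
        # bound: max within-bin variation of the surface around each center
        w = grid.bin_width
        offs = np.linspace(-w / 2, w / 2, 5)
        lo = np.full(X.shape, np.inf)
        hi = np.full(X.shape, -np.inf)
        for dx in offs:
            for dy in offs:
                v = surf.z(X + dx, Y + dy, spec.dome_height)
                lo = np.minimum(lo, v)
                hi = np.maximum(hi, v)
        dev = np.abs(grid.z_midplane - spec.box_Lz / 2 - z_true)
        bound = (hi - lo) + 1e-9
        assert np.all(dev[grid.valid] <= bound[grid.valid])

    def test_single_head_bin_flagged_and_filled_from_neighbors(self):
        fr = flat_bilayer(n_side=40, z0=10.0)
        labels = assign_leaflets(fr)
        # empty one interior bin except a single upper head (10 bins, w=2)
        bx, by = 4, 5
        w = 2.0
        in_bin = ((fr.positions[:, 0] >= bx * w) & (fr.positions[:, 0] < (bx + 1) * w)
                  & (fr.positions[:, 1] >= by * w) & (fr.positions[:, 1] < (by + 1) * w))
        heads_in_bin = np.flatnonzero(in_bin & (fr.role == Role.lipid_head))
        keep_head_mol = fr.molecule_id[heads_in_bin[0]]
        drop = in_bin & (fr.molecule_id != keep_head_mol)
        fr2 = fr.select(~drop)
        grid = midplane_grid(fr2, assign_leaflets(fr2), n_bins=10)
        assert not grid.valid[bx, by]
        nb = [grid.z_midplane[bx + 1, by], grid.z_midplane[bx - 1, by],
              grid.z_midplane[bx, by + 1], grid.z_midplane[bx, by - 1]]
        assert grid.z_midplane[bx, by] == pytest.approx(np.mean(nb))

    def test_only_head_beads_enter_the_height_fields(self, spec, topology,
                                                     surface_and_truth):
        surf, _ = surface_and_truth
        fr, labels = sample_bilayer_frame(surf, spec, seed=5)
        g1 = midplane_grid(fr, assign_leaflets(fr), n_bins=25)
        no_protein = fr.select(fr.role != Role.protein)
        g2 = midplane_grid(no_protein, assign_leaflets(no_protein), n_bins=25)
        np.testing.assert_array_equal(g1.z_midplane, g2.z_midplane)

    def test_reconstruction_error_shrinks_with_density(self, spec,
                                                       surface_and_truth):
        surf, _ = surface_and_truth
        errs = []
        for dens in (1.5, 12.0):
            sp = dataclasses.replace(spec, lipid_density=dens,
                                     head_placement="vertical")
            fr, _ = sample_bilayer_frame(surf, sp, seed=21,
                                         with_undulations=False,
                                         with_protein=False)
            grid = midplane_grid(fr, assign_leaflets(fr), n_bins=25)
            c = grid.centers - spec.patch_size / 2
            X, Y = np.meshgrid(c, c, indexing="ij")
            z_true = surf.z(X, Y, spec.dome_height) + spec.box_Lz / 2
            errs.append(np.sqrt(np.mean(
                (grid.z_midplane[grid.valid] - z_true[grid.valid]) ** 2)))
        assert errs[1] < errs[0]

    def test_empty_boundary_row_suggests_coarser_binning(self):
        fr = flat_bilayer(n_side=40, z0=10.0)
        keep = fr.positions[:, 0] >= 2.0  # empty first bin column
        fr = fr.select(keep)
        with pytest.raises(ValueError, match="coarser"):
            midplane_grid(fr, assign_leaflets(fr), n_bins=10)

    def test_n_bins_floor(self):
        fr = flat_bilayer()
        with pytest.raises(ValueError):
            midplane_grid(fr, assign_leaflets(fr), n_bins=3)
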