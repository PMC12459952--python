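"""Per-frame membrane midplane reconstruction.

One bead frame is turned into a continuous midplane height field by:
recentering on the ion channel, separating lipid head beads into the two
leaflets, binning head heights on an n x n square lattice, averaging the
leaflet surfaces, and bilinearly interpolating over bins with too few
heads.  The midplane of a bin is the mean of the upper- and lower-leaflet
average head heights in that bin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from nanodome.frame_io import BeadFrame, ProteinTopology, Role


def _molecule_com(frame: BeadFrame, mask: np.ndarray) -> np.ndarray:
    """Center of mass (uniform bead mass) of the selected particles."""
    return frame.positions[mask].mean(axis=0)


def recenter_and_wrap(frame: BeadFrame, topology: ProteinTopology) -> BeadFrame:
    """Translate so the channel COM sits at the box center; wrap molecules.

    The ion channel is the set of backbone particles of the three channel
    helices (helix 38 of each arm).  After the translation every molecule
    is wrapped back into the box *as a whole*, by the periodic image of its
    center of mass, so lipids are never split across the boundary.
    """
    ch_res = topology.channel_residues()
    mask = (np.isin(frame.molecule_id, ch_res)
            & (frame.particle == topology.backbone_particle)
            & (frame.role == Role.protein))
    if not mask.any():
        raise ValueError(
            "frame has no backbone particles of the channel helices "
            f"(topology residues {ch_res[:6]}..., backbone "
            f"{topology.backbone_particle!r})"
        )
    com = _molecule_com(frame, mask)
    shift = frame.box / 2.0 - com
    pos = frame.positions + shift

    # wrap each molecule by its COM so molecules stay whole
    order = np.argsort(frame.molecule_id, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    mol_sorted = frame.molecule_id[order]
    uniq, start = np.unique(mol_sorted, return_index=True)
    counts = np.diff(np.append(start, len(mol_sorted)))
    sums = np.add.reduceat(pos[order], start, axis=0)
    coms = sums / counts[:, None]
    wrap = np.floor(coms / frame.box)  # images to subtract, per molecule
    per_particle_wrap = np.repeat(wrap, counts, axis=0)[inv]
    pos = pos - per_particle_wrap * frame.box
    return replace(frame, positions=pos)


def assign_leaflets(frame: BeadFrame) -> np.ndarray:
    """Leaflet label per lipid *head bead*: +1 upper, -1 lower.

    A head bead is labelled ``upper`` iff its z exceeds the mean z of the
    tail beads of its own molecule.  This head-vs-own-tail rule is local
    and therefore robust on strongly curved membranes, unlike a global
    midplane cut.

    Returns an array aligned with the head beads of the frame (i.e. with
    ``frame.positions[frame.role == Role.lipid_head]``).
    """
    is_head = frame.role == Role.lipid_head
    is_tail = frame.role == Role.lipid_tail
    head_mol = frame.molecule_id[is_head]
    tail_mol = frame.molecule_id[is_tail]
    missing = np.setdiff1d(head_mol, tail_mol)
    if missing.size:
        raise ValueError(f"lipids without tail beads: {missing[:10].tolist()}")

    # mean tail z per molecule
    uniq, idx = np.unique(tail_mol, return_inverse=True)
    tail_sum = np.zeros(len(uniq))
    tail_cnt = np.zeros(len(uniq))
    np.add.at(tail_sum, idx, frame.positions[is_tail, 2])
    np.add.at(tail_cnt, idx, 1.0)
    tail_mean = tail_sum / tail_cnt

    pos = np.searchsorted(uniq, head_mol)
    labels = np.where(frame.positions[is_head, 2] > tail_mean[pos], 1, -1)
    return labels.astype(np.int8)


@dataclass
class MidplaneGrid:
    """Binned membrane midplane heights of one frame, with a continuous
    bilinear evaluator between bin centers (periodic across the box)."""

    n_bins: int
    bin_width: float            # nm
    box: np.ndarray             # (3,)
    z_upper: np.ndarray         # (n, n) mean head z, upper leaflet
    z_lower: np.ndarray
    z_midplane: np.ndarray      # (n, n), finite everywhere after fill
    valid: np.ndarray           # (n, n) bool: >=2 heads in each leaflet
    head_counts: np.ndarray     # (n, n) all head beads per bin
    time: float = 0.0           # ns

    def __post_init__(self) -> None:
        self._interp = None
        self._interp_counts = None

    @property
    def centers(self) -> np.ndarray:
        """Bin-center coordinates along one axis (box frame, nm)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def _build(self, values: np.ndarray) -> RegularGridInterpolator:
        # pad one periodic ring so the evaluator covers the full box
        c = self.centers
        cx = np.concatenate([[c[0] - self.bin_width], c, [c[-1] + self.bin_width]])
        v = np.pad(values, 1, mode="wrap")
        return RegularGridInterpolator((cx, cx), v, method="linear",
                                       bounds_error=False, fill_value=None)

    def evaluate(self, x, y) -> np.ndarray:
        """Continuous midplane height at box coordinates (x, y), nm."""
        if self._interp is None:
            self._interp = self._build(self.z_midplane)
        pts = np.stack(np.broadcast_arrays(x, y), axis=-1)
        return self._interp(pts)

    def evaluate_counts(self, x, y) -> np.ndarray:
        """Continuous interpolated head count per bin at (x, y)."""
        if self._interp_counts is None:
            self._interp_counts = self._build(self.head_counts.astype(float))
        pts = np.stack(np.broadcast_arrays(x, y), axis=-1)
        return self._interp_counts(pts)


def _fill_invalid(z: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Iterative bilinear fill of invalid bins from valid axis neighbors.

    Each pass assigns every still-invalid bin the mean of its already
    filled 4-neighbors (periodic at the boundary); passes repeat until no
    invalid bins remain.
    """
    z = z.copy()
    filled = valid.copy()
    if not filled.any():
        raise ValueError("no valid bins: membrane too sparse for this binning")
    while not filled.all():
        nb_sum = np.zeros_like(z)
        nb_cnt = np.zeros_like(z)
        for axis in (0, 1):
            for shift in (1, -1):
                v = np.roll(np.where(filled, z, 0.0), shift, axis=axis)
                f = np.roll(filled, shift, axis=axis)
                nb_sum += np.where(f, v, 0.0)
                nb_cnt += f
        newly = (~filled) & (nb_cnt > 0)
        if not newly.any():  # pragma: no cover - unreachable on connected grids
            raise RuntimeError("fill stalled")
        z[newly] = nb_sum[newly] / nb_cnt[newly]
        filled |= newly
    return z


def midplane_grid(frame: BeadFrame, labels: np.ndarray,
                  n_bins: int = 25) -> MidplaneGrid:
    """Bin lipid head beads into an n x n lattice and form the midplane.

    Parameters
    ----------
    frame : BeadFrame
        A recentered frame (see :func:`recenter_and_wrap`).
    labels : array
        Leaflet labels (+1/-1) aligned with the frame's head beads, from
        :func:`assign_leaflets`.
    n_bins : int
        Lattice size; defaults to 25 (coarse-grained convention; 17 is the
        matching choice for smaller atomistic boxes).

    Bins with fewer than two head beads in either leaflet are flagged
    invalid and filled by iterative bilinear interpolation from valid
    neighbors; the lipid count grid covers all bins.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    is_head = frame.role == Role.lipid_head
    heads = frame.positions[is_head]
    if len(labels) != len(heads):
        raise ValueError("labels must align with the frame's head beads")
    Lx, Ly = frame.box[0], frame.box[1]
    bw = Lx / n_bins
    ix = np.clip((heads[:, 0] / bw).astype(int), 0, n_bins - 1)
    iy = np.clip((heads[:, 1] / (Ly / n_bins)).astype(int), 0, n_bins - 1)

    def leaflet_stats(sel):
        cnt = np.zeros((n_bins, n_bins))
        zs = np.zeros((n_bins, n_bins))
        np.add.at(cnt, (ix[sel], iy[sel]), 1.0)
        np.add.at(zs, (ix[sel], iy[sel]), heads[sel, 2])
        with np.errstate(invalid="ignore", divide="ignore"):
            return cnt, np.where(cnt > 0, zs / np.maximum(cnt, 1), np.nan)

    cnt_up, z_up = leaflet_stats(labels > 0)
    cnt_lo, z_lo = leaflet_stats(labels < 0)
    valid = (cnt_up >= 2) & (cnt_lo >= 2)

    for axis, name in ((0, "row"), (1, "column")):
        edge_idx = (0, n_bins - 1)
        for e in edge_idx:
            line = np.take(valid, e, axis=axis)
            if not line.any():
                raise ValueError(
                    f"boundary {name} {e} has no valid bins; "
                    "use coarser binning (smaller n_bins)"
                )

    z_mid = np.where(valid, 0.5 * (z_up + z_lo), np.nan)
    z_mid = _fill_invalid(np.nan_to_num(z_mid), valid)
    return MidplaneGrid(
        n_bins=n_bins, bin_width=bw, box=frame.box.copy(),
        z_upper=z_up, z_lower=z_lo, z_midplane=z_mid, valid=valid,
        head_counts=cnt_up + cnt_lo, time=frame.time,
    )
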