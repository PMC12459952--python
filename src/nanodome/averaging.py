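"""Rotational alignment and threefold-symmetrized shape averaging.

Proteins diffuse rotationally along a trajectory, so per-frame midplane
shapes are rotated about the channel axis to a common reference before
averaging.  Because the channel is a trimer, each aligned shape also
contributes its 120- and 240-degree rotated copies, which imposes exact
threefold symmetry on the average.  Averages live on a square lattice
(lattice constant ``a``, default 1 nm) restricted to the inscribed disk of
diameter ``d_m``, the mean box width — only that disk overlaps in all
rotated conformations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from nanodome.surface import MidplaneGrid


def _rotate_xy(x, y, angle_deg: float):
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    return c * x - s * y, c * y + s * x


def rotational_align(grid: MidplaneGrid, channel_helix_xy: np.ndarray,
                     reference: np.ndarray) -> tuple[float, "AlignedShape"]:
    """Find the z-axis rotation aligning the channel helices to a reference.

    Parameters
    ----------
    grid : MidplaneGrid
        The frame's midplane grid.
    channel_helix_xy, reference : (3, 2) arrays
        In-plane centers of mass of the three channel helices, in
        channel-centered coordinates (both triplets centered on the
        rotation axis).

    Returns
    -------
    (angle_deg, AlignedShape)
        The angle (degrees, in [0, 360)) minimizing the summed squared
        x-y distance between the rotated helix COMs and the reference over
        the three cyclic pairings, and the correspondingly rotated
        continuous shape.  Ties break toward the smallest non-negative
        angle.
    """
    p = np.asarray(channel_helix_xy, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != (3, 2) or r.shape != (3, 2):
        raise ValueError("helix COM triplets must be (3, 2) arrays")
    for trip in (p, r):
        if np.any(np.linalg.norm(trip, axis=1) < 1e-9):
            raise ValueError("degenerate helix triplet: point on the rotation axis")
        u, v = trip[1] - trip[0], trip[2] - trip[0]
        area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        if area < 1e-9:
            raise ValueError("degenerate helix triplet: collinear points")

    best = None
    for k in range(3):
        tgt = r[np.roll(np.arange(3), -k)]
        # optimal rotation angle for this pairing (2D orthogonal Procrustes)
        num = np.sum(p[:, 0] * tgt[:, 1] - p[:, 1] * tgt[:, 0])
        den = np.sum(p[:, 0] * tgt[:, 0] + p[:, 1] * tgt[:, 1])
        theta = math.degrees(math.atan2(num, den)) % 360.0
        c, s = math.cos(math.radians(theta)), math.sin(math.radians(theta))
        rot = p @ np.array([[c, s], [-s, c]])
        resid = float(np.sum((rot - tgt) ** 2))
        cand = (round(resid, 12), theta)
        if best is None or cand < best:
            best = cand
    angle = best[1] % 360.0
    if angle > 360.0 - 1e-9:
        angle = 0.0
    return angle, AlignedShape(grid=grid, angle=angle)


@dataclass
class AlignedShape:
    """A midplane grid viewed in channel-centered, rotation-aligned
    coordinates.  ``evaluate(x, y)`` rotates the query back into the frame
    of the underlying grid."""

    grid: MidplaneGrid
    angle: float = 0.0  # degrees applied to the shape

    @property
    def box_xy(self) -> tuple[float, float]:
        return float(self.grid.box[0]), float(self.grid.box[1])

    @property
    def time(self) -> float:
        return self.grid.time

    def _to_grid_coords(self, x, y):
        xr, yr = _rotate_xy(np.asarray(x, float), np.asarray(y, float), -self.angle)
        return xr + self.grid.box[0] / 2.0, yr + self.grid.box[1] / 2.0

    def evaluate(self, x, y) -> np.ndarray:
        gx, gy = self._to_grid_coords(x, y)
        return self.grid.evaluate(gx, gy)

    def evaluate_counts(self, x, y) -> np.ndarray:
        gx, gy = self._to_grid_coords(x, y)
        return self.grid.evaluate_counts(gx, gy)


@dataclass
class AveragedShape:
    """Aligned, optionally threefold-symmetrized, disk-masked mean shape.

    ``z`` and ``rho`` are defined on the square lattice ``coords`` x
    ``coords`` (channel-centered) at sites with x^2+y^2 <= (d_m/2)^2 and
    are NaN outside.  ``rho`` is the relative lipid density, normalized to
    ~1 far from the protein.  A continuous evaluator interpolates
    bilinearly between lattice sites; queries beyond the disk return the
    boundary value along the same direction.
    """

    a: float                     # lattice constant, nm
    coords: np.ndarray           # (m,) lattice coordinates, centered on 0
    z: np.ndarray                # (m, m), NaN outside the disk
    rho: np.ndarray | None       # (m, m) relative lipid density, or None
    d_m: float                   # disk diameter, nm
    n_frames: int = 1
    window: tuple[float, float] | None = None   # (start, end) ns
    function: Callable | None = None  # exact evaluator, if analytic

    def __post_init__(self) -> None:
        self._interp = None

    @classmethod
    def from_function(cls, fn: Callable, a: float, d_m: float,
                      rho_fn: Callable | None = None) -> "AveragedShape":
        """Build a shape from an analytic height function z = fn(x, y).

        The function itself serves as the continuous evaluator (clamped to
        the disk boundary), so geometry operations see exact values."""
        n = int(math.floor(d_m / 2.0 / a))
        coords = np.arange(-n, n + 1) * a
        X, Y = np.meshgrid(coords, coords, indexing="ij")
        inside = X**2 + Y**2 <= (d_m / 2.0) ** 2
        z = np.where(inside, np.asarray(fn(X, Y), dtype=float), np.nan)
        rho = None
        if rho_fn is not None:
            rho = np.where(inside, np.asarray(rho_fn(X, Y), dtype=float), np.nan)
        return cls(a=a, coords=coords, z=z, rho=rho, d_m=d_m, function=fn)

    @property
    def inside(self) -> np.ndarray:
        X, Y = np.meshgrid(self.coords, self.coords, indexing="ij")
        return X**2 + Y**2 <= (self.d_m / 2.0) ** 2

    def _clamp(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r = np.hypot(x, y)
        R = self.d_m / 2.0
        scale = np.where(r > R, R / np.maximum(r, 1e-300), 1.0)
        return x * scale, y * scale

    def evaluate(self, x, y, clamp: bool = False) -> np.ndarray:
        """Continuous height at (x, y).

        With ``clamp`` queries beyond the disk return the boundary value
        along the same direction; otherwise the continuous shape is
        evaluated at the requested point (the analytic function, or the
        lattice interpolant extended past the disk), which is what the
        one-ring-inset difference stencils need.
        """
        if clamp:
            x, y = self._clamp(x, y)
        if self.function is not None:
            return np.asarray(self.function(x, y), dtype=float)
        if self._interp is None:
            filled = _nearest_fill(self.z, np.isfinite(self.z))
            self._interp = RegularGridInterpolator(
                (self.coords, self.coords), filled, method="linear",
                bounds_error=False, fill_value=None)
        pts = np.stack(np.broadcast_arrays(x, y), axis=-1)
        return self._interp(pts)

    def with_offset(self, c: float) -> "AveragedShape":
        fn = None
        if self.function is not None:
            base = self.function
            fn = lambda x, y: base(x, y) + c  # noqa: E731
        return AveragedShape(a=self.a, coords=self.coords, z=self.z + c,
                             rho=self.rho, d_m=self.d_m,
                             n_frames=self.n_frames, window=self.window,
                             function=fn)


def _nearest_fill(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid lattice sites by repeated 4-neighbor averaging so the
    interpolator has support up to the lattice hull (non-periodic)."""
    v = np.where(valid, values, 0.0)
    filled = valid.copy()
    while not filled.all():
        nb_sum = np.zeros_like(v)
        nb_cnt = np.zeros_like(v)
        for axis in (0, 1):
            for shift in (1, -1):
                sv = np.zeros_like(v)
                sf = np.zeros(v.shape, dtype=bool)
                src = slice(None, -1) if shift == 1 else slice(1, None)
                dst = slice(1, None) if shift == 1 else slice(None, -1)
                idx_src = (src, slice(None)) if axis == 0 else (slice(None), src)
                idx_dst = (dst, slice(None)) if axis == 0 else (slice(None), dst)
                sv[idx_dst] = v[idx_src]
                sf[idx_dst] = filled[idx_src]
                nb_sum += np.where(sf, sv, 0.0)
                nb_cnt += sf
        newly = (~filled) & (nb_cnt > 0)
        if not newly.any():
            raise RuntimeError("nearest fill stalled")
        v[newly] = nb_sum[newly] / nb_cnt[newly]
        filled |= newly
    return v


def average_shapes(shapes: Sequence, a: float = 1.0,
                   symmetrize: bool = True,
                   far_field_fraction: float = 0.8) -> AveragedShape:
    """Average aligned shapes site-wise on the ``a``-lattice.

    Each input contributes itself plus its 120- and 240-degree rotated
    copies when ``symmetrize`` is on, which makes the output exactly
    invariant under 120-degree rotations.  The disk diameter ``d_m`` is the
    mean of the inputs' box x and y dimensions.  The relative lipid density
    ``rho`` is the mean interpolated head count per bin normalized by its
    far-field mean (sites with r > ``far_field_fraction`` * d_m/2).
    """
    shapes = list(shapes)
    if not shapes:
        raise ValueError("no shapes to average")
    d_m = float(np.mean([np.mean(s.box_xy) for s in shapes]))
    n = int(math.floor(d_m / 2.0 / a))
    coords = np.arange(-n, n + 1) * a
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    inside = X**2 + Y**2 <= (d_m / 2.0) ** 2
    Xi, Yi = X[inside], Y[inside]

    angles = (0.0, 120.0, 240.0) if symmetrize else (0.0,)
    z_acc = np.zeros(Xi.shape)
    c_acc = np.zeros(Xi.shape)
    have_counts = all(hasattr(s, "evaluate_counts") for s in shapes)
    m = 0
    for s in shapes:
        for ang in angles:
            # rotating the shape by +ang samples the source at -ang
            xq, yq = _rotate_xy(Xi, Yi, -ang)
            z_acc += s.evaluate(xq, yq)
            if have_counts:
                c_acc += s.evaluate_counts(xq, yq)
            m += 1
    z = np.full(X.shape, np.nan)
    z[inside] = z_acc / m
    rho = None
    if have_counts:
        counts = np.full(X.shape, np.nan)
        counts[inside] = c_acc / m
        far = inside & (np.hypot(X, Y) > far_field_fraction * d_m / 2.0)
        far_mean = float(np.nanmean(counts[far]))
        if far_mean <= 0:
            raise ValueError("far-field lipid count is zero; cannot normalize rho")
        rho = counts / far_mean

    times = [s.time for s in shapes]
    return AveragedShape(a=a, coords=coords, z=z, rho=rho, d_m=d_m,
                         n_frames=len(shapes),
                         window=(float(min(times)), float(max(times))))
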