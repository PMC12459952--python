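"""Synthetic nanodome generator with analytic ground truth.

Generates bead-cloud frames that emulate the statistical structure of
coarse-grained membrane-protein trajectories: a threefold-capable dome of
a few nm height over a ~50 x 50 nm^2 periodic patch, two lipid leaflets of
head/tail beads at realistic areal density, thermal undulations with a
Helfrich spectrum ~ k_B T / (kappa q^4 + gamma q^2), a central region
depleted of lipids with pseudo-protein marker beads (three channel-helix
strings and 3 x 9 unit-COM markers along spiraling arms), and a slow 1/t
relaxation of the dome's excess area.

Ground truth (excess area, bending energy, curvature profile) is computed
by fine-grid quadrature of the closed-form surface derivatives, at a
resolution 20x finer than the default analysis lattice.  Trajectories can
embed a harmonic protein spring (F0*, k*) together with an area response
slope; the dome width is calibrated once per parameter set so that the
noiseless observables reproduce the embedded spring exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import sympy as sp
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq

from nanodome.frame_io import BeadFrame, ProteinTopology, Role
from nanodome.geometry import kbt_pn_nm

TAIL_TYPES = ("flat", "catenoid", "screened-exponential")

#: residue-id offsets for pseudo-protein markers (clear of lipid ids)
_HELIX_RES_BASE = 1_000_000
_UNIT_RES_BASE = 2_000_000

#: fractional depth of the 9 unit markers below the channel, relative to z4
_UNIT_DEPTH_PROFILE = np.array(
    [0.35, 0.60, 0.85, 1.00, 0.92, 0.80, 0.65, 0.50, 0.35])
#: radial positions of the unit markers (nm from the channel axis)
_UNIT_RADII = 3.0 + 1.125 * np.arange(9)


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of the synthetic nanodome and its trajectory statistics.

    Defaults reflect the coarse-grained study conditions this generator
    emulates: a ~5 nm dome over a 50 x 50 nm^2 patch, POPC-like areal
    density, kappa = 25 k_B T, a ~40 nm^2 tensionless excess area, and a
    harmonic protein spring near 90 pN / 60 pN/nm.
    """

    dome_height: float = 5.0          # nm
    dome_sigma: float = 6.0           # nm, Gaussian width of the dome
    tail: str = "flat"                # far-field shape beyond the dome
    tail_amplitude: float = 0.3       # nm, amplitude of the tail term
    patch_size: float = 50.0          # nm, L of the L x L periodic patch
    protein_radius: float = 2.0       # nm, lipid-depleted channel core
    threefold_amplitude: float = 0.0  # nm, optional 3-fold perturbation
    kappa_gen: float = 25.0           # k_B T, undulation rigidity
    gamma_gen: float = 0.0            # mN/m, undulation tension
    mode_cutoff: float = 1.5          # 1/nm, undulation q cutoff
    lipid_density: float = 1.5        # heads per nm^2 per leaflet
    half_thickness: float = 2.0       # nm, head offset from the midplane
    head_placement: str = "normal"    # "normal" or "vertical" offsets
    marker_jitter: float = 0.2        # nm, per-frame marker position noise
    # relaxation DA(t) = DA_inf + c/t
    dA_inf: float = 40.0              # nm^2, asymptotic excess area (gamma=0)
    relax_c: float = 0.0              # nm^2 * ns
    # embedded protein spring and response
    F0_star: float = 90.0             # pN, spring force at dz = 0
    k_star: float = 60.0              # pN/nm, spring force constant
    dA_ddz_star: float = -15.0        # nm, area response slope
    gamma_cap: float = 6.0            # mN/m, linear-response range of dz(gamma)
    z4_0: float = 3.7                 # nm, tensionless unit-4 displacement
    box_Lz: float = 20.0              # nm
    T: float = 310.0                  # K
    seed: int = 0

    def __post_init__(self):
        if self.tail not in TAIL_TYPES:
            raise ValueError(f"tail must be one of {TAIL_TYPES}")
        for name in ("dome_sigma", "patch_size", "protein_radius",
                     "half_thickness", "lipid_density", "box_Lz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tail != "flat" and self.tail_amplitude > 0.25 * self.patch_size:
            raise ValueError("tail amplitude incompatible with patch size")


@dataclass
class TruthRecord:
    """Analytic/oracle ground truth accompanying generated data."""

    excess_area: float | None = None          # nm^2, quadrature
    bending_energy: float | None = None       # kappa units, rho-weighted
    bending_energy_bare: float | None = None  # kappa units, rho = 1
    curvature_profile: tuple | None = None    # (r, M) arrays
    leaflet_labels: np.ndarray | None = None
    dome_height: float | None = None
    spring: dict | None = None                # embedded (F0*, k*, slopes...)
    per_tension: pd.DataFrame | None = None
    quadrature_step: float = 0.05
    extras: dict = field(default_factory=dict)


class ParametricSurface:
    """Closed-form nanodome surface z(x, y) = h * g(x, y).

    The unit-height profile g combines a Gaussian dome, an optional
    far-field tail (catenoid-like logarithmic decay, or the
    screened-exponential decay expected under tension), and an optional
    threefold perturbation.  First and second derivatives are generated
    symbolically, so quadrature oracles see exact gradients and Hessians.
    """

    def __init__(self, sigma: float, tail: str = "flat",
                 tail_amplitude: float = 0.0, patch_size: float = 50.0,
                 threefold_amplitude: float = 0.0,
                 screening_length: float = 10.0):
        self.sigma = sigma
        self.tail = tail
        self.patch_size = patch_size
        x, y = sp.symbols("x y", real=True)
        r2 = x**2 + y**2
        g = sp.exp(-r2 / (2 * sigma**2))
        if tail == "catenoid" and tail_amplitude != 0.0:
            # logarithmic far field: the small-gradient catenoid
            R = patch_size / 2.0
            g = g + tail_amplitude * sp.log(R / sp.sqrt(r2 + sigma**2))
        elif tail == "screened-exponential" and tail_amplitude != 0.0:
            lam = screening_length
            g = g + tail_amplitude * sp.exp(-sp.sqrt(r2 + sigma**2) / lam)
        if threefold_amplitude != 0.0:
            g = g + threefold_amplitude * (x**3 - 3 * x * y**2) / sigma**3 \
                * sp.exp(-r2 / (2 * sigma**2))
        derivs = [g, g.diff(x), g.diff(y), g.diff(x, 2), g.diff(y, 2),
                  sp.diff(g, x, y)]
        fns = [sp.lambdify((x, y), d, modules="numpy") for d in derivs]
        self.g, self.gx, self.gy, self.gxx, self.gyy, self.gxy = fns
        self._quad_cache: dict = {}

    # -- closed-form evaluation ------------------------------------------
    def z(self, x, y, h: float):
        return h * np.asarray(self.g(x, y), dtype=float)

    def grad(self, x, y, h: float):
        return (h * np.asarray(self.gx(x, y), dtype=float),
                h * np.asarray(self.gy(x, y), dtype=float))

    def height_fn(self, h: float) -> Callable:
        return lambda x, y: h * np.asarray(self.g(x, y), dtype=float)

    # -- quadrature oracles ----------------------------------------------
    def _grids(self, R: float, step: float):
        key = (round(R, 9), round(step, 9))
        if key not in self._quad_cache:
            c = np.arange(-R + step / 2.0, R, step)
            X, Y = np.meshgrid(c, c, indexing="ij")
            inside = X**2 + Y**2 <= R**2
            Xi, Yi = X[inside], Y[inside]
            Ri = np.hypot(Xi, Yi)
            self._quad_cache[key] = {
                "r": Ri,
                "gx": np.asarray(self.gx(Xi, Yi), dtype=float),
                "gy": np.asarray(self.gy(Xi, Yi), dtype=float),
                "gxx": np.asarray(self.gxx(Xi, Yi), dtype=float),
                "gyy": np.asarray(self.gyy(Xi, Yi), dtype=float),
                "gxy": np.asarray(self.gxy(Xi, Yi), dtype=float),
            }
        return self._quad_cache[key]

    def quad_excess_area(self, h: float, R: float, step: float = 0.05,
                         rho_radius: float | None = None) -> float:
        """Oracle excess area by fine-grid quadrature of the exact gradient."""
        g = self._grids(R, step)
        grad2 = h**2 * (g["gx"]**2 + g["gy"]**2)
        dA = np.sqrt(1.0 + grad2) - 1.0
        return float(np.sum(dA) * step**2)

    def quad_bending_energy(self, h: float, R: float, step: float = 0.05,
                            rho_radius: float | None = None) -> float:
        """Oracle bending energy (kappa units) from exact derivatives.

        ``rho_radius`` mimics the lipid-density weighting: sites inside
        that radius (the protein disk) carry zero density.
        """
        g = self._grids(R, step)
        zx, zy = h * g["gx"], h * g["gy"]
        zxx, zyy, zxy = h * g["gxx"], h * g["gyy"], h * g["gxy"]
        s = zx**2 + zy**2
        H = (zxx * (1 + zy**2) + zyy * (1 + zx**2) - 2 * zxy * zx * zy) \
            / (2.0 * (1 + s) ** 1.5)
        e = 2.0 * H**2 * np.sqrt(1 + s)
        if rho_radius is not None:
            e = e * (g["r"] >= rho_radius)
        return float(np.sum(e) * step**2)

    def curvature_profile(self, h: float, R: float,
                          dr: float = 0.1, n_theta: int = 360):
        """Oracle angular-mean mean-curvature profile M(r)."""
        r = np.arange(dr / 2.0, R, dr)
        th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        X = r[:, None] * np.cos(th)[None, :]
        Y = r[:, None] * np.sin(th)[None, :]
        zx, zy = h * self.gx(X, Y), h * self.gy(X, Y)
        zxx, zyy = h * self.gxx(X, Y), h * self.gyy(X, Y)
        zxy = h * self.gxy(X, Y)
        s = zx**2 + zy**2
        H = (zxx * (1 + zy**2) + zyy * (1 + zx**2) - 2 * zxy * zx * zy) \
            / (2.0 * (1 + s) ** 1.5)
        return r, H.mean(axis=1)


def make_surface(spec: SurfaceSpec,
                 quadrature_step: float = 0.05) -> tuple[ParametricSurface, TruthRecord]:
    """Build the closed-form surface and its quadrature ground truth."""
    surf = ParametricSurface(
        sigma=spec.dome_sigma, tail=spec.tail,
        tail_amplitude=spec.tail_amplitude, patch_size=spec.patch_size,
        threefold_amplitude=spec.threefold_amplitude,
        screening_length=_screening_length(spec),
    )
    h = spec.dome_height
    R = spec.patch_size / 2.0
    r, M = surf.curvature_profile(h, R)
    truth = TruthRecord(
        excess_area=surf.quad_excess_area(h, R, quadrature_step),
        bending_energy=surf.quad_bending_energy(
            h, R, quadrature_step, rho_radius=spec.protein_radius),
        bending_energy_bare=surf.quad_bending_energy(h, R, quadrature_step),
        curvature_profile=(r, M),
        dome_height=h,
        quadrature_step=quadrature_step,
    )
    return surf, truth


def _screening_length(spec: SurfaceSpec) -> float:
    if spec.gamma_gen > 0:
        return math.sqrt(spec.kappa_gen * kbt_pn_nm(spec.T) / spec.gamma_gen)
    return 10.0


def make_topology(spec: SurfaceSpec | None = None) -> ProteinTopology:
    """Topology of the pseudo-protein markers produced by the generator."""
    residues = {}
    for arm in (1, 2, 3):
        for k in range(8):
            residues[_HELIX_RES_BASE + arm * 1000 + k] = (arm, None, 38)
        for unit in range(1, 10):
            helix = 4 * (unit - 1) + 1
            residues[_UNIT_RES_BASE + arm * 100 + unit] = (arm, unit, helix)
    constriction = tuple(_HELIX_RES_BASE + arm * 1000 + 3 for arm in (1, 2, 3))
    return ProteinTopology(residues=residues,
                           constriction_residues=constriction,
                           backbone_particle="BB")


def _undulation_field(spec: SurfaceSpec, rng: np.random.Generator,
                      n_grid: int = 64, gamma: float | None = None):
    """Sample a periodic Helfrich undulation field on an n x n grid.

    Mode amplitudes follow <|u_q|^2> = A * k_B T/(kappa q^4 + gamma q^2)
    with kappa in k_B T and gamma converted to k_B T/nm^2; modes beyond
    the cutoff (and q = 0) are zero.  Returns a periodic interpolator
    over the patch.
    """
    L = spec.patch_size
    A = L * L
    gam = spec.gamma_gen if gamma is None else gamma
    gam_kbt = gam / kbt_pn_nm(spec.T)  # mN/m = pN/nm -> kBT / nm^2
    q1 = 2 * np.pi * np.fft.fftfreq(n_grid, d=L / n_grid)
    QX, QY = np.meshgrid(q1, q1, indexing="ij")
    q2 = QX**2 + QY**2
    with np.errstate(divide="ignore"):
        S = 1.0 / (spec.kappa_gen * q2**2 + gam_kbt * q2)
    S[q2 == 0] = 0.0
    S[np.sqrt(q2) > spec.mode_cutoff] = 0.0
    C = (rng.standard_normal((n_grid, n_grid))
         + 1j * rng.standard_normal((n_grid, n_grid))) / np.sqrt(2.0)
    U = C * np.sqrt(n_grid**4 * S / A)
    u = np.sqrt(2.0) * np.fft.ifft2(U).real
    centers = (np.arange(n_grid) + 0.5) * (L / n_grid)
    cx = np.concatenate([[centers[0] - L / n_grid], centers,
                         [centers[-1] + L / n_grid]])
    up = np.pad(u, 1, mode="wrap")
    interp = RegularGridInterpolator((cx, cx), up, method="linear",
                                     bounds_error=False, fill_value=None)

    def evaluate(x, y):
        pts = np.stack([np.mod(x, L), np.mod(y, L)], axis=-1)
        return interp(pts)

    return evaluate, u


def sample_bilayer_frame(surface: ParametricSurface, spec: SurfaceSpec,
                         seed: int, h: float | None = None,
                         time: float = 0.0, gamma: float | None = None,
                         z4: float | None = None,
                         with_protein: bool = True,
                         with_undulations: bool = True,
                         ) -> tuple[BeadFrame, np.ndarray]:
    """Sample one bead frame from the surface.

    Lipid head beads are Poisson-sampled per leaflet at the target areal
    density outside the protein disk and placed at +- half thickness along
    the local surface normal (or vertically, in ``vertical`` mode); two
    tail beads per lipid sit between head and midplane.  A Helfrich
    undulation field is added to the membrane.  Pseudo-protein markers
    (channel helices + unit COMs) are placed near the apex.  Deterministic
    given ``seed``.

    Returns the frame and the generator's leaflet labels (+1 upper / -1
    lower), aligned with the frame's head beads.
    """
    rng = np.random.default_rng(seed)
    L = spec.patch_size
    h = spec.dome_height if h is None else h
    z4 = spec.z4_0 if z4 is None else z4
    zc = spec.box_Lz / 2.0
    t = spec.half_thickness

    if with_undulations:
        u_fn, _ = _undulation_field(spec, rng, gamma=gamma)
    else:
        u_fn = lambda x, y: np.zeros(np.shape(x))  # noqa: E731

    def leaflet(sign: int):
        n = rng.poisson(spec.lipid_density * L * L)
        xy = rng.uniform(0.0, L, size=(n, 2))
        if with_protein:
            r = np.hypot(xy[:, 0] - L / 2, xy[:, 1] - L / 2)
            xy = xy[r >= spec.protein_radius]
        xc, yc = xy[:, 0] - L / 2, xy[:, 1] - L / 2
        zs = surface.z(xc, yc, h) + np.asarray(u_fn(xy[:, 0], xy[:, 1]))
        if spec.head_placement == "vertical":
            nx = ny = np.zeros(len(xy))
            nz = np.ones(len(xy))
        else:
            gx, gy = surface.grad(xc, yc, h)
            norm = np.sqrt(1.0 + gx**2 + gy**2)
            nx, ny, nz = -gx / norm, -gy / norm, 1.0 / norm
        pts = {}
        for tag, frac in (("head", 1.0), ("tailA", 0.6), ("tailB", 0.25)):
            off = sign * frac * t
            pts[tag] = np.column_stack([
                xy[:, 0] + off * nx, xy[:, 1] + off * ny, zc + zs + off * nz])
        return pts, len(xy)

    up, n_up = leaflet(+1)
    lo, n_lo = leaflet(-1)

    blocks = []  # (positions, residue, particle, role, molecule_ids)
    mol_up = np.arange(1, n_up + 1)
    mol_lo = np.arange(n_up + 1, n_up + n_lo + 1)
    blocks.append((up["head"], "POPC", "PO4", Role.lipid_head, mol_up))
    blocks.append((lo["head"], "POPC", "PO4", Role.lipid_head, mol_lo))
    for tag, name in (("tailA", "C1A"), ("tailB", "C2A")):
        blocks.append((up[tag], "POPC", name, Role.lipid_tail, mol_up))
        blocks.append((lo[tag], "POPC", name, Role.lipid_tail, mol_lo))

    if with_protein:
        z_apex = zc + surface.z(0.0, 0.0, h)
        mpos, mres = [], []
        for arm in (1, 2, 3):
            phi = math.radians(120.0 * (arm - 1))
            hx, hy = 1.2 * math.cos(phi), 1.2 * math.sin(phi)
            for k in range(8):
                zk = z_apex - 1.75 + 0.5 * k
                mpos.append([L / 2 + hx, L / 2 + hy, zk])
                mres.append(_HELIX_RES_BASE + arm * 1000 + k)
            for unit in range(1, 10):
                r_i = _UNIT_RADII[unit - 1]
                ang = phi + math.radians(15.0 * (unit - 1))
                depth = _UNIT_DEPTH_PROFILE[unit - 1] * z4
                mpos.append([L / 2 + r_i * math.cos(ang),
                             L / 2 + r_i * math.sin(ang),
                             z_apex - depth])
                mres.append(_UNIT_RES_BASE + arm * 100 + unit)
        mpos = np.asarray(mpos)
        mpos = mpos + rng.normal(0.0, spec.marker_jitter, size=mpos.shape)
        blocks.append((mpos, "ALA", "BB", Role.protein, np.asarray(mres)))

    pos = np.vstack([b[0] for b in blocks])
    residue = np.concatenate([np.full(len(b[0]), b[1], dtype=object)
                              for b in blocks]).astype(str)
    particle = np.concatenate([np.full(len(b[0]), b[2], dtype=object)
                               for b in blocks]).astype(str)
    role = np.concatenate([np.full(len(b[0]), int(b[3]), dtype=np.int8)
                           for b in blocks])
    molecule = np.concatenate([np.asarray(b[4]) for b in blocks])
    box = np.array([L, L, spec.box_Lz])
    pos = np.mod(pos, box)

    pressures = None
    if gamma is not None:
        Px = 1.0 - 10.0 * gamma / spec.box_Lz
        pressures = (Px, Px, 1.0)

    frame = BeadFrame(
        particle_id=np.arange(1, len(pos) + 1), molecule_id=molecule,
        residue=residue, particle=particle, role=role, positions=pos,
        box=box, time=time, pressures=pressures,
    )
    labels = np.concatenate([np.ones(n_up, dtype=np.int8),
                             -np.ones(n_lo, dtype=np.int8)])
    return frame, labels


# ---------------------------------------------------------------------------
# noiseless measurement operator
# ---------------------------------------------------------------------------


def measure_noiseless(surf: ParametricSurface, spec: SurfaceSpec, h: float,
                      n_bins: int = 25, a: float = 1.0,
                      sample_step: float = 0.33) -> tuple[float, float]:
    """(excess area, bending energy) of the surface as the reconstruction
    pipeline would measure them at infinite lipid density and zero noise.

    Head positions are generated on a dense regular grid per leaflet
    (outside the protein disk), offset along the local normal, binned on
    the standard n x n lattice, combined into the midplane, and evaluated
    exactly like real frames.  This defines the generator's *observable*
    ground truth: it differs from the quadrature surface truth by the
    deterministic attenuation of binning, interpolation, and leaflet
    geometry that any bead-based measurement carries.
    """
    from nanodome.averaging import AlignedShape, average_shapes
    from nanodome.geometry import bending_energy, excess_area
    from nanodome.surface import MidplaneGrid, _fill_invalid

    L = spec.patch_size
    t = spec.half_thickness
    n_src = int(round(L / sample_step))
    c = (np.arange(n_src) + 0.5) * (L / n_src)
    X, Y = np.meshgrid(c, c, indexing="ij")
    xc, yc = (X - L / 2).ravel(), (Y - L / 2).ravel()
    keep = np.hypot(xc, yc) >= spec.protein_radius
    xc, yc = xc[keep], yc[keep]
    zs = surf.z(xc, yc, h)
    if spec.head_placement == "vertical":
        nx = ny = np.zeros_like(xc)
        nz = np.ones_like(xc)
    else:
        gx, gy = surf.grad(xc, yc, h)
        nrm = np.sqrt(1 + gx**2 + gy**2)
        nx, ny, nz = -gx / nrm, -gy / nrm, 1.0 / nrm

    bw = L / n_bins
    z_leaf = []
    cnt_tot = np.zeros((n_bins, n_bins))
    for sign in (+1, -1):
        hx = np.mod(xc + L / 2 + sign * t * nx, L)
        hy = np.mod(yc + L / 2 + sign * t * ny, L)
        hz = zs + sign * t * nz
        ix = np.clip((hx / bw).astype(int), 0, n_bins - 1)
        iy = np.clip((hy / bw).astype(int), 0, n_bins - 1)
        cnt = np.zeros((n_bins, n_bins))
        acc = np.zeros((n_bins, n_bins))
        np.add.at(cnt, (ix, iy), 1.0)
        np.add.at(acc, (ix, iy), hz)
        with np.errstate(invalid="ignore"):
            z_leaf.append(np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan))
        cnt_tot += cnt
    valid = np.isfinite(z_leaf[0]) & np.isfinite(z_leaf[1])
    z_mid = np.where(valid, 0.5 * (z_leaf[0] + z_leaf[1]), 0.0)
    z_mid = _fill_invalid(z_mid, valid)
    grid = MidplaneGrid(n_bins=n_bins, bin_width=bw,
                        box=np.array([L, L, spec.box_Lz]),
                        z_upper=z_leaf[0], z_lower=z_leaf[1],
                        z_midplane=z_mid, valid=valid,
                        head_counts=cnt_tot, time=0.0)
    avg = average_shapes([AlignedShape(grid=grid, angle=0.0)], a=a,
                         symmetrize=True)
    return excess_area(avg), bending_energy(avg)


# ---------------------------------------------------------------------------
# trajectory synthesis with an embedded harmonic spring
# ---------------------------------------------------------------------------

_CAL_CACHE: dict = {}
_CAL_STEP = 0.1  # nm, quadrature step used for surface-truth entries


def _spring_key(spec: SurfaceSpec) -> tuple:
    return (spec.tail, spec.tail_amplitude, spec.patch_size,
            spec.protein_radius, spec.threefold_amplitude, spec.kappa_gen,
            spec.dA_inf, spec.F0_star, spec.k_star, spec.dA_ddz_star,
            spec.T)


def _make_surf(spec: SurfaceSpec, sigma: float) -> ParametricSurface:
    return ParametricSurface(
        sigma=sigma, tail=spec.tail, tail_amplitude=spec.tail_amplitude,
        patch_size=spec.patch_size,
        threefold_amplitude=spec.threefold_amplitude,
        screening_length=_screening_length(spec))


def _measured_tables(surf: ParametricSurface, spec: SurfaceSpec,
                     h_max: float = 13.0, n: int = 27):
    hs = np.linspace(0.0, h_max, n)
    meas = [measure_noiseless(surf, spec, h) for h in hs]
    dAs = np.array([m[0] for m in meas])
    ebs = np.array([m[1] for m in meas])
    return hs, dAs, ebs


def calibrate_spring(spec: SurfaceSpec) -> dict:
    """Calibrate the dome width so the noiseless observables reproduce the
    embedded spring (F0*, k*) and area slope exactly.

    Observables are defined through :func:`measure_noiseless` — the
    reconstruction pipeline applied at infinite density — so the embedded
    relations hold for what the analysis actually measures.  The target
    bending-energy slope is dE_b/dDz = -F0*/(kappa k_B T); the dome width
    sigma controls how much bending energy a given excess area carries
    (small-gradient limit E_b ~ 2 DA / sigma^2), so sigma is root-found
    against the measured E_b-vs-Dz slope.  Cached per parameter set.
    """
    key = _spring_key(spec)
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    kbt = kbt_pn_nm(spec.T)
    s_E_target = -spec.F0_star / (spec.kappa_gen * kbt)  # kappa / nm
    s_A = spec.dA_ddz_star
    dz_grid = np.linspace(0.0, 1.5, 6)
    dA_targets = spec.dA_inf + s_A * dz_grid

    def tables(sigma):
        return _measured_tables(_make_surf(spec, sigma), spec)

    def eb_slope(sigma):
        hs, dAs, ebs = tables(sigma)
        h_tgt = np.interp(dA_targets, dAs, hs)
        eb_tgt = np.interp(h_tgt, hs, ebs)
        return float(np.polyfit(dz_grid, eb_tgt, 1)[0])

    sigma_cal = brentq(lambda s: eb_slope(s) - s_E_target, 3.0, 13.0,
                       xtol=5e-3)
    surf = _make_surf(spec, sigma_cal)
    hs, dAs, ebs = tables(sigma_cal)
    out = {
        "sigma": sigma_cal,
        "surface": surf,
        "h_table": hs, "dA_table": dAs, "eb_table": ebs,
        "c_gamma": abs(s_A) / spec.k_star,  # nm per mN/m
        "s_E": s_E_target,
    }
    _CAL_CACHE[key] = out
    return out


def _child_seed(master: int, *path: int) -> int:
    """Documented counter scheme: one SeedSequence child per index path."""
    ss = np.random.SeedSequence([int(master), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31))


def make_trajectory(spec: SurfaceSpec, tensions: Sequence[float],
                    n_runs: int = 2, n_frames: int = 10, seed: int = 0,
                    frame_interval: float = 20.0,
                    ) -> tuple[dict, TruthRecord]:
    """Generate runs of bead frames per tension, with embedded spring truth.

    Per tension gamma the protein height change is dz = c_gamma * gamma
    (capped at ``gamma_cap``), the asymptotic excess area is
    DA_inf(gamma) = DA_inf + dA_ddz* . dz, and each frame's dome height is
    set so the instantaneous excess area follows DA(t) = DA_inf(gamma) +
    c/t.  Per-frame pressures invert the tension relation gamma =
    Lz (Pz - (Px+Py)/2) exactly.  Seeds for every (tension, run, frame)
    derive from the master seed by a counter scheme, so runs are
    independent and the whole trajectory is reproducible.

    Returns ``(runs_by_tension, truth)`` where ``runs_by_tension`` maps
    gamma to a list of runs, each a list of frames.
    """
    tensions = list(tensions)
    if not tensions:
        raise ValueError("tensions must be non-empty")
    cal = calibrate_spring(spec)
    surf: ParametricSurface = cal["surface"]
    h_of_dA = lambda dA: float(np.interp(dA, cal["dA_table"], cal["h_table"]))  # noqa: E731

    runs_by_tension: dict = {}
    rows = []
    heights: dict = {}
    for ti, gamma in enumerate(tensions):
        g_eff = min(gamma, spec.gamma_cap)
        dz = cal["c_gamma"] * g_eff
        dA_inf = spec.dA_inf + spec.dA_ddz_star * dz
        if dA_inf <= 0:
            raise ValueError(f"tension {gamma}: asymptotic excess area <= 0")
        h_inf = h_of_dA(dA_inf)
        z4 = spec.z4_0 - dz
        runs = []
        for run in range(n_runs):
            frames = []
            for j in range(n_frames):
                t_ns = (j + 1) * frame_interval
                dA_t = dA_inf + spec.relax_c / t_ns
                h_t = h_of_dA(dA_t)
                fr, _ = sample_bilayer_frame(
                    surf, spec, seed=_child_seed(seed, ti, run, j),
                    h=h_t, time=t_ns, gamma=gamma, z4=z4)
                frames.append(fr)
                heights.setdefault((gamma, run), []).append(h_t)
            runs.append(frames)
        runs_by_tension[gamma] = runs
        rows.append({
            "gamma": gamma, "dz": dz, "dA_inf": dA_inf, "h_inf": h_inf,
            "eb_inf": float(np.interp(h_inf, cal["h_table"],
                                      cal["eb_table"])),
        })
    truth = TruthRecord(
        spring={
            "F0_star": spec.F0_star, "k_star": spec.k_star,
            "dA_ddz_star": spec.dA_ddz_star,
            "dEb_ddz_star": cal["s_E"],
            "c_gamma": cal["c_gamma"], "sigma": cal["sigma"],
        },
        per_tension=pd.DataFrame(rows),
        extras={"heights": heights},
        quadrature_step=_CAL_STEP,
    )
    return runs_by_tension, truth
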