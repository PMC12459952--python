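"""Excess area, Helfrich bending energy, and curvature profiles of an
averaged midplane shape in Monge parametrization.

The shape is a height field z(x, y) discretized on a square lattice with
lattice constant ``a`` over a disk of diameter ``d_m``.  The excess area is
the discretized area of the curved surface minus its planar projection,
with one-sided (forward) differences:

    dA(x,y) = a^2 ( sqrt(1 + (z(x+a,y)-z(x,y))^2/a^2
                       + (z(x,y+a)-z(x,y))^2/a^2) - 1 )

The bending energy density is 2*kappa*H^2 dA with the full Monge-gauge mean
curvature H from centered first and second differences, optionally weighted
by the relative lipid density rho(x,y) to restrict the energy to the lipid
membrane.  Energies are reported in units of the bending rigidity kappa.

Sites whose difference stencil leaves the disk use the continuous
evaluator's boundary value (one-ring inset), so boundary handling is
identical for data-driven and analytic shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from nanodome.averaging import AveragedShape

#: Boltzmann constant times 310 K, in pN nm.
KBT_310K_PN_NM = 4.2804


def kbt_pn_nm(T: float = 310.0) -> float:
    """Thermal energy k_B*T in pN nm at temperature T (K)."""
    return KBT_310K_PN_NM * T / 310.0


@dataclass
class ElasticScalars:
    """Excess area (nm^2) and bending energy (units of kappa) of a shape."""

    excess_area: float
    bending_energy: float
    r_max: float | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class RadialProfile:
    r: np.ndarray          # bin centers, nm
    z: np.ndarray          # angular-mean height, nm
    sem: np.ndarray | None = None


@dataclass
class CurvatureProfile:
    r: np.ndarray
    M: np.ndarray          # mean curvature, 1/nm
    dz_dr: np.ndarray
    d2z_dr2: np.ndarray


def _site_lattice(shape: AveragedShape, r_max: float | None,
                  r_min: float = 0.0):
    R = shape.d_m / 2.0
    if r_max is not None:
        if r_max > R + 1e-9:
            raise ValueError(f"r_max={r_max} exceeds disk radius {R}")
        R = min(r_max, R)
    X, Y = np.meshgrid(shape.coords, shape.coords, indexing="ij")
    r2 = X**2 + Y**2
    sel = (r2 <= R**2) & (r2 >= r_min**2)
    return X[sel], Y[sel]


def excess_area(shape: AveragedShape, r_max: float | None = None) -> float:
    """Excess area (nm^2) of the shape, summed over lattice sites within
    ``min(r_max, d_m/2)`` using forward differences."""
    a = shape.a
    X, Y = _site_lattice(shape, r_max)
    z0 = shape.evaluate(X, Y, clamp=True)
    zx = shape.evaluate(X + a, Y, clamp=True)
    zy = shape.evaluate(X, Y + a, clamp=True)
    if not (np.all(np.isfinite(z0)) and np.all(np.isfinite(zx))
            and np.all(np.isfinite(zy))):
        raise ValueError("non-finite heights in shape")
    dA = a**2 * (np.sqrt(1.0 + (zx - z0) ** 2 / a**2 + (zy - z0) ** 2 / a**2) - 1.0)
    return float(np.sum(dA))


def _stencil(shape: AveragedShape, X, Y):
    a = shape.a
    ev = shape.evaluate
    z0 = ev(X, Y)
    zpx, zmx = ev(X + a, Y), ev(X - a, Y)
    zpy, zmy = ev(X, Y + a), ev(X, Y - a)
    zpp, zmm = ev(X + a, Y + a), ev(X - a, Y - a)
    zpm, zmp = ev(X + a, Y - a), ev(X - a, Y + a)
    z_x = (zpx - zmx) / (2 * a)
    z_y = (zpy - zmy) / (2 * a)
    z_xx = (zpx + zmx - 2 * z0) / a**2
    z_yy = (zpy + zmy - 2 * z0) / a**2
    z_xy = (zpp + zmm - zpm - zmp) / (4 * a**2)
    return z_x, z_y, z_xx, z_yy, z_xy


def bending_energy(shape: AveragedShape, kappa: float = 25.0,
                   r_max: float | None = None,
                   r_min: float = 0.0,
                   use_density: bool = True) -> float:
    """Bending energy of the shape in units of kappa.

    The per-site energy is 2*kappa*H^2*dA with the Monge-gauge mean
    curvature from centered differences; sites are weighted by the
    relative lipid density rho(x, y) when available (and ``use_density``),
    restricting the energy to the lipid membrane around the protein.
    The ``kappa`` argument sets the rigidity used by callers converting to
    absolute units; the returned value is the dimensionless multiple of it.
    """
    if r_max is not None and r_max < 2 * shape.a:
        raise ValueError("r_max must span at least two lattice steps")
    a = shape.a
    X, Y = _site_lattice(shape, r_max, r_min)
    z_x, z_y, z_xx, z_yy, z_xy = _stencil(shape, X, Y)
    num = z_xx * (1 + z_y**2) + z_yy * (1 + z_x**2) - 2 * z_xy * z_x * z_y
    denom = 2.0 * (1 + z_x**2 + z_y**2) ** 2.5
    e_b = a**2 * num**2 / denom  # per site, in kappa units
    if not np.all(np.isfinite(e_b)):
        raise ValueError("non-finite bending energy density")
    if use_density and shape.rho is not None:
        Xg, Yg = np.meshgrid(shape.coords, shape.coords, indexing="ij")
        R = shape.d_m / 2.0 if r_max is None else min(r_max, shape.d_m / 2.0)
        r2 = Xg**2 + Yg**2
        sel = (r2 <= R**2) & (r2 >= r_min**2)
        rho = shape.rho[sel]
        e_b = e_b * np.where(np.isfinite(rho), rho, 1.0)
    return float(np.sum(e_b))


def elastic_scalars(shape: AveragedShape, kappa: float = 25.0,
                    r_max: float | None = None) -> ElasticScalars:
    """Convenience wrapper computing both scalars with shared provenance."""
    return ElasticScalars(
        excess_area=excess_area(shape, r_max),
        bending_energy=bending_energy(shape, kappa, r_max),
        r_max=r_max,
        provenance={"window": shape.window, "n_frames": shape.n_frames,
                    "a": shape.a, "kappa": kappa},
    )


def radial_mean_curvature_profile(
    shape: AveragedShape,
    radial_bin_width: float = 1.0,
    fit_half_window: float = 2.0,
    n_theta: int = 720,
    apex_positive: bool = True,
) -> tuple[RadialProfile, CurvatureProfile, float]:
    """Radial height profile, mean-curvature profile, and 2D bending energy.

    The height profile z(r) is the angular average of the shape on radial
    bins.  At each r a quadratic is least-squares fitted to the profile
    over [r - w, r + w] (default half-window 2 nm), giving smoothed z'(r)
    and z''(r); the axisymmetric mean curvature is

        M(r) = 0.5 * ( z'' / (1 + z'^2)^(3/2) + z' / (r * sqrt(1 + z'^2)) )

    with M(0) = z''(0).  The profile-based bending energy (in kappa units)
    integrates 2*M(r)^2 over the surface of revolution:

        E_b_2D = sum 2 * M(r)^2 * 2*pi*r * sqrt(1 + z'^2) * dr

    With ``apex_positive`` (default) the sign of M is flipped so that an
    upward dome carries positive mean curvature at its apex; set it False
    for the raw Monge-gauge sign.
    """
    R = shape.d_m / 2.0
    if radial_bin_width > shape.d_m / 4.0:
        raise ValueError("radial bin width too coarse for the disk")
    dr = radial_bin_width
    # cell-centered radial bins so the revolution sum covers [0, R] exactly
    r_vals = (np.arange(int(math.floor(R / dr))) + 0.5) * dr
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    z_prof = np.empty_like(r_vals)
    for i, r in enumerate(r_vals):
        if r == 0.0:
            z_prof[i] = float(shape.evaluate(0.0, 0.0))
        else:
            z_prof[i] = float(np.mean(shape.evaluate(r * np.cos(theta),
                                                     r * np.sin(theta))))

    w = fit_half_window
    M = np.empty_like(r_vals)
    dz = np.empty_like(r_vals)
    d2z = np.empty_like(r_vals)
    for i, r in enumerate(r_vals):
        sel = np.abs(r_vals - r) <= w + 1e-9
        if sel.sum() < 3:
            sel = np.argsort(np.abs(r_vals - r))[:3]
        rs = r_vals[sel] - r
        coef = np.polynomial.polynomial.polyfit(rs, z_prof[sel], 2)
        zp, zpp = coef[1], 2.0 * coef[2]
        dz[i], d2z[i] = zp, zpp
        if r == 0.0:
            M[i] = zpp
        else:
            M[i] = 0.5 * (zpp / (1 + zp**2) ** 1.5
                          + zp / (r * np.sqrt(1 + zp**2)))
    if apex_positive:
        M = -M

    eb_2d = float(np.sum(2.0 * M**2 * 2.0 * np.pi * r_vals
                         * np.sqrt(1 + dz**2) * dr))
    return (RadialProfile(r=r_vals, z=z_prof),
            CurvatureProfile(r=r_vals, M=M, dz_dr=dz, d2z_dr2=d2z),
            eb_2d)


def crossover_length(kappa: float, T: float = 310.0, gamma: float = 1.0) -> float:
    """Crossover length sqrt(kappa*k_B*T/gamma) in nm.

    Above this length membrane tension dominates the elastic energy; below
    it bending does.  ``kappa`` in units of k_B*T, ``gamma`` in mN/m
    (1 mN/m = 1 pN/nm).
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0 (length diverges at zero tension)")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return float(np.sqrt(kappa * kbt_pn_nm(T) / gamma))
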