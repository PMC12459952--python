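"""Tension-series elasticity modelling of the protein-membrane nanodome.

Per-tension observables — protein height change Dz, excess area DA, and
bending energy E_b — respond linearly to moderate tension.  The membrane
energy E_m = E_b + gamma*DA exerts a vertical force

    F = dE_m/dDz = dE_b/dDz + gamma * dDA/dDz

on the protein; in mechanical equilibrium the protein resists with the
opposite force.  F grows linearly with Dz, which identifies the protein as
a harmonic spring with force constant k_F = dF/dDz and a force-free height
change Dz_free = -F0/k_F.  Forces are reported as magnitudes (the membrane
pulls the protein toward the flat state; Dz is positive under tension).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from nanodome.geometry import kbt_pn_nm


def tension_from_pressures(Px: float, Py: float, Pz: float, Lz: float) -> float:
    """Membrane tension gamma = Lz*(Pz - (Px+Py)/2) in mN/m.

    Pressures in bar, box height Lz in nm; 1 bar*nm = 0.1 mN/m.
    """
    if Lz <= 0:
        raise ValueError("Lz must be > 0")
    return Lz * (Pz - (Px + Py) / 2.0) / 10.0


@dataclass
class TensionSeries:
    """Per-tension records of Dz, DA, and E_b with 1-sigma errors."""

    gamma: np.ndarray        # mN/m
    dz: np.ndarray           # nm
    dz_err: np.ndarray
    dA: np.ndarray           # nm^2
    dA_err: np.ndarray
    eb: np.ndarray           # units of kappa
    eb_err: np.ndarray

    def __post_init__(self) -> None:
        for name in ("gamma", "dz", "dz_err", "dA", "dA_err", "eb", "eb_err"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.gamma < 0):
            raise ValueError("tensions must be >= 0")
        if len(np.unique(self.gamma)) != len(self.gamma):
            raise ValueError("one record per tension required")
        for name in ("dz_err", "dA_err", "eb_err"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be >= 0")

    def to_csv(self, path) -> Path:
        df = pd.DataFrame({
            "gamma_mN_per_m": self.gamma, "dz_nm": self.dz,
            "dz_err_nm": self.dz_err, "dA_nm2": self.dA,
            "dA_err_nm2": self.dA_err, "eb_kappa": self.eb,
            "eb_err_kappa": self.eb_err,
        })
        path = Path(path)
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "TensionSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            gamma=df["gamma_mN_per_m"], dz=df["dz_nm"], dz_err=df["dz_err_nm"],
            dA=df["dA_nm2"], dA_err=df["dA_err_nm2"],
            eb=df["eb_kappa"], eb_err=df["eb_err_kappa"],
        )


@dataclass
class Slope:
    value: float
    se: float


@dataclass
class ResponseSlopes:
    """Linear response slopes of the tension series."""

    dz_dgamma: Slope         # nm per mN/m, fitted for gamma <= gamma_max
    dA_ddz: Slope            # nm, fitted for dz < dz_max
    deb_ddz: Slope           # kappa per nm, fitted for dz < dz_max


def _linfit(x: np.ndarray, y: np.ndarray,
            sigma: np.ndarray | None = None,
            weighted: bool = False) -> tuple[Slope, Slope]:
    """Straight-line fit returning (intercept, slope) with standard errors.

    The default estimator is unweighted ordinary least squares.  Standard
    errors are the larger of (a) the residual-based OLS errors and (b) the
    errors propagated from the known per-point sigmas through the OLS
    estimator.  With few points either estimate alone can collapse — the
    residual one when the points happen to be collinear, the propagated
    one when the per-point error estimates are unstable — so the maximum
    is the conservative choice.  ``weighted=True`` switches to a
    fixed-scale weighted fit (requires sigmas).
    """
    X = np.column_stack([np.ones_like(x), x])
    if weighted:
        if sigma is None or not np.all(sigma > 0):
            raise ValueError("weighted fit requires positive sigmas")
        W = 1.0 / sigma**2
        XtWX = X.T @ (X * W[:, None])
        beta = np.linalg.solve(XtWX, X.T @ (y * W))
        se = np.sqrt(np.diag(np.linalg.inv(XtWX)))
        return (Slope(float(beta[0]), float(se[0])),
                Slope(float(beta[1]), float(se[1])))
    res = sm.OLS(y, X).fit()
    beta = res.params
    var_resid = res.bse**2 if res.df_resid > 0 else np.zeros(2)
    var_prop = np.zeros(2)
    if sigma is not None and np.all(sigma >= 0) and np.any(sigma > 0):
        # Var(beta_hat) = (X'X)^-1 X' diag(sigma^2) X (X'X)^-1
        XtX_inv = np.linalg.inv(X.T @ X)
        A = XtX_inv @ X.T
        var_prop = np.diag(A @ np.diag(sigma**2) @ A.T)
    var = np.maximum(np.nan_to_num(var_resid), var_prop)
    se = np.sqrt(var)
    return Slope(float(beta[0]), float(se[0])), Slope(float(beta[1]), float(se[1]))


def fit_response_slopes(series: TensionSeries,
                        gamma_max: float = 6.0,
                        dz_max: float = 2.0,
                        use_errors: bool = True) -> ResponseSlopes:
    """Fit the three linear responses on their standard subsets.

    Dz(gamma) is fitted for gamma <= ``gamma_max`` (default 6 mN/m);
    DA(Dz) and E_b(Dz) for Dz < ``dz_max`` (default 2 nm).  When
    ``use_errors`` and the series carries errors, they are propagated
    into the slope standard errors (see :func:`_linfit`).
    """
    out = {}
    specs = [
        ("dz_dgamma", series.gamma <= gamma_max, series.gamma, series.dz,
         series.dz_err),
        ("dA_ddz", series.dz < dz_max, series.dz, series.dA, series.dA_err),
        ("deb_ddz", series.dz < dz_max, series.dz, series.eb, series.eb_err),
    ]
    for name, sel, x, y, err in specs:
        if sel.sum() < 3:
            raise ValueError(
                f"fit subset for {name} has {int(sel.sum())} points; need >= 3"
            )
        sigma = err[sel] if (use_errors and np.all(err[sel] >= 0)) else None
        _, slope = _linfit(x[sel], y[sel], sigma)
        out[name] = slope
    return ResponseSlopes(**out)


def vertical_force(deb_ddz: float, dA_ddz: float, kappa: float = 25.0,
                   T: float = 310.0, gamma: float = 0.0) -> float:
    """Magnitude of the vertical membrane force, in pN.

    |F| = |dE_b/dDz| * kappa * k_B*T / nm + gamma * |dDA/dDz|, with the
    bending slope in kappa/nm, kappa in k_B*T units, and gamma in mN/m
    (= pN/nm).  Both energy terms pull toward flattening, so magnitudes
    add.
    """
    if not (math.isfinite(deb_ddz) and math.isfinite(dA_ddz)):
        raise ValueError("slopes must be finite")
    return abs(deb_ddz) * kappa * kbt_pn_nm(T) + gamma * abs(dA_ddz)


@dataclass
class ForceRelation:
    """OLS fit of F against Dz."""

    F0: float                # pN, force at Dz = 0
    k_F: float               # pN/nm, force constant dF/dDz
    dz_free: float           # nm, -F0/k_F (nan if k_F == 0)
    F0_se: float
    k_F_se: float
    dz_free_se: float
    band_halfwidth_at_0: float   # 50%-level prediction band at Dz = 0
    degenerate: bool = False     # k_F == 0: force-free state undefined


def fit_force_relation(points, F0_se: float | None = None,
                       k_F_se: float | None = None) -> ForceRelation:
    """Fit the linear force relation F(Dz) and locate the force-free state.

    ``points`` is a sequence of (Dz, F) pairs.  F0 is the intercept, k_F
    the slope, Dz_free = -F0/k_F.  The 50%-level prediction band of the
    OLS fit is evaluated at Dz = 0.

    Because F values are usually *constructed* from globally fitted slopes
    (so the points are nearly collinear and residual-based errors
    degenerate), callers may pass externally propagated standard errors
    ``F0_se`` / ``k_F_se``, which then replace the residual-based ones and
    propagate into the Dz_free error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 (dz, F) points")
    dz, F = pts[:, 0], pts[:, 1]
    X = sm.add_constant(dz)
    res = sm.OLS(F, X).fit()
    F0, kF = float(res.params[0]), float(res.params[1])
    if res.df_resid > 0 and np.isfinite(res.scale):
        ols_F0_se, ols_kF_se = float(res.bse[0]), float(res.bse[1])
        pred = res.get_prediction(np.array([[1.0, 0.0]]))
        frame = pred.summary_frame(alpha=0.5)
        band = float(frame["obs_ci_upper"].iloc[0] - frame["mean"].iloc[0])
    else:
        ols_F0_se = ols_kF_se = band = 0.0
    se_F0 = F0_se if F0_se is not None else ols_F0_se
    se_kF = k_F_se if k_F_se is not None else ols_kF_se
    if kF == 0.0:
        return ForceRelation(F0=F0, k_F=kF, dz_free=float("nan"),
                             F0_se=se_F0, k_F_se=se_kF,
                             dz_free_se=float("nan"),
                             band_halfwidth_at_0=band, degenerate=True)
    dz_free = -F0 / kF
    rel = 0.0
    if F0 != 0.0:
        rel = math.sqrt((se_F0 / F0) ** 2 + (se_kF / kF) ** 2)
    return ForceRelation(F0=F0, k_F=kF, dz_free=dz_free,
                         F0_se=se_F0, k_F_se=se_kF,
                         dz_free_se=abs(dz_free) * rel,
                         band_halfwidth_at_0=band)


@dataclass
class ForceModel:
    """Fitted elasticity model of the protein-membrane nanodome.

    The protein enters as a harmonic spring (F0, k_F); the membrane energy
    E_m = E_b + gamma*DA enters through the fitted response slopes.  All
    forces are magnitudes in pN.
    """

    slopes: ResponseSlopes
    kappa: float
    T: float
    gamma: np.ndarray            # tensions used for the force points, mN/m
    dz_points: np.ndarray        # nm
    F_points: np.ndarray         # pN
    relation: ForceRelation

    def to_dict(self) -> dict:
        return {
            "kappa_kBT": self.kappa,
            "T_K": self.T,
            "dz_dgamma_nm_per_mN_m": [self.slopes.dz_dgamma.value,
                                      self.slopes.dz_dgamma.se],
            "dA_ddz_nm": [self.slopes.dA_ddz.value, self.slopes.dA_ddz.se],
            "dEb_ddz_kappa_per_nm": [self.slopes.deb_ddz.value,
                                     self.slopes.deb_ddz.se],
            "gamma_mN_per_m": self.gamma.tolist(),
            "dz_nm": self.dz_points.tolist(),
            "F_pN": self.F_points.tolist(),
            "F0_pN": [self.relation.F0, self.relation.F0_se],
            "k_F_pN_per_nm": [self.relation.k_F, self.relation.k_F_se],
            "dz_free_nm": [self.relation.dz_free, self.relation.dz_free_se],
            "prediction_band_halfwidth_at_dz0_pN":
                self.relation.band_halfwidth_at_0,
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


def build_force_model(series: TensionSeries, kappa: float = 25.0,
                      T: float = 310.0, gamma_max: float = 6.0,
                      dz_max: float = 2.0,
                      force_tensions: np.ndarray | None = None) -> ForceModel:
    """End-to-end model fit: slopes, per-tension forces, force relation.

    Forces are evaluated at the lowest tensions (default: all tensions
    <= ``gamma_max``) using the constant global slopes at the per-tension
    Dz values.  Standard errors of F0 and k_F are propagated from the
    slope errors: F0 = |dE_b/dDz| * kappa * k_B*T, and k_F is, in the
    collinear limit, |dDA/dDz| / (dDz/dgamma), so its relative error adds
    those of the two slopes in quadrature.
    """
    slopes = fit_response_slopes(series, gamma_max=gamma_max, dz_max=dz_max)
    if force_tensions is None:
        sel = series.gamma <= gamma_max
    else:
        sel = np.isin(series.gamma, np.asarray(force_tensions, dtype=float))
    gam = series.gamma[sel]
    dz = series.dz[sel]
    F = np.array([
        vertical_force(slopes.deb_ddz.value, slopes.dA_ddz.value,
                       kappa=kappa, T=T, gamma=g) for g in gam
    ])
    F0_se = slopes.deb_ddz.se * kappa * kbt_pn_nm(T)
    c = slopes.dz_dgamma
    sA = slopes.dA_ddz
    kF_prop = abs(sA.value) / c.value if c.value != 0 else float("nan")
    kF_se = abs(kF_prop) * math.sqrt(
        (sA.se / sA.value) ** 2 + (c.se / c.value) ** 2
    ) if c.value != 0 and sA.value != 0 else float("nan")
    relation = fit_force_relation(np.column_stack([dz, F]),
                                  F0_se=F0_se, k_F_se=kF_se)
    return ForceModel(slopes=slopes, kappa=kappa, T=T, gamma=gam,
                      dz_points=dz, F_points=F, relation=relation)
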