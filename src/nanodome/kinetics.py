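"""Time-windowed observables and inverse-time extrapolation.

Finite trajectories undersample slow membrane relaxation, so per-window
observables (excess area, bending energy) are extrapolated to infinite
time by an ordinary least-squares fit against inverse time 1/t over the
last windows; the intercept at 1/t = 0 is the extrapolated value and its
uncertainty is the half-width of the 50%-level prediction band for a new
observation there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from nanodome.averaging import average_shapes
from nanodome.geometry import bending_energy, excess_area

OBSERVABLES = ("excess_area", "bending_energy")


@dataclass
class WindowSeries:
    """Per-window observable values with across-run errors of the mean."""

    centers: np.ndarray          # window midpoints, ns
    values: np.ndarray
    errors: np.ndarray           # SEM across runs (0 when a single run)
    observable: str
    per_run: np.ndarray | None = None   # (n_windows, n_runs)

    @property
    def n_windows(self) -> int:
        return len(self.centers)


@dataclass
class ExtrapolationResult:
    """OLS extrapolation of an observable to 1/t = 0."""

    intercept: float
    slope: float
    band_halfwidth: float        # 50%-level prediction band at 1/t = 0
    n_fit: int
    intercept_se: float = float("nan")

    @property
    def sigma(self) -> float:
        """Approximate 1-sigma error of the extrapolated value.

        The 50% prediction band half-width corresponds to ~0.674 sigma for
        a normal predictive distribution; this rescaling is used when the
        extrapolated values enter weighted downstream fits.
        """
        return self.band_halfwidth / 0.6744897501960817


def window_series(runs: Sequence[Sequence], n_windows: int = 5,
                  observable: str = "excess_area", *,
                  topology=None, n_bins: int = 25, a: float = 1.0,
                  kappa: float = 25.0, symmetrize: bool = True,
                  reference=None, truncate: bool = False) -> WindowSeries:
    """Compute a per-window observable from grouped runs of bead frames.

    Each run is a sequence of BeadFrames sharing length and cadence (pass
    ``truncate=True`` to cut all runs to the shortest).  The trajectory is
    split into ``n_windows`` equal time intervals; in each window one
    averaged shape is pooled over all runs' frames and the observable is
    evaluated on it.  Errors of the mean come from per-run values.
    """
    from nanodome.pipeline import aligned_shapes_for_frames  # local to avoid cycle

    if observable not in OBSERVABLES:
        raise ValueError(f"observable must be one of {OBSERVABLES}")
    lengths = {len(r) for r in runs}
    if len(lengths) > 1:
        if not truncate:
            raise ValueError(
                f"runs of unequal length {sorted(lengths)}; pass truncate=True"
            )
        n = min(lengths)
        runs = [list(r)[:n] for r in runs]

    aligned_per_run = []
    ref = reference
    for run in runs:
        shapes, ref = aligned_shapes_for_frames(
            run, topology=topology, n_bins=n_bins, reference=ref)
        aligned_per_run.append(shapes)

    times = np.array([s.time for s in aligned_per_run[0]])
    duration = float(times.max())
    width = duration / n_windows
    centers = (np.arange(n_windows) + 0.5) * width

    def measure(shapes):
        avg = average_shapes(shapes, a=a, symmetrize=symmetrize)
        if observable == "excess_area":
            return excess_area(avg)
        return bending_energy(avg, kappa=kappa)

    values = np.empty(n_windows)
    per_run = np.full((n_windows, len(runs)), np.nan)
    for w in range(n_windows):
        lo, hi = w * width, (w + 1) * width
        pooled = []
        for ri, shapes in enumerate(aligned_per_run):
            in_w = [s for s in shapes if lo < s.time <= hi + 1e-9]
            if not in_w:
                raise ValueError(f"window {w} has no frames in run {ri}")
            pooled.extend(in_w)
            per_run[w, ri] = measure(in_w)
        values[w] = measure(pooled)
    if len(runs) > 1:
        errors = per_run.std(axis=1, ddof=1) / np.sqrt(len(runs))
    else:
        errors = np.zeros(n_windows)
    return WindowSeries(centers=centers, values=values, errors=errors,
                        observable=observable, per_run=per_run)


def inverse_time_extrapolate(series: WindowSeries,
                             n_fit: int = 3,
                             weighted: bool = False) -> ExtrapolationResult:
    """OLS of the last ``n_fit`` window values against 1/t; intercept at
    1/t = 0 is the extrapolated long-time value.

    ``weighted=True`` weights points by 1/error^2 (requires positive
    errors); the default is the unweighted fit.
    """
    if n_fit < 2:
        raise ValueError("n_fit must be >= 2")
    if n_fit > series.n_windows:
        raise ValueError("n_fit exceeds number of windows")
    t = np.asarray(series.centers, dtype=float)[-n_fit:]
    y = np.asarray(series.values, dtype=float)[-n_fit:]
    if np.any(t <= 0):
        raise ValueError("window centers must be positive")
    x = 1.0 / t
    X = sm.add_constant(x)
    if weighted:
        err = np.asarray(series.errors, dtype=float)[-n_fit:]
        if np.any(err <= 0):
            raise ValueError("weighted fit requires positive errors")
        res = sm.WLS(y, X, weights=1.0 / err**2).fit()
    else:
        res = sm.OLS(y, X).fit()
    intercept = float(res.params[0])
    slope = float(res.params[1])
    if res.df_resid > 0 and np.isfinite(res.scale):
        pred = res.get_prediction(np.array([[1.0, 0.0]]))
        frame = pred.summary_frame(alpha=0.5)
        half = float(frame["obs_ci_upper"].iloc[0] - frame["mean"].iloc[0])
        se = float(res.bse[0])
    else:  # saturated two-point fit: no residual dof
        half, se = 0.0, 0.0
    return ExtrapolationResult(intercept=intercept, slope=slope,
                               band_halfwidth=half, n_fit=n_fit,
                               intercept_se=se)
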