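"""End-to-end orchestration: frames -> aligned shapes -> tension series ->
force model.

These helpers wire the per-module operations together in the order the
analysis requires: recenter on the channel, assign leaflets, bin the
midplane, rotationally align to a common reference, average per time
window with threefold symmetrization, extrapolate the windowed observables
to long timescales, and fit the elasticity model to the per-tension
records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from nanodome.averaging import AlignedShape, rotational_align
from nanodome.elasticity import ForceModel, TensionSeries, build_force_model
from nanodome.frame_io import BeadFrame, ProteinTopology, Role
from nanodome.kinetics import inverse_time_extrapolate
from nanodome.protein import z4_summary
from nanodome.surface import assign_leaflets, midplane_grid, recenter_and_wrap


def channel_helix_xy(frame: BeadFrame, topology: ProteinTopology) -> np.ndarray:
    """In-plane COMs of the three channel helices, channel-centered (3, 2)."""
    out = []
    for arm, residues in sorted(topology.channel_residues_by_arm().items()):
        mask = (np.isin(frame.molecule_id, residues)
                & (frame.particle == topology.backbone_particle)
                & (frame.role == Role.protein))
        if not mask.any():
            raise ValueError(f"no channel backbone beads for arm {arm}")
        out.append(frame.positions[mask, :2].mean(axis=0))
    coms = np.asarray(out)
    return coms - frame.box[:2] / 2.0


def aligned_shapes_for_frames(frames, topology: ProteinTopology,
                              n_bins: int = 25, reference=None):
    """Recenter, reconstruct, and rotationally align each frame's midplane.

    Returns the aligned shapes and the alignment reference used (the helix
    COMs of the first frame, when none is given), so later calls can share
    it.
    """
    shapes = []
    for fr in frames:
        rec = recenter_and_wrap(fr, topology)
        labels = assign_leaflets(rec)
        grid = midplane_grid(rec, labels, n_bins=n_bins)
        hxy = channel_helix_xy(rec, topology)
        if reference is None:
            reference = hxy
        _, shape = rotational_align(grid, hxy, reference)
        shapes.append(shape)
    return shapes, reference


@dataclass
class TensionAnalysis:
    """Per-tension extrapolated observables and their diagnostics."""

    series: TensionSeries
    model: ForceModel
    details: dict


def analyze_tension_series(runs_by_tension: dict, topology: ProteinTopology,
                           n_bins: int = 25, a: float = 1.0,
                           kappa: float = 25.0, T: float = 310.0,
                           n_windows: int = 5, n_fit: int = 3,
                           symmetrize: bool = True,
                           gamma_max: float = 6.0, dz_max: float = 2.0,
                           ) -> TensionAnalysis:
    """Run the full analysis over a {tension: [runs]} mapping of frames.

    For each tension, windowed excess area and bending energy are
    extrapolated to infinite time; the protein height change Dz comes from
    per-run unit-4 displacements (Dz(gamma) = z4(0) - z4(gamma)).  The
    resulting tension series is then fitted to the harmonic-spring force
    model.
    """
    from nanodome.averaging import average_shapes
    from nanodome.geometry import bending_energy, excess_area
    from nanodome.kinetics import WindowSeries

    gammas = sorted(runs_by_tension)
    if 0.0 not in [float(g) for g in gammas]:
        raise ValueError("a tensionless (gamma=0) condition is required for Dz")
    reference = None
    rows = {"gamma": [], "dA": [], "dA_err": [], "eb": [], "eb_err": [],
            "z4": [], "z4_err": []}
    details: dict = {}
    for gamma in gammas:
        runs = runs_by_tension[gamma]
        det: dict = {}
        aligned_per_run = []
        for run in runs:
            shapes, reference = aligned_shapes_for_frames(
                run, topology=topology, n_bins=n_bins, reference=reference)
            aligned_per_run.append(shapes)
        times = np.array([s.time for s in aligned_per_run[0]])
        width = float(times.max()) / n_windows
        centers = (np.arange(n_windows) + 0.5) * width

        vals = {"excess_area": np.empty(n_windows),
                "bending_energy": np.empty(n_windows)}
        per_run = {k: np.empty((n_windows, len(runs))) for k in vals}

        def both(shapes):
            avg = average_shapes(shapes, a=a, symmetrize=symmetrize)
            return excess_area(avg), bending_energy(avg, kappa=kappa)

        for w in range(n_windows):
            lo, hi = w * width, (w + 1) * width
            pooled = []
            for ri, shapes in enumerate(aligned_per_run):
                in_w = [s for s in shapes if lo < s.time <= hi + 1e-9]
                if not in_w:
                    raise ValueError(f"window {w} empty in run {ri}")
                pooled.extend(in_w)
                da_r, eb_r = both(in_w)
                per_run["excess_area"][w, ri] = da_r
                per_run["bending_energy"][w, ri] = eb_r
            da_p, eb_p = both(pooled)
            vals["excess_area"][w] = da_p
            vals["bending_energy"][w] = eb_p

        for obs, key in (("excess_area", "dA"), ("bending_energy", "eb")):
            if len(runs) > 1:
                errs = per_run[obs].std(axis=1, ddof=1) / math.sqrt(len(runs))
            else:
                errs = np.zeros(n_windows)
            ws = WindowSeries(centers=centers, values=vals[obs], errors=errs,
                              observable=obs, per_run=per_run[obs])
            ex = inverse_time_extrapolate(ws, n_fit=n_fit)
            rows[key].append(ex.intercept)
            rows[key + "_err"].append(ex.sigma if ex.sigma > 0 else ex.intercept_se)
            det[obs] = (ws, ex)
        # z4 per run -> mean and SEM across runs
        z4s = [z4_summary(run, topology)[0] for run in runs]
        z4 = float(np.mean(z4s))
        z4_err = (float(np.std(z4s, ddof=1) / math.sqrt(len(z4s)))
                  if len(z4s) > 1 else z4_summary(runs[0], topology)[1])
        rows["gamma"].append(float(gamma))
        rows["z4"].append(z4)
        rows["z4_err"].append(z4_err)
        details[float(gamma)] = det

    z4_0, z4_0_err = rows["z4"][0], rows["z4_err"][0]
    dz = [z4_0 - v for v in rows["z4"]]
    dz_err = [math.sqrt(z4_0_err**2 + e**2) for e in rows["z4_err"]]
    series = TensionSeries(
        gamma=rows["gamma"], dz=dz, dz_err=dz_err,
        dA=rows["dA"], dA_err=rows["dA_err"],
        eb=rows["eb"], eb_err=rows["eb_err"],
    )
    model = build_force_model(series, kappa=kappa, T=T,
                              gamma_max=gamma_max, dz_max=dz_max)
    return TensionAnalysis(series=series, model=model, details=details)
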