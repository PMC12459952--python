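"""Protein-side observables: TM trimming, 4-TM-unit displacements, channel
constriction distance and helix tilt.

Transmembrane helix ends that protrude out of the membrane are trimmed by
lipid-contact probability before computing unit centers of mass.  Unit
displacements are measured downward from the channel center: z_i =
z_channel - z_COM(unit i), so a more curved dome has larger z_i.  The
channel response to tension is summarized by the mean pairwise distance of
the three constriction-residue backbone beads and the tilt of the
channel-lining helices relative to the vertical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from nanodome.frame_io import BeadFrame, ProteinTopology, Role

logger = logging.getLogger(__name__)


def trim_protruding_residues(frames: Sequence[BeadFrame],
                             topology: ProteinTopology,
                             cutoff: float = 0.6,
                             threshold: float = 0.10,
                             window_fraction: float = 0.5) -> set[int]:
    """Retained TM residue set after trimming membrane-protruding helix ends.

    A residue is in lipid contact in a frame if any of its beads is within
    ``cutoff`` (nm) of any lipid tail bead.  Contact probabilities are
    computed over the last ``window_fraction`` of the frames.  Consecutive
    stretches at helix ends with probability < ``threshold`` are removed;
    interior low-contact residues are retained.
    """
    frames = list(frames)
    n_use = max(1, int(round(window_fraction * len(frames))))
    use = frames[-n_use:]
    helix_res = topology.helix_residues()
    all_res = sorted({r for rs in helix_res.values() for r in rs})
    contact = {r: 0 for r in all_res}
    for fr in use:
        tails = fr.positions[fr.role == Role.lipid_tail]
        if len(tails) == 0:
            raise ValueError("frame has no lipid tail beads")
        tree = cKDTree(tails)
        prot = fr.role == Role.protein
        mol = fr.molecule_id[prot]
        pos = fr.positions[prot]
        d, _ = tree.query(pos, k=1)
        in_contact = d < cutoff
        for r in all_res:
            sel = mol == r
            if sel.any() and in_contact[sel].any():
                contact[r] += 1
    prob = {r: contact[r] / n_use for r in all_res}

    retained: set[int] = set()
    for (arm, helix), residues in helix_res.items():
        keep = list(residues)
        while keep and prob[keep[0]] < threshold:
            keep.pop(0)
        while keep and prob[keep[-1]] < threshold:
            keep.pop()
        if not keep:
            logger.warning("helix %s of arm %s fully trimmed; excluded",
                           helix, arm)
            continue
        retained.update(keep)
    return retained


def _com(frame: BeadFrame, residues, backbone: str | None = None) -> np.ndarray:
    mask = np.isin(frame.molecule_id, list(residues)) & (frame.role == Role.protein)
    if backbone is not None:
        mask &= frame.particle == backbone
    if not mask.any():
        raise ValueError(f"no particles for residues {sorted(residues)[:6]}...")
    return frame.positions[mask].mean(axis=0)


def unit_displacements(frames: Sequence[BeadFrame],
                       topology: ProteinTopology,
                       retained: set[int] | None = None) -> pd.DataFrame:
    """Per-unit vertical displacement z_i and radial distance r_i.

    For each (arm, unit) the COM over retained TM residues is computed per
    frame; z_i = z_channel - z_COM and r_i is the in-plane distance from
    the channel axis.  Returns a frame-and-arm-averaged table with columns
    ``unit, r, z, r_sem, z_sem`` (SEM over frames of the arm-mean), plus
    the per-arm table in the attribute ``per_arm``.
    """
    rows = []
    for fi, fr in enumerate(frames):
        ch = _com(fr, topology.channel_residues(), topology.backbone_particle)
        for arm in (1, 2, 3):
            for unit in range(1, 10):
                res = topology.unit_residues(arm, unit)
                if not res:
                    raise ValueError(f"topology missing unit {unit} of arm {arm}")
                if retained is not None:
                    res = [r for r in res if r in retained]
                    if not res:
                        continue
                com = _com(fr, res)
                rows.append({
                    "frame": fi, "arm": arm, "unit": unit,
                    "r": float(np.hypot(com[0] - ch[0], com[1] - ch[1])),
                    "z": float(ch[2] - com[2]),
                })
    per = pd.DataFrame(rows)
    # average over arms within each frame, then mean/SEM over frames
    by_frame = per.groupby(["frame", "unit"])[["r", "z"]].mean().reset_index()
    agg = by_frame.groupby("unit").agg(
        r=("r", "mean"), z=("z", "mean"),
        r_sem=("r", "sem"), z_sem=("z", "sem"),
    ).reset_index()
    agg.attrs["per_arm"] = per
    return agg


def z4_summary(frames: Sequence[BeadFrame], topology: ProteinTopology,
               retained: set[int] | None = None) -> tuple[float, float]:
    """(mean, SEM) of the unit-4 vertical displacement z_4 over frames."""
    table = unit_displacements(frames, topology, retained)
    row = table[table["unit"] == 4]
    z = float(row["z"].iloc[0])
    sem = float(row["z_sem"].iloc[0]) if np.isfinite(row["z_sem"].iloc[0]) else 0.0
    return z, sem


def _helix_axis(points: np.ndarray) -> np.ndarray:
    """Leading principal direction of backbone positions, oriented to +z."""
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    return axis


def channel_metrics(frames: Sequence[BeadFrame],
                    topology: ProteinTopology) -> dict:
    """Constriction distance (nm) and channel-helix tilt (degrees).

    The constriction distance is the mean of the three pairwise distances
    between the constriction-residue backbone beads, averaged over frames.
    The tilt is the angle between each channel helix axis (leading
    principal direction of its backbone beads, oriented toward +z) and the
    z axis, averaged over helices and frames.
    """
    by_arm = topology.channel_residues_by_arm()
    if len(by_arm) < 3 or any(not v for v in by_arm.values()):
        raise ValueError("need channel helices for all three arms")
    dists, tilts = [], []
    for fr in frames:
        beads = []
        for resid in topology.constriction_residues:
            mask = ((fr.molecule_id == resid)
                    & (fr.particle == topology.backbone_particle))
            if not mask.any():
                raise ValueError(f"constriction residue {resid} not in frame")
            beads.append(fr.positions[mask].mean(axis=0))
        beads = np.asarray(beads)
        pair = [np.linalg.norm(beads[i] - beads[j])
                for i in range(3) for j in range(i + 1, 3)]
        dists.append(float(np.mean(pair)))
        for arm, residues in by_arm.items():
            mask = (np.isin(fr.molecule_id, residues)
                    & (fr.particle == topology.backbone_particle))
            pts = fr.positions[mask]
            if len(pts) < 2:
                raise ValueError(f"channel helix of arm {arm} has < 2 beads")
            axis = _helix_axis(pts)
            tilts.append(float(np.degrees(np.arccos(np.clip(axis[2], -1, 1)))))
    dists = np.asarray(dists)
    tilts = np.asarray(tilts)
    return {
        "constriction_distance_nm": float(dists.mean()),
        "constriction_distance_sem_nm":
            float(dists.std(ddof=1) / np.sqrt(len(dists))) if len(dists) > 1 else 0.0,
        "helix_tilt_deg": float(tilts.mean()),
        "helix_tilt_sem_deg":
            float(tilts.std(ddof=1) / np.sqrt(len(tilts))) if len(tilts) > 1 else 0.0,
    }
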