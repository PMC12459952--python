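"""Coordinate-frame I/O: GRO / PDB subsets and the native bead-table format.

A *bead frame* is one coordinate snapshot of a membrane-protein system:
particle positions in nm, a periodic box, a time stamp, per-particle role
labels (lipid head, lipid tail, protein, other), and optionally the lateral
and normal pressures used to compute membrane tension.

The GRO and PDB readers are deliberately minimal fixed-column parsers for
the records this pipeline needs (coordinates, box, residue/particle names);
the native interchange format is a plain CSV bead table with a JSON sidecar
carrying box dimensions and pressures.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BEAD_TABLE_COLUMNS = [
    "frame", "time_ns", "particle_id", "molecule_id", "residue",
    "particle", "role", "x_nm", "y_nm", "z_nm",
]


class Role(enum.IntEnum):
    """Structural role of a particle."""

    lipid_head = 0
    lipid_tail = 1
    protein = 2
    other = 3


#: Lipid residue names recognised by the default role rules (Martini names).
DEFAULT_LIPID_RESIDUES = frozenset({
    "POPC", "POPE", "POPS", "POP2", "PIP2", "DPSM", "CHOL",
    "DPPC", "DOPC", "DOPE", "DLPC",
})

#: Head-group bead/atom names counted as lipid heads.  Martini phosphate /
#: choline / amine / ceramide beads plus the atomistic phosphorus atom.
DEFAULT_HEAD_NAMES = frozenset({"PO4", "NC3", "NH3", "CNO", "ROH", "P", "P8"})

#: Residue names treated as solvent/ions (role ``other``).
DEFAULT_SOLVENT_RESIDUES = frozenset({
    "W", "WN", "WF", "ION", "NA+", "CL-", "NA", "CL", "K", "K+",
    "SOL", "TIP3", "HOH", "POT", "CLA", "SOD",
})

_AMINO3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL HSD HSE HSP".split()
)


def default_role_rules() -> dict:
    """Shipped role rules for Martini bead names and atomistic phosphorus.

    The mapping is deliberately overridable: trajectory conventions for
    which beads count as "lipid heads" vary, so callers may pass their own
    rules to :func:`read_frames` / :func:`assign_roles`.
    """
    return {
        "lipid_residues": set(DEFAULT_LIPID_RESIDUES),
        "head_names": set(DEFAULT_HEAD_NAMES),
        "tail_prefixes": ("C", "D"),
        "solvent_residues": set(DEFAULT_SOLVENT_RESIDUES),
        "protein_residues": set(_AMINO3),
    }


@dataclass
class BeadFrame:
    """One coordinate frame of a membrane-protein system.

    Positions are in nm, the box is ``(Lx, Ly, Lz)`` in nm, ``time`` in ns.
    ``pressures`` optionally carries ``(Px, Py, Pz)`` in bar for membrane
    tension computation.
    """

    particle_id: np.ndarray      # (N,) int
    molecule_id: np.ndarray      # (N,) int — residue id; one id per lipid
    residue: np.ndarray          # (N,) str
    particle: np.ndarray         # (N,) str
    role: np.ndarray             # (N,) int8, values of Role
    positions: np.ndarray        # (N, 3) float, nm
    box: np.ndarray              # (3,) float, nm
    time: float = 0.0            # ns
    pressures: tuple[float, float, float] | None = None  # (Px, Py, Pz) bar

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions in frame")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box dimensions must be three positive lengths")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def select(self, mask: np.ndarray) -> "BeadFrame":
        """Sub-frame with the particles selected by a boolean mask."""
        return replace(
            self,
            particle_id=self.particle_id[mask],
            molecule_id=self.molecule_id[mask],
            residue=self.residue[mask],
            particle=self.particle[mask],
            role=self.role[mask],
            positions=self.positions[mask],
        )

    def validate_lipids(self) -> None:
        """Check that every lipid molecule has >=1 head and >=1 tail bead."""
        is_head = self.role == Role.lipid_head
        is_tail = self.role == Role.lipid_tail
        heads = set(self.molecule_id[is_head].tolist())
        tails = set(self.molecule_id[is_tail].tolist())
        missing = sorted(heads ^ tails)
        if missing:
            raise ValueError(
                f"lipid molecules without both head and tail beads: {missing[:10]}"
            )


@dataclass
class ProteinTopology:
    """Residue-level topology of a trimeric mechanosensitive channel.

    Maps each protein residue id to its arm (1-3), 4-TM unit (1-9, or None
    for the channel-lining helix 38), and helix index (1-38).  The three
    helices 38 line the ion channel; one constriction residue per arm forms
    the outermost constriction site.
    """

    residues: Mapping[int, tuple[int, int | None, int]]
    constriction_residues: tuple[int, int, int]
    backbone_particle: str = "BB"

    def __post_init__(self) -> None:
        arms = {arm for arm, _, _ in self.residues.values()}
        if arms - {1, 2, 3} or len(arms) != 3:
            raise ValueError(f"topology must have exactly three arms, got {sorted(arms)}")
        for resid, (arm, unit, helix) in self.residues.items():
            if unit is not None and not 1 <= unit <= 9:
                raise ValueError(f"residue {resid}: unit index {unit} outside 1-9")
            if not 1 <= helix <= 38:
                raise ValueError(f"residue {resid}: helix index {helix} outside 1-38")
        ch_arms = {arm for arm, _, helix in self.residues.values() if helix == 38}
        if ch_arms != {1, 2, 3}:
            raise ValueError("topology must contain exactly three channel helices (38)")

    def channel_residues(self) -> list[int]:
        """Residue ids of the three channel-lining helices 38."""
        return sorted(r for r, (_, _, h) in self.residues.items() if h == 38)

    def channel_residues_by_arm(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {1: [], 2: [], 3: []}
        for r, (arm, _, h) in self.residues.items():
            if h == 38:
                out[arm].append(r)
        return {a: sorted(v) for a, v in out.items()}

    def unit_residues(self, arm: int, unit: int) -> list[int]:
        return sorted(
            r for r, (a, u, _) in self.residues.items() if a == arm and u == unit
        )

    def helix_residues(self) -> dict[tuple[int, int], list[int]]:
        """Residues per (arm, helix), each sorted by residue id."""
        out: dict[tuple[int, int], list[int]] = {}
        for r, (arm, _, helix) in self.residues.items():
            out.setdefault((arm, helix), []).append(r)
        return {k: sorted(v) for k, v in out.items()}


def assign_roles(residue: np.ndarray, particle: np.ndarray,
                 role_rules: Mapping | None = None) -> np.ndarray:
    """Vectorised role assignment from residue and particle names."""
    rules = default_role_rules()
    if role_rules:
        rules.update(role_rules)
    residue = np.asarray(residue)
    particle = np.asarray(particle)
    role = np.full(len(residue), int(Role.other), dtype=np.int8)

    is_lipid = np.isin(residue, list(rules["lipid_residues"]))
    is_head = is_lipid & np.isin(particle, list(rules["head_names"]))
    starts = np.char.startswith(particle.astype(str), rules["tail_prefixes"][0])
    for p in rules["tail_prefixes"][1:]:
        starts |= np.char.startswith(particle.astype(str), p)
    is_tail = is_lipid & ~is_head & starts
    is_protein = np.isin(residue, list(rules["protein_residues"]))
    role[is_protein] = int(Role.protein)
    role[is_head] = int(Role.lipid_head)
    role[is_tail] = int(Role.lipid_tail)
    return role


class ParseError(ValueError):
    """Malformed record in a coordinate file, with line number."""


def _parse_gro(path: Path, role_rules) -> list[BeadFrame]:
    frames = []
    lines = path.read_text().splitlines()
    i = 0
    nline = 0
    while i < len(lines):
        title = lines[i]
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])  # ps in GRO
                time /= 1000.0  # ns
            except (ValueError, IndexError):
                pass
        try:
            natoms = int(lines[i + 1].strip())
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{i + 2}: expected atom count") from exc
        body = lines[i + 2: i + 2 + natoms]
        if len(body) < natoms:
            raise ParseError(f"{path}: truncated frame starting at line {i + 1}")
        resid = np.empty(natoms, dtype=int)
        resname = np.empty(natoms, dtype=object)
        atomname = np.empty(natoms, dtype=object)
        pos = np.empty((natoms, 3))
        for j, line in enumerate(body):
            nline = i + 3 + j
            try:
                resid[j] = int(line[0:5])
                resname[j] = line[5:10].strip()
                atomname[j] = line[10:15].strip()
                pos[j, 0] = float(line[20:28])
                pos[j, 1] = float(line[28:36])
                pos[j, 2] = float(line[36:44])
            except ValueError as exc:
                raise ParseError(f"{path}:{nline}: malformed GRO line") from exc
        box_line = lines[i + 2 + natoms].split()
        if len(box_line) < 3:
            raise ParseError(f"{path}:{i + 3 + natoms}: missing box record")
        box = np.array([float(v) for v in box_line[:3]])
        role = assign_roles(resname, atomname, role_rules)
        pos = np.mod(pos, box)  # wrapped into [0, L) per axis
        frames.append(BeadFrame(
            particle_id=np.arange(1, natoms + 1),
            molecule_id=resid,
            residue=resname.astype(str),
            particle=atomname.astype(str),
            role=role, positions=pos, box=box, time=time,
        ))
        i += natoms + 3
    return frames


def _parse_pdb(path: Path, role_rules) -> list[BeadFrame]:
    frames = []
    box = None
    cur: list[tuple] = []
    model_idx = 0

    def flush():
        nonlocal cur, model_idx
        if not cur:
            return
        if box is None:
            raise ParseError(f"{path}: missing CRYST1 box record (box is required)")
        resid = np.array([c[0] for c in cur], dtype=int)
        resname = np.array([c[1] for c in cur], dtype=str)
        atomname = np.array([c[2] for c in cur], dtype=str)
        pos = np.array([c[3] for c in cur]) / 10.0  # Angstrom -> nm
        role = assign_roles(resname, atomname, role_rules)
        pos = np.mod(pos, box)
        frames.append(BeadFrame(
            particle_id=np.arange(1, len(cur) + 1),
            molecule_id=resid, residue=resname, particle=atomname,
            role=role, positions=pos, box=np.asarray(box),
            time=float(model_idx),
        ))
        cur = []
        model_idx += 1

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                box = np.array([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])]) / 10.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed CRYST1") from exc
        elif rec in ("ATOM", "HETATM"):
            try:
                atomname = line[12:16].strip()
                resname = line[17:21].strip()
                resid = int(line[22:26])
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed ATOM record") from exc
            cur.append((resid, resname, atomname, xyz))
        elif rec == "ENDMDL":
            flush()
    flush()
    if not frames:
        raise ParseError(f"{path}: no ATOM records found")
    return frames


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _read_bead_table(path: Path) -> list[BeadFrame]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in BEAD_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: bead table missing columns {missing}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ParseError(f"{path}: missing box sidecar {sidecar} (box is required)")
    meta = json.loads(sidecar.read_text())
    frames = []
    role_codes = {r.name: int(r) for r in Role}
    for rec in meta["frames"]:
        sub = df[df["frame"] == rec["frame"]]
        pressures = rec.get("pressures_bar")
        frames.append(BeadFrame(
            particle_id=sub["particle_id"].to_numpy(),
            molecule_id=sub["molecule_id"].to_numpy(),
            residue=sub["residue"].to_numpy(dtype=str),
            particle=sub["particle"].to_numpy(dtype=str),
            role=sub["role"].map(role_codes).to_numpy(dtype=np.int8),
            positions=sub[["x_nm", "y_nm", "z_nm"]].to_numpy(),
            box=np.asarray(rec["box_nm"], dtype=float),
            time=float(rec["time_ns"]),
            pressures=tuple(pressures) if pressures is not None else None,
        ))
    return frames


def read_frames(path, format: str = "auto",
                role_rules: Mapping | None = None) -> list[BeadFrame]:
    """Read coordinate frames from GRO, PDB, or the native bead table.

    Parameters
    ----------
    path : path-like
        Input file.  The bead-table format expects a ``<path>.meta.json``
        sidecar next to it.
    format : {"gro", "pdb", "bead_table", "auto"}
        ``auto`` dispatches on the file extension.
    role_rules : mapping, optional
        Overrides for the default role assignment rules
        (see :func:`default_role_rules`).

    Returns
    -------
    list of BeadFrame
        One frame per model/frame, positions in nm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        ext = path.suffix.lower()
        format = {".gro": "gro", ".pdb": "pdb"}.get(ext, "bead_table")
    if format == "gro":
        frames = _parse_gro(path, role_rules)
    elif format == "pdb":
        frames = _parse_pdb(path, role_rules)
    elif format == "bead_table":
        frames = _read_bead_table(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    times = [f.time for f in frames]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        logger.warning("frame time stamps are not non-decreasing: %s", times[:20])
    return frames


def write_bead_table(frames: Sequence[BeadFrame], path) -> Path:
    """Write frames as a CSV bead table plus a JSON sidecar.

    The CSV carries one row per particle with full-precision decimal text
    (``repr`` of the float), so a read-back reproduces positions
    bit-identically.  Box dimensions, times, and pressures go to the
    ``<path>.meta.json`` sidecar.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    path = Path(path)
    meta = {"frames": []}
    chunks = []
    for i, fr in enumerate(frames):
        chunks.append(pd.DataFrame({
            "frame": i,
            "time_ns": fr.time,
            "particle_id": fr.particle_id,
            "molecule_id": fr.molecule_id,
            "residue": fr.residue,
            "particle": fr.particle,
            "role": [Role(r).name for r in fr.role],
            "x_nm": fr.positions[:, 0],
            "y_nm": fr.positions[:, 1],
            "z_nm": fr.positions[:, 2],
        }))
        meta["frames"].append({
            "frame": i,
            "time_ns": fr.time,
            "box_nm": fr.box.tolist(),
            "pressures_bar": list(fr.pressures) if fr.pressures is not None else None,
        })
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path
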