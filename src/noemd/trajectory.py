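"""Trajectory container, format readers and periodic-distance primitives.

Everything downstream works on :class:`Trajectory`: an ordered stack of
coordinate frames (nm) in a cubic periodic box with constant snapshot
spacing (ps), plus an atom table assigning each atom a *role* --
``peptide-H``, ``fluorine``, ``water-O`` or ``other`` -- and a molecule id.

Standard MD formats (PDB/GRO topology, XTC/TRR/DCD frames) are read through
MDAnalysis; a dependency-free plain-text internal format is provided for
fixtures and synthetic data and round-trips bit-identically.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLE_PEPTIDE_H = "peptide-H"
ROLE_FLUORINE = "fluorine"
ROLE_WATER_O = "water-O"
ROLE_OTHER = "other"

#: residue-name dialects for water (PDB v3 and GROMACS)
WATER_RESNAMES = {"SOL", "HOH", "WAT", "TIP3", "TIP4", "TIP5", "T5P"}
#: residue-name dialects for hexafluoroisopropanol
HFIP_RESNAMES = {"HFP", "HFIP", "HFI"}

ATOM_COLUMNS = ["name", "resname", "resid", "role", "molecule_id"]

_LABEL_RE = re.compile(r"^(\d+)([A-Za-z]{3})(\w+)$")


def parse_atom_label(label: str) -> tuple[int, str, str]:
    """Split a label like ``"6TrpHE1"`` into (resid, resname, atom name)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(
            f"cannot parse atom label {label!r}; expected <resid><Res3><name>, e.g. '6TrpHE1'"
        )
    return int(m.group(1)), m.group(2), m.group(3)


def assign_roles(atoms: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Assign roles from residue/atom naming conventions.

    F* atoms in HFIP residues become ``fluorine``; OW/O in water residues
    become ``water-O``; H* in any other (peptide) residue becomes
    ``peptide-H``. Everything else is ``other``; with ``strict=True`` an
    unrecognised residue raises, listing the unassigned atoms.
    """
    atoms = atoms.copy()
    roles = []
    unknown = []
    for _, row in atoms.iterrows():
        resname = str(row["resname"]).upper()
        name = str(row["name"]).upper()
        if resname in HFIP_RESNAMES:
            roles.append(ROLE_FLUORINE if name.startswith("F") else ROLE_OTHER)
        elif resname in WATER_RESNAMES:
            roles.append(ROLE_WATER_O if name in ("OW", "O") or name.startswith("OW") else ROLE_OTHER)
        elif name.startswith("H") or (name[:1].isdigit() and "H" in name):
            roles.append(ROLE_PEPTIDE_H)
        else:
            roles.append(ROLE_OTHER)
            unknown.append(f"{row['resid']}{row['resname']}{row['name']}")
    atoms["role"] = roles
    if strict and unknown:
        raise ValueError(f"atoms with no role assignment rule: {unknown}")
    return atoms


@dataclass
class SelectionSpec:
    """Reference hydrogen + solvent filter used by the NOE pipeline."""

    reference_hydrogen: str
    solvent_role: str = ROLE_FLUORINE
    cutoff_radius: float = 3.0  # nm, origin-frame inclusion radius


@dataclass
class Trajectory:
    """Coordinate frames (nm) in a cubic periodic box.

    Attributes
    ----------
    coords:
        (n_frames, n_atoms, 3) wrapped coordinates in nm.
    box_edge:
        cubic box edge, nm (constant across frames).
    dt:
        snapshot spacing, ps.
    atoms:
        per-atom table with columns ``name resname resid role molecule_id``.
    unwrapped:
        optional (n_frames, n_atoms, 3) continuous coordinates for MSD and
        lagged-displacement work; computed on demand by :meth:`unwrap`.
    """

    coords: np.ndarray
    box_edge: float
    dt: float
    atoms: pd.DataFrame
    unwrapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")
        if self.dt <= 0:
            raise ValueError("snapshot spacing dt must be positive")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError(
                f"atom table has {len(self.atoms)} rows but frames carry "
                f"{self.coords.shape[1]} atoms"
            )
        if self.unwrapped is not None and self.unwrapped.shape != self.coords.shape:
            raise ValueError("unwrapped array must match coords shape")

    # -- basic views ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps, ps."""
        return np.arange(self.n_frames) * self.dt

    def atom_index(self, label: str) -> int:
        """Resolve a ``"6TrpHE1"``-style label to a unique atom index."""
        resid, resname, name = parse_atom_label(label)
        mask = (
            (self.atoms["resid"] == resid)
            & (self.atoms["resname"].str.upper() == resname.upper())
            & (self.atoms["name"].str.upper() == name.upper())
        )
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"no atom matches label {label!r}")
        if len(idx) > 1:
            raise KeyError(f"label {label!r} matches {len(idx)} atoms")
        return int(idx[0])

    def role_indices(self, role: str) -> np.ndarray:
        return np.flatnonzero((self.atoms["role"] == role).to_numpy())

    def unwrap(self) -> np.ndarray:
        """Continuous coordinates via cumulative minimum-image displacements.

        Valid when no atom moves more than half a box edge between snapshots.
        The result is cached on the instance.
        """
        if self.unwrapped is None:
            d = np.diff(self.coords.astype(np.float64), axis=0)
            d -= self.box_edge * np.round(d / self.box_edge)
            uw = np.empty_like(self.coords, dtype=np.float64)
            uw[0] = self.coords[0]
            np.cumsum(d, axis=0, out=uw[1:])
            uw[1:] += self.coords[0]
            self.unwrapped = uw.astype(self.coords.dtype)
        return self.unwrapped

    # -- internal text format ------------------------------------------
    def write_internal(self, path: str | Path) -> None:
        """Write the plain-text internal format (round-trips bit-identically)."""
        path = Path(path)
        has_uw = self.unwrapped is not None
        header = {
            "n_frames": int(self.n_frames),
            "n_atoms": int(self.n_atoms),
            "box_edge": float(self.box_edge),
            "dt": float(self.dt),
            "unwrapped": has_uw,
            "dtype": str(self.coords.dtype),
        }
        with path.open("w") as fh:
            fh.write("#noemd-trajectory 1\n")
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            fh.write("#atoms\n")
            self.atoms[ATOM_COLUMNS].to_csv(fh, sep="\t", index=False)
            fh.write("#frames\n")
            for f in range(self.n_frames):
                block = self.coords[f]
                if has_uw:
                    block = np.hstack([block, self.unwrapped[f]])
                np.savetxt(fh, block, fmt="%.9g")

    @classmethod
    def read_internal(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        with path.open() as fh:
            magic = fh.readline().strip()
            if magic != "#noemd-trajectory 1":
                raise ValueError(f"{path} is not a noemd internal trajectory")
            header = json.loads(fh.readline())
            if fh.readline().strip() != "#atoms":
                raise ValueError("malformed internal trajectory: missing #atoms")
            atom_lines = [fh.readline() for _ in range(header["n_atoms"] + 1)]
            atoms = pd.read_csv(
                pd.io.common.StringIO("".join(atom_lines)), sep="\t"
            )
            if fh.readline().strip() != "#frames":
                raise ValueError("malformed internal trajectory: missing #frames")
            data = np.loadtxt(fh, dtype=np.float64)
        n_f, n_a = header["n_frames"], header["n_atoms"]
        width = 6 if header["unwrapped"] else 3
        data = data.reshape(n_f, n_a, width).astype(header["dtype"])
        coords = data[:, :, :3]
        uw = data[:, :, 3:6] if header["unwrapped"] else None
        return cls(coords, header["box_edge"], header["dt"], atoms, unwrapped=uw)


def read_trajectory(
    topology_path: str | Path,
    frames_path: str | Path | None = None,
    dt: float | None = None,
    strict_roles: bool = False,
) -> Trajectory:
    """Read PDB/GRO (+XTC/TRR/DCD) through MDAnalysis, or the internal format.

    Coordinates are converted to nm; roles are assigned from naming rules.
    ``dt`` (ps) overrides whatever spacing the frame file reports.
    """
    topology_path = Path(topology_path)
    if topology_path.suffix in (".noemd", ".txt") or _looks_internal(topology_path):
        return Trajectory.read_internal(topology_path)

    import MDAnalysis as mda

    if frames_path is None:
        u = mda.Universe(str(topology_path))
    else:
        u = mda.Universe(str(topology_path), str(frames_path))
    atoms = pd.DataFrame(
        {
            "name": u.atoms.names,
            "resname": u.atoms.resnames,
            "resid": u.atoms.resids,
        }
    )
    atoms = assign_roles(atoms, strict=strict_roles)
    atoms["molecule_id"] = u.atoms.resids
    coords = np.empty((len(u.trajectory), len(u.atoms), 3), dtype=np.float32)
    edges = []
    for i, ts in enumerate(u.trajectory):
        coords[i] = ts.positions / 10.0  # Angstrom -> nm
        dims = ts.dimensions
        if dims is None or dims[0] <= 0:
            raise ValueError("trajectory frames carry no box information")
        if not (abs(dims[0] - dims[1]) < 1e-3 and abs(dims[0] - dims[2]) < 1e-3):
            raise ValueError("only cubic boxes are supported")
        edges.append(dims[0] / 10.0)
    if dt is None:
        dt = float(getattr(u.trajectory, "dt", 1.0)) or 1.0
    return Trajectory(coords, float(np.mean(edges)), float(dt), atoms)


def _looks_internal(path: Path) -> bool:
    try:
        with path.open() as fh:
            return fh.readline().startswith("#noemd-trajectory")
    except (OSError, UnicodeDecodeError):
        return False


# -- periodic-distance primitives --------------------------------------

def min_image_vector(delta: np.ndarray, edge: float) -> np.ndarray:
    """Map displacement(s) to the minimum-image convention for a cubic box."""
    delta = np.asarray(delta, dtype=np.float64)
    return delta - edge * np.round(delta / edge)


def min_image_distance(traj: Trajectory, frame: int, i: int, j: int) -> float:
    """Minimum-image distance (nm) between atoms ``i`` and ``j`` at ``frame``."""
    d = min_image_vector(traj.coords[frame, j] - traj.coords[frame, i], traj.box_edge)
    return float(np.linalg.norm(d))


@dataclass
class DistanceSeries:
    """Per-frame minimum-image distance between two named atoms."""

    values: np.ndarray  # nm, one per frame
    dt: float
    atom_a: str
    atom_b: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def range(self) -> tuple[float, float]:
        return float(np.min(self.values)), float(np.max(self.values))


def distance_series(traj: Trajectory, atom_a: str, atom_b: str) -> DistanceSeries:
    """Minimum-image distance between two atoms across all frames."""
    ia, ib = traj.atom_index(atom_a), traj.atom_index(atom_b)
    d = min_image_vector(traj.coords[:, ib] - traj.coords[:, ia], traj.box_edge)
    return DistanceSeries(np.linalg.norm(d, axis=1), traj.dt, atom_a, atom_b)
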