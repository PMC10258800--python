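"""Solvation shells and solvent-contact persistence.

Shells are concentric 0.556 nm layers around a reference peptide hydrogen
(0.556 nm being the effective diameter of a rapidly rotating HFIP
molecule); occupancies count fluorine atoms and water oxygens per shell
per snapshot. Contacts follow the strict consecutive-snapshot rule: an
H-F contact exists while the pair distance is <= 0.5 nm (H-Ow: 0.4 nm),
and a single snapshot outside the cutoff ends the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import (
    ROLE_FLUORINE,
    ROLE_WATER_O,
    SelectionSpec,
    Trajectory,
    min_image_vector,
)

DEFAULT_SHELL_WIDTH = 0.556  # nm
DEFAULT_CONTACT_CUTOFFS = {"fluorine": 0.5, "water": 0.4}  # nm
DEFAULT_LONG_CONTACT_THRESHOLD = 60.0  # ps
BULK_WATER_TO_FLUORINE_RATIO = 2.57
"""7434 waters / (482 HFIP x 6 F) for the emulated box composition."""


def composition_summary(n_hfip: int = 482, n_water: int = 7434) -> dict:
    """Box-composition arithmetic: water:fluorine ratio and HFIP mole fraction."""
    n_f = 6 * n_hfip
    return {
        "n_hfip": n_hfip,
        "n_water": n_water,
        "n_fluorines": n_f,
        "water_to_fluorine_ratio": n_water / n_f,
        "hfip_mole_fraction": n_hfip / (n_hfip + n_water),
    }


@dataclass(frozen=True)
class ShellDefinition:
    """Contiguous radial shells [k*width, (k+1)*width), k = 0..n_shells-1."""

    width: float = DEFAULT_SHELL_WIDTH
    n_shells: int = 5

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("shell width must be positive")
        if self.n_shells < 1:
            raise ValueError("need at least one shell")

    @property
    def edges(self) -> np.ndarray:
        return self.width * np.arange(self.n_shells + 1, dtype=np.float64)

    @property
    def outer_radius(self) -> float:
        return self.width * self.n_shells


@dataclass
class ShellOccupancySeries:
    """Per-frame fluorine / water-oxygen counts per shell.

    ``counts`` has shape (n_frames, n_shells, 2) with species order
    (fluorine, water-O).
    """

    counts: np.ndarray
    shells: ShellDefinition
    reference_hydrogen: str
    dt: float

    SPECIES = ("fluorine", "water")

    def mean_counts(self) -> pd.DataFrame:
        m = self.counts.mean(axis=0)
        return pd.DataFrame(
            m, columns=["F", "Ow"], index=[f"shell{i+1}" for i in range(m.shape[0])]
        )

    def water_to_fluorine_ratio(self, shell: int | None = None, cumulative: bool = False):
        """Mean-count ratio per shell (1-based ``shell``), NaN-flagged where
        the fluorine count is zero. ``cumulative`` uses shell unions 1..k."""
        m = self.counts.mean(axis=0)
        if cumulative:
            m = np.cumsum(m, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(m[:, 0] > 0, m[:, 1] / m[:, 0], np.nan)
        return r if shell is None else float(r[shell - 1])


def shell_occupancy_series(
    traj: Trajectory,
    sel: SelectionSpec,
    shells: ShellDefinition | None = None,
) -> ShellOccupancySeries:
    """Bin every fluorine and water oxygen into shells, every frame."""
    shells = shells or ShellDefinition()
    if shells.outer_radius > traj.box_edge / 2:
        raise ValueError(
            f"outer shell radius {shells.outer_radius:.3f} nm exceeds half the box "
            f"edge ({traj.box_edge / 2:.3f} nm): minimum-image binning is ambiguous"
        )
    ih = traj.atom_index(sel.reference_hydrogen)
    edges = shells.edges
    counts = np.zeros((traj.n_frames, shells.n_shells, 2), dtype=np.int64)
    for si, role in enumerate((ROLE_FLUORINE, ROLE_WATER_O)):
        idx = traj.role_indices(role)
        if idx.size == 0:
            continue
        d = traj.coords[:, idx, :] - traj.coords[:, ih, None, :]
        d = d - traj.box_edge * np.round(d / traj.box_edge)
        r = np.sqrt((d.astype(np.float64) ** 2).sum(axis=2))
        for k in range(shells.n_shells):
            counts[:, k, si] = ((r >= edges[k]) & (r < edges[k + 1])).sum(axis=1)
    return ShellOccupancySeries(counts, shells, sel.reference_hydrogen, traj.dt)


def shell_average_table(
    series: list[ShellOccupancySeries],
    bulk_ratio: float = BULK_WATER_TO_FLUORINE_RATIO,
) -> pd.DataFrame:
    """Replicate-averaged shell occupancies, one row per (hydrogen, shell).

    Columns mirror the occupancy-table layout: mean F count, mean Ow count,
    water:F ratio, mean deviation from the mean across replicate series, and
    an enrichment flag (ratio above ``bulk_ratio`` = locally water-enriched).
    """
    if not series:
        raise ValueError("need at least one occupancy series")
    rows = []
    by_h: dict[str, list[ShellOccupancySeries]] = {}
    for s in series:
        by_h.setdefault(s.reference_hydrogen, []).append(s)
    for hydrogen, group in by_h.items():
        n_shells = group[0].shells.n_shells
        per_rep = np.array([g.counts.mean(axis=0) for g in group])  # (rep, shell, 2)
        mean = per_rep.mean(axis=0)
        mdev = np.abs(per_rep - mean).mean(axis=0)
        for k in range(n_shells):
            f_mean, ow_mean = mean[k]
            ratio = ow_mean / f_mean if f_mean > 0 else np.nan
            rows.append(
                {
                    "hydrogen": hydrogen,
                    "shell": k + 1,
                    "F_mean": f_mean,
                    "Ow_mean": ow_mean,
                    "water_to_F_ratio": ratio,
                    "F_mean_dev": mdev[k, 0],
                    "Ow_mean_dev": mdev[k, 1],
                    "enrichment": (
                        "water" if (np.isfinite(ratio) and ratio > bulk_ratio) else "hfip"
                    ),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContactEvent:
    """Maximal run of consecutive snapshots with the pair inside the cutoff."""

    atom_index: int
    species: str  # "fluorine" | "water"
    start_frame: int
    n_frames: int
    duration_ps: float
    censored_start: bool
    censored_end: bool
    molecule_id: int = -1


def _runs(mask: np.ndarray):
    """(start, length) of each maximal True run in a boolean series."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends - starts))


def contact_events(
    traj: Trajectory,
    sel: SelectionSpec,
    cutoffs: dict | None = None,
    per_molecule: bool = False,
) -> list[ContactEvent]:
    """Detect solvent contacts with the reference hydrogen.

    ``cutoffs`` maps species to distances (nm), default F 0.5 / water 0.4.
    With ``per_molecule=True`` fluorine contacts are aggregated per HFIP
    molecule (contact while *any* of its fluorines is inside the cutoff);
    the default counts atom-level events. Events touching either end of
    the trajectory are flagged censored.
    """
    cutoffs = dict(DEFAULT_CONTACT_CUTOFFS, **(cutoffs or {}))
    unknown = set(cutoffs) - {"fluorine", "water"}
    if unknown:
        raise ValueError(f"unknown species cutoff(s): {sorted(unknown)}")
    ih = traj.atom_index(sel.reference_hydrogen)
    mol_ids = traj.atoms["molecule_id"].to_numpy()
    events: list[ContactEvent] = []
    n_last = traj.n_frames - 1
    for species, role in (("fluorine", ROLE_FLUORINE), ("water", ROLE_WATER_O)):
        idx = traj.role_indices(role)
        if idx.size == 0:
            continue
        cutoff = cutoffs[species]
        d = traj.coords[:, idx, :] - traj.coords[:, ih, None, :]
        d = d - traj.box_edge * np.round(d / traj.box_edge)
        within = (d.astype(np.float64) ** 2).sum(axis=2) <= cutoff**2
        if per_molecule and species == "fluorine":
            mols = mol_ids[idx]
            cols = []
            for mol in np.unique(mols):
                cols.append((mol, within[:, mols == mol].any(axis=1)))
            series_iter = [(-1, mol, m) for mol, m in cols]
        else:
            series_iter = [
                (int(idx[j]), int(mol_ids[idx[j]]), within[:, j])
                for j in range(idx.size)
            ]
        for atom_i, mol, mask in series_iter:
            for start, length in _runs(mask):
                events.append(
                    ContactEvent(
                        atom_index=atom_i,
                        species=species,
                        start_frame=int(start),
                        n_frames=int(length),
                        duration_ps=float(length * traj.dt),
                        censored_start=start == 0,
                        censored_end=start + length - 1 == n_last,
                        molecule_id=mol,
                    )
                )
    events.sort(key=lambda e: (e.species, e.atom_index, e.start_frame))
    return events


@dataclass
class ContactStats:
    """Contact-rate statistics in the layout of the contact-duration table."""

    contacts_per_ns: float
    percent_longer_than_threshold: float
    mean_long_duration_ps: float
    threshold_ps: float
    n_events: int
    n_censored: int
    no_events: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.percent_longer_than_threshold <= 100:
            raise ValueError("percentage out of [0, 100]")


def contact_stats(
    events: list[ContactEvent],
    trajectory_length_ns: float,
    threshold_ps: float = DEFAULT_LONG_CONTACT_THRESHOLD,
) -> ContactStats:
    """Events started per ns, share longer than the threshold, and the mean
    duration of over-threshold events (censored events count toward rates
    and percentages at their observed length but are excluded from the
    long-duration mean)."""
    if trajectory_length_ns <= 0:
        raise ValueError("trajectory length must be positive")
    n = len(events)
    if n == 0:
        return ContactStats(0.0, 0.0, 0.0, threshold_ps, 0, 0, no_events=True)
    durations = np.array([e.duration_ps for e in events])
    censored = np.array([e.censored_start or e.censored_end for e in events])
    long_mask = durations > threshold_ps
    long_complete = durations[long_mask & ~censored]
    return ContactStats(
        contacts_per_ns=n / trajectory_length_ns,
        percent_longer_than_threshold=100.0 * long_mask.sum() / n,
        mean_long_duration_ps=float(long_complete.mean()) if long_complete.size else 0.0,
        threshold_ps=threshold_ps,
        n_events=n,
        n_censored=int(censored.sum()),
    )
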