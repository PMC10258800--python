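"""Translational diffusion from trajectories.

Three estimators: the Einstein relation (MSD slope / 6), the
fixed-interval displacement estimator used for slow solutes
(<dr^2>/(6 dt) over successive snapshots), and a distance-resolved local
coefficient where molecules are binned by their origin-frame distance to
a reference hydrogen and each bin's MSD over a short lag is converted to
a local D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import d_nm2_per_ps_to_si
from .trajectory import (
    ROLE_FLUORINE,
    ROLE_WATER_O,
    SelectionSpec,
    Trajectory,
)


def _molecule_centers(traj: Trajectory, role: str) -> np.ndarray:
    """Unwrapped per-molecule centres (n_frames, n_mol, 3) for a role."""
    idx = traj.role_indices(role)
    if idx.size == 0:
        raise ValueError(f"no atoms with role {role!r}")
    uw = traj.unwrap()[:, idx, :].astype(np.float64)
    mols = traj.atoms["molecule_id"].to_numpy()[idx]
    uniq, inv = np.unique(mols, return_inverse=True)
    if uniq.size == idx.size:
        return uw
    counts = np.bincount(inv, minlength=uniq.size).astype(np.float64)
    acc = np.zeros((uniq.size, traj.n_frames, 3))
    np.add.at(acc, inv, uw.transpose(1, 0, 2))
    acc /= counts[:, None, None]
    return acc.transpose(1, 0, 2)


_SPECIES_ROLE = {"hfip": ROLE_FLUORINE, "fluorine": ROLE_FLUORINE, "water": ROLE_WATER_O}


@dataclass
class DiffusionEstimate:
    """D in m^2 s^-1 with a molecule-wise standard error."""

    d: float
    stderr: float
    fit_window_ps: tuple[float, float]
    method: str
    n_molecules: int = 0

    def __post_init__(self) -> None:
        if self.d < 0 and abs(self.d) > 5 * max(self.stderr, 1e-30):
            raise ValueError("significantly negative diffusion coefficient")


def einstein_diffusion(
    traj: Trajectory,
    species: str = "water",
    fit_window: tuple[float, float] | None = None,
    n_lag_points: int = 12,
) -> DiffusionEstimate:
    """Self-diffusion from the Einstein relation, averaged over molecules.

    The MSD (all origins) is fitted linearly over ``fit_window`` (ps,
    default 10%..50% of the trajectory span); D = slope/6. The quoted
    error is the standard error of per-molecule D values.
    """
    centers = _molecule_centers(traj, _SPECIES_ROLE[species.lower()])
    n_frames = centers.shape[0]
    span = (n_frames - 1) * traj.dt
    if fit_window is None:
        fit_window = (0.1 * span, 0.5 * span)
    lo, hi = fit_window
    if not (0 <= lo < hi <= span):
        raise ValueError("fit window must lie within the trajectory span")
    lag_lo = max(int(np.ceil(lo / traj.dt)), 1)
    lag_hi = int(hi / traj.dt)
    lags = np.unique(np.linspace(lag_lo, lag_hi, n_lag_points).astype(int))
    if lags.size < 5:
        raise ValueError(
            "fewer than 5 lag points in the fit window; widen the window "
            "(short-lag-only windows are ballistic-regime dominated)"
        )
    t = lags * traj.dt
    msd = np.empty((lags.size, centers.shape[1]))
    for i, lag in enumerate(lags):
        disp = centers[lag:] - centers[:-lag]
        msd[i] = (disp**2).sum(axis=2).mean(axis=0)
    A = np.vstack([t, np.ones_like(t)]).T
    coef, *_ = np.linalg.lstsq(A, msd, rcond=None)
    d_per_mol = coef[0] / 6.0  # nm^2/ps
    d_mean = d_nm2_per_ps_to_si(float(d_per_mol.mean()))
    se = d_nm2_per_ps_to_si(
        float(d_per_mol.std(ddof=1) / np.sqrt(d_per_mol.size))
        if d_per_mol.size > 1
        else 0.0
    )
    return DiffusionEstimate(
        d=d_mean,
        stderr=se,
        fit_window_ps=(float(t[0]), float(t[-1])),
        method="einstein_msd",
        n_molecules=centers.shape[1],
    )


def interval_displacement_diffusion(
    traj: Trajectory,
    selection: np.ndarray | str,
    interval: float = 10.0,
    n_intervals: int = 1000,
) -> DiffusionEstimate:
    """D from the mean squared displacement of a selection's centroid over
    ``n_intervals`` successive intervals (the slow-solute estimator)."""
    if isinstance(selection, str):
        idx = np.array([traj.atom_index(selection)])
    else:
        idx = np.asarray(selection, dtype=int)
    lag = int(round(interval / traj.dt))
    if lag < 1:
        raise ValueError("interval must be at least one snapshot")
    if traj.n_frames < n_intervals * lag + 1:
        raise ValueError(
            f"need {n_intervals * lag + 1} frames for {n_intervals} intervals "
            f"of {interval} ps, have {traj.n_frames}"
        )
    centroid = traj.unwrap()[:, idx, :].astype(np.float64).mean(axis=1)
    pts = centroid[: n_intervals * lag + 1 : lag]
    dr2 = ((np.diff(pts, axis=0)) ** 2).sum(axis=1)
    d = dr2.mean() / (6.0 * lag * traj.dt)
    se = dr2.std(ddof=1) / np.sqrt(dr2.size) / (6.0 * lag * traj.dt)
    return DiffusionEstimate(
        d=d_nm2_per_ps_to_si(float(d)),
        stderr=d_nm2_per_ps_to_si(float(se)),
        fit_window_ps=(interval, interval * n_intervals),
        method="interval_displacement",
        n_molecules=1,
    )


@dataclass
class DiffusionProfile:
    """Distance-resolved local D per species; low-count bins are masked."""

    bin_edges: np.ndarray  # nm
    d_by_species: dict  # species -> (n_bins,) m^2/s with NaN where masked
    counts: dict  # species -> (n_bins,) origin-molecule samples
    lag_ps: float
    min_count: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def local_diffusion_profile(
    traj: Trajectory,
    sel: SelectionSpec,
    bin_width: float = 0.2,
    lag: float = 20.0,
    r_max: float = 3.0,
    min_count: int = 200,
    species: tuple[str, ...] = ("hfip", "water"),
) -> DiffusionProfile:
    """Local D(r): bin molecules by origin distance to the reference
    hydrogen, convert each bin's mean squared displacement over ``lag`` to
    a diffusion coefficient.

    Bin membership is decided at the origin only; molecules may drift
    between bins during the lag, which smooths sharp steps over roughly a
    diffusion length sqrt(6 D lag).
    """
    if lag < traj.dt:
        raise ValueError("lag must be at least one snapshot interval")
    lagf = int(round(lag / traj.dt))
    if traj.n_frames <= lagf:
        raise ValueError("trajectory shorter than the requested lag")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    if edges.size < 2:
        raise ValueError("profile needs at least one bin")
    ih = traj.atom_index(sel.reference_hydrogen)
    ref_w = traj.coords[:, ih, :]
    d_out, c_out = {}, {}
    got_any = False
    for sp in species:
        try:
            centers = _molecule_centers(traj, _SPECIES_ROLE[sp.lower()])
        except ValueError:
            continue
        got_any = True
        rel = centers[:-lagf] - ref_w[:-lagf, None, :]
        rel -= traj.box_edge * np.round(rel / traj.box_edge)
        r0 = np.sqrt((rel**2).sum(axis=2)).ravel()
        disp2 = ((centers[lagf:] - centers[:-lagf]) ** 2).sum(axis=2).ravel()
        which = np.digitize(r0, edges) - 1
        ok = (which >= 0) & (which < edges.size - 1)
        counts = np.bincount(which[ok], minlength=edges.size - 1)
        sums = np.bincount(which[ok], weights=disp2[ok], minlength=edges.size - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d_local = sums / counts / (6.0 * lagf * traj.dt)
        d_local[counts < min_count] = np.nan
        d_out[sp] = np.array([d_nm2_per_ps_to_si(v) for v in d_local])
        c_out[sp] = counts
    if not got_any:
        raise ValueError("no solvent molecules available for the profile")
    return DiffusionProfile(edges, d_out, c_out, float(lagf * traj.dt), min_count)
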