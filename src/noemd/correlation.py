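"""Intermolecular dipolar correlation functions G(t).

For a reference peptide hydrogen H and the solvent fluorines F_k,

    G(t) = < sum_k P2(cos theta_k(t0, t0+t)) / (r_k(t0)^3 r_k(t0+t)^3) >

averaged over time origins t0, where r is the minimum-image H-F distance,
theta the angle between the origin and lagged H->F vectors, and the sum
runs over fluorines within the origin-frame cutoff (default 3.0 nm).
Included spins are followed via their unwrapped displacement even if they
later leave the cutoff, so the correlation decays smoothly.

Units: G in nm^-6, lags in ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .solvation import ShellDefinition
from .trajectory import SelectionSpec, Trajectory

MAX_UNIFORM_LAG_POINTS = 1000


@dataclass
class CorrelationFunction:
    """Averaged dipolar correlation on a lag grid.

    ``stderr`` is the standard error over time origins (origins overlap, so
    it is a noise scale for weighting, not an independent-sample error).
    """

    lags: np.ndarray  # ps, starting at 0
    values: np.ndarray  # nm^-6
    n_evaluations: np.ndarray  # origins per lag
    stderr: np.ndarray
    reference_hydrogen: str
    shell_label: str = "all"
    cutoff_radius: float = 3.0  # nm
    lag_thinning: str = "uniform"  # or "log"
    time_unit: str = "ps"
    value_unit: str = "nm^-6"

    def __post_init__(self) -> None:
        if self.lags[0] != 0:
            raise ValueError("lag grid must start at 0")
        if len(self.lags) > MAX_UNIFORM_LAG_POINTS and self.lag_thinning == "uniform":
            raise ValueError("uniform lag grid capped at 1000 points")
        if np.any(self.n_evaluations < 1):
            raise ValueError("every reported lag needs at least one evaluation")

    @property
    def g0(self) -> float:
        return float(self.values[0])


def _lag_grid(max_lag_frames: int) -> tuple[np.ndarray, str]:
    """Uniform lag grid at snapshot spacing up to 1000 points; longer
    windows switch to logarithmic thinning (flagged)."""
    if max_lag_frames <= MAX_UNIFORM_LAG_POINTS - 1:
        return np.arange(max_lag_frames + 1, dtype=np.int64), "uniform"
    n_log = MAX_UNIFORM_LAG_POINTS - 101
    lags = np.unique(
        np.concatenate(
            [
                np.arange(101, dtype=np.int64),
                np.geomspace(101, max_lag_frames, n_log).astype(np.int64),
            ]
        )
    )
    return lags, "log"


def _relative_unwrapped(traj: Trajectory, sel: SelectionSpec) -> np.ndarray:
    """Unwrapped solvent positions relative to the reference hydrogen."""
    ih = traj.atom_index(sel.reference_hydrogen)
    solvent = traj.role_indices(sel.solvent_role)
    if solvent.size == 0:
        raise ValueError(f"no atoms with role {sel.solvent_role!r}")
    uw = traj.unwrap()
    rel = uw[:, solvent, :].astype(np.float32, copy=True)
    rel -= uw[:, ih, None, :].astype(np.float32)
    return rel


def _compute(
    traj: Trajectory,
    sel: SelectionSpec,
    shell_edges: np.ndarray,
    max_lag: float,
    origin_stride: int,
):
    if max_lag >= (traj.n_frames - 1) * traj.dt:
        raise ValueError(
            f"max_lag {max_lag} ps needs more than the {traj.n_frames} available frames"
        )
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    if shell_edges[-1] > traj.box_edge * np.sqrt(3) / 2:
        raise ValueError("cutoff exceeds the largest minimum-image distance")
    rel = _relative_unwrapped(traj, sel)
    max_lag_frames = int(round(max_lag / traj.dt))
    lags, thinning = _lag_grid(max_lag_frames)
    g_sum, pair_count, n_origins, tot_sum, tot_sq = _kernels.dipolar_correlation_sums(
        rel,
        np.float32(traj.box_edge),
        lags,
        int(origin_stride),
        np.asarray(shell_edges, dtype=np.float64),
    )
    if pair_count[:, 0].sum() == 0:
        raise ValueError(
            f"no {sel.solvent_role} atoms inside the {shell_edges[-1]} nm cutoff "
            "at any origin"
        )
    n = n_origins.astype(np.float64)
    mean = tot_sum / n
    var = np.maximum(tot_sq / n - mean**2, 0.0)
    stderr = np.sqrt(var / np.maximum(n - 1, 1))
    return lags * traj.dt, g_sum / n, n_origins, stderr, thinning


def compute_dipolar_correlation(
    traj: Trajectory,
    sel: SelectionSpec,
    max_lag: float,
    origin_stride: int = 1,
) -> CorrelationFunction:
    """All-solvent dipolar correlation function.

    Parameters
    ----------
    max_lag : float
        longest lag, ps.
    origin_stride : int
        origin spacing in frames (1 = every snapshot).
    """
    edges = np.array([0.0, sel.cutoff_radius])
    lags_ps, g, n_origins, stderr, thinning = _compute(
        traj, sel, edges, max_lag, origin_stride
    )
    return CorrelationFunction(
        lags=lags_ps,
        values=g[0],
        n_evaluations=n_origins,
        stderr=stderr,
        reference_hydrogen=sel.reference_hydrogen,
        shell_label="all",
        cutoff_radius=sel.cutoff_radius,
        lag_thinning=thinning,
    )


def shell_resolved_correlation(
    traj: Trajectory,
    sel: SelectionSpec,
    shells: ShellDefinition,
    max_lag: float,
    origin_stride: int = 1,
) -> list[CorrelationFunction]:
    """G(t) decomposed by the origin-frame solvent shell of each fluorine.

    Contributions are routed by where the spin *starts*; summed over shells
    they reproduce the all-solvent G(t) computed over the same origins with
    cutoff equal to the outer shell edge (exact additivity).
    """
    edges = shells.edges
    lags_ps, g, n_origins, stderr, thinning = _compute(
        traj, sel, edges, max_lag, origin_stride
    )
    out = []
    for s in range(shells.n_shells):
        out.append(
            CorrelationFunction(
                lags=lags_ps,
                values=g[s],
                n_evaluations=n_origins,
                stderr=stderr,
                reference_hydrogen=sel.reference_hydrogen,
                shell_label=str(s + 1),
                cutoff_radius=float(edges[-1]),
                lag_thinning=thinning,
            )
        )
    return out


def correlation_to_table(corr: CorrelationFunction):
    """TSV-ready table (lag_ps, G, n_eval, stderr)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "lag_ps": corr.lags,
            "G_nm6": corr.values,
            "n_eval": corr.n_evaluations,
            "stderr": corr.stderr,
        }
    )
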