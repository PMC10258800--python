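"""Brownian synthetic trajectories around a fixed model solute.

The generator emulates the sampling conditions of the solvated-peptide MD
this package analyses -- a cubic periodic box of HFIP (six fluorine sites
per molecule) and water around a central solute, snapshots every 10 ps --
with force-free translational diffusion at known input coefficients, a
reflecting solute sphere setting the distance of closest approach, and an
optional sticky surface producing rare long-lived contacts. Ground truth
(input D, b, fluorine density, bound intervals) accompanies every
trajectory so downstream estimators can be validated against it.

The model is deliberately minimal: no solvent-solvent interactions, no
HFIP rotation (a rapidly rotating HFIP is treated as an effective sphere),
no hydrodynamics. What this does and does not establish about real MD is
discussed in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .constants import d_si_to_nm2_per_ps
from .trajectory import (
    ROLE_FLUORINE,
    ROLE_PEPTIDE_H,
    ROLE_WATER_O,
    Trajectory,
)

FLUORINES_PER_HFIP = 6
_CHUNK_FRAMES = 512  # fixed so a given seed yields a bit-identical stream


@dataclass(frozen=True)
class StickySpec:
    """Sticky-surface mode: Poisson unbinding at rate ``k_off`` (ns^-1).

    A molecule whose centre enters ``capture_shell`` (nm) binds: its
    diffusion is scaled by ``bound_d_scale`` and it stays confined between
    the solute sphere and the capture shell until the exponential clock
    releases it; it must then leave the shell before it can rebind.
    """

    k_off: float
    capture_shell: float
    bound_d_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.k_off < 0:
            raise ValueError("k_off must be >= 0")
        if self.capture_shell <= 0:
            raise ValueError("capture_shell must be positive")
        if not (0 < self.bound_d_scale <= 1):
            raise ValueError("bound_d_scale must be in (0, 1]")


@dataclass(frozen=True)
class SimulationSpec:
    """Input parameters of a synthetic Brownian system.

    Lengths nm, times ps, diffusion coefficients m^2 s^-1. ``site_offset``
    is the maximum radial offset of the six rigid fluorine sites from the
    HFIP centre (sites are drawn once, uniformly oriented, with radii in
    [site_offset/2, site_offset]); zero puts all six at the centre, which
    makes the system coincide with the centred hard-sphere model.
    """

    box_edge: float = 6.7
    n_hfip: int = 482
    n_water: int = 0
    d_hfip: float = 4.8e-10
    d_water: float = 17e-10
    closest_approach_b: float = 0.3
    snapshot_dt: float = 10.0
    n_frames: int = 1000
    substeps_per_snapshot: int = 10
    seed: int = 0
    site_offset: float = 0.2
    sticky: StickySpec | None = None
    d_profile: tuple[tuple[float, float], ...] | None = None
    """Optional piecewise diffusion scaling: ((r_upper_nm, scale), ...) with
    increasing r_upper; the scale applies below each upper edge, 1 beyond."""

    def __post_init__(self) -> None:
        if self.box_edge <= 2 * self.closest_approach_b:
            raise ValueError("box_edge must exceed twice the solute radius b")
        if self.n_hfip < 0 or self.n_water < 0 or self.n_hfip + self.n_water == 0:
            raise ValueError("need at least one solvent molecule")
        if self.d_hfip < 0 or self.d_water < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.snapshot_dt <= 0:
            raise ValueError("snapshot_dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.substeps_per_snapshot < 1:
            raise ValueError("substeps_per_snapshot must be >= 1")
        if not (0 <= self.site_offset < self.box_edge / 2):
            raise ValueError("site_offset out of range")
        if self.d_profile is not None:
            edges = [e for e, _ in self.d_profile]
            if sorted(edges) != edges:
                raise ValueError("d_profile upper edges must increase")
        self._check_substep_resolution()

    def _check_substep_resolution(self) -> None:
        """Reflection accuracy requires substep RMS displacement < b/2."""
        b = self.closest_approach_b
        if b <= 0:
            return
        dt_sub = self.snapshot_dt / self.substeps_per_snapshot
        species = []
        if self.n_hfip > 0:
            species.append(("d_hfip", self.d_hfip))
        if self.n_water > 0:
            species.append(("d_water", self.d_water))
        for name, d_si in species:
            d = d_si_to_nm2_per_ps(d_si)
            rms = np.sqrt(6 * d * dt_sub)
            if rms > b / 2:
                need = int(np.ceil(self.snapshot_dt * 6 * d / (b / 2) ** 2))
                raise ValueError(
                    f"substep RMS displacement {rms:.3f} nm for {name} exceeds "
                    f"b/2 = {b / 2:.3f} nm; use substeps_per_snapshot >= {need}"
                )

    @property
    def n_fluorines(self) -> int:
        return FLUORINES_PER_HFIP * self.n_hfip

    @property
    def fluorine_density(self) -> float:
        """Fluorine number density N_F, nm^-3."""
        return self.n_fluorines / self.box_edge**3


@dataclass
class GroundTruth:
    """Known inputs of a generated system, for validating estimators."""

    spec: SimulationSpec
    d_hfip: float  # m^2 s^-1, as input
    d_water: float
    closest_approach_b: float  # nm
    fluorine_density: float  # nm^-3
    bound_intervals: pd.DataFrame | None = None
    """Sticky mode only: one row per bound interval with columns
    molecule_id, start_ps, end_ps, duration_ps, censored_start, censored_end."""


def _uniform_outside_sphere(rng, n, half, b):
    """Uniform points in the cubic box (relative frame) with |r| >= b."""
    out = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-half, half, size=(n, 3))
        keep = cand[np.linalg.norm(cand, axis=1) >= b]
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
    return out


def _fluorine_sites(rng, n_hfip, site_offset):
    """Fixed internal geometry: six sites per molecule, isotropic directions,
    radii uniform in [site_offset/2, site_offset]."""
    dirs = rng.standard_normal((n_hfip, FLUORINES_PER_HFIP, 3))
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
    if site_offset == 0:
        return np.zeros((n_hfip, FLUORINES_PER_HFIP, 3))
    radii = rng.uniform(site_offset / 2, site_offset, size=(n_hfip, FLUORINES_PER_HFIP, 1))
    return dirs * radii


def _atom_table(spec: SimulationSpec) -> pd.DataFrame:
    rows = [("HREF", "PEP", 1, ROLE_PEPTIDE_H, 0)]
    for i in range(spec.n_hfip):
        mol_id = 1 + i
        for k in range(FLUORINES_PER_HFIP):
            rows.append((f"F{k + 1}", "HFP", mol_id + 1, ROLE_FLUORINE, mol_id))
    for i in range(spec.n_water):
        mol_id = 1 + spec.n_hfip + i
        rows.append(("OW", "SOL", mol_id + 1, ROLE_WATER_O, mol_id))
    return pd.DataFrame(rows, columns=["name", "resname", "resid", "role", "molecule_id"])


def _generate(spec: SimulationSpec, sticky: bool):
    """Shared driver for free and sticky generation.

    The Gaussian step stream and the auxiliary stream (initial placement,
    site geometry, unbinding uniforms) are independent children of the seed,
    so free mode and degenerate sticky mode (scale 1) share step noise.
    """
    if sticky and spec.sticky is None:
        raise ValueError("sticky mode requested but spec.sticky is None")
    ss = np.random.SeedSequence(spec.seed)
    steps_rng, aux_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    L, b = spec.box_edge, spec.closest_approach_b
    half = L / 2.0
    n_mol = spec.n_hfip + spec.n_water
    dt_sub = spec.snapshot_dt / spec.substeps_per_snapshot
    sig_h = np.sqrt(2 * d_si_to_nm2_per_ps(spec.d_hfip) * dt_sub)
    sig_w = np.sqrt(2 * d_si_to_nm2_per_ps(spec.d_water) * dt_sub)
    sig = np.concatenate(
        [np.full(spec.n_hfip, sig_h), np.full(spec.n_water, sig_w)]
    )[None, :, None]

    u = _uniform_outside_sphere(aux_rng, n_mol, half, b)
    sites = _fluorine_sites(aux_rng, spec.n_hfip, spec.site_offset)

    if spec.d_profile:
        r_edges = np.array([e for e, _ in spec.d_profile], dtype=np.float64)
        d_scales = np.array([s for _, s in spec.d_profile], dtype=np.float64)
    else:
        r_edges = np.empty(0, dtype=np.float64)
        d_scales = np.empty(0, dtype=np.float64)

    if sticky:
        st = spec.sticky
        p_off = 1.0 - np.exp(-st.k_off * 1e-3 * dt_sub)  # ns^-1 -> ps^-1
        state = np.zeros(n_mol, dtype=np.int64)
        bind_start = np.zeros(n_mol, dtype=np.float64)
        r0 = np.linalg.norm(u, axis=1)
        init_bound = r0 <= st.capture_shell
        state[init_bound] = _kernels.STATE_BOUND
        cap_events = max(1024, int(4 * n_mol + spec.n_frames))
        ev_mol = np.empty(cap_events, dtype=np.int64)
        ev_start = np.empty(cap_events, dtype=np.float64)
        ev_end = np.empty(cap_events, dtype=np.float64)
        n_ev = 0

    n_frames = spec.n_frames
    uw = np.empty((n_frames, n_mol, 3), dtype=np.float64)
    uw[0] = u
    frame = 1
    t_sub_base = 0.0
    while frame < n_frames:
        nf = min(_CHUNK_FRAMES, n_frames - frame)
        n_sub = nf * spec.substeps_per_snapshot
        steps = steps_rng.standard_normal((n_sub, n_mol, 3)) * sig
        if sticky:
            unif = aux_rng.random((n_sub, n_mol))
        for i in range(nf):
            lo = i * spec.substeps_per_snapshot
            hi = lo + spec.substeps_per_snapshot
            if sticky:
                # worst case one event per molecule per substep in this call
                need = n_ev + n_mol * spec.substeps_per_snapshot + 1
                if need > len(ev_mol):
                    grow = max(need, 2 * len(ev_mol))
                    ev_mol = np.concatenate([ev_mol, np.empty(grow, np.int64)])
                    ev_start = np.concatenate([ev_start, np.empty(grow, np.float64)])
                    ev_end = np.concatenate([ev_end, np.empty(grow, np.float64)])
                n_ev = _kernels.propagate_sticky(
                    u, steps[lo:hi], unif[lo:hi], state, bind_start,
                    b, L, st.capture_shell, st.bound_d_scale, p_off,
                    t_sub_base + lo * dt_sub, dt_sub,
                    ev_mol, ev_start, ev_end, n_ev,
                )
            else:
                _kernels.propagate_free(u, steps[lo:hi], b, L, r_edges, d_scales)
            uw[frame + i] = u
        t_sub_base += n_sub * dt_sub
        frame += nf

    # assemble per-atom coordinate arrays (reference H fixed at box centre)
    n_atoms = 1 + spec.n_fluorines + spec.n_water
    uw_atoms = np.empty((n_frames, n_atoms, 3), dtype=np.float32)
    uw_atoms[:, 0, :] = 0.0
    if spec.n_hfip:
        centers = uw[:, : spec.n_hfip, :].astype(np.float32)
        sites32 = sites.astype(np.float32)
        for k in range(FLUORINES_PER_HFIP):
            uw_atoms[:, 1 + k : 1 + spec.n_fluorines : FLUORINES_PER_HFIP, :] = (
                centers + sites32[None, :, k, :]
            )
    if spec.n_water:
        uw_atoms[:, 1 + spec.n_fluorines :, :] = uw[:, spec.n_hfip :, :]
    # shift so the solute sits at the box centre, wrap into [0, L)
    uw_atoms += half
    coords = np.mod(uw_atoms, np.float32(L))

    traj = Trajectory(coords, L, spec.snapshot_dt, _atom_table(spec), unwrapped=uw_atoms)
    gt = GroundTruth(
        spec=spec,
        d_hfip=spec.d_hfip,
        d_water=spec.d_water,
        closest_approach_b=b,
        fluorine_density=spec.fluorine_density,
    )
    if sticky:
        frames_rows = []
        t_end = (n_frames - 1) * spec.snapshot_dt
        for i in range(n_ev):
            frames_rows.append((int(ev_mol[i]) + 1, ev_start[i], ev_end[i], False))
        for m in range(n_mol):
            if state[m] == _kernels.STATE_BOUND:
                frames_rows.append((m + 1, bind_start[m], t_end, True))
        df = pd.DataFrame(
            frames_rows, columns=["molecule_id", "start_ps", "end_ps", "censored_end"]
        )
        df["censored_start"] = df["start_ps"] <= 0.0
        df["duration_ps"] = df["end_ps"] - df["start_ps"]
        gt.bound_intervals = df.sort_values(
            ["molecule_id", "start_ps"], kind="stable"
        ).reset_index(drop=True)
    return traj, gt


def generate_free_trajectory(spec: SimulationSpec) -> tuple[Trajectory, GroundTruth]:
    """Free Brownian solvent around the reflecting solute sphere."""
    return _generate(spec, sticky=False)


def generate_sticky_trajectory(spec: SimulationSpec) -> tuple[Trajectory, GroundTruth]:
    """Sticky-surface mode; ``GroundTruth.bound_intervals`` logs true events."""
    if spec.sticky is None:
        raise ValueError("spec.sticky must be set for sticky generation")
    return _generate(spec, sticky=True)


def make_distance_fixture(
    series: Sequence[float],
    dt: float = 10.0,
    species: str = "fluorine",
    box_edge: float = 10.0,
) -> Trajectory:
    """Deterministic fixture: one solvent atom at given distances from the
    reference hydrogen (both on the x axis), one frame per entry."""
    series = np.asarray(series, dtype=np.float64)
    if series.size == 0:
        raise ValueError("distance series must be nonempty")
    if np.any(series < 0):
        raise ValueError("distances must be >= 0")
    if np.any(series >= box_edge / 2):
        raise ValueError("distances must stay below half the box edge")
    n = series.size
    half = box_edge / 2.0
    coords = np.zeros((n, 2, 3), dtype=np.float64)
    coords[:, 0, :] = half
    coords[:, 1, 0] = half + series
    coords[:, 1, 1] = half
    coords[:, 1, 2] = half
    if species == "fluorine":
        solvent = ("F1", "HFP", 2, ROLE_FLUORINE, 1)
    elif species == "water":
        solvent = ("OW", "SOL", 2, ROLE_WATER_O, 1)
    else:
        raise ValueError(f"unknown species {species!r}")
    atoms = pd.DataFrame(
        [("HREF", "PEP", 1, ROLE_PEPTIDE_H, 0), solvent],
        columns=["name", "resname", "resid", "role", "molecule_id"],
    )
    return Trajectory(coords, box_edge, dt, atoms, unwrapped=coords.copy())
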