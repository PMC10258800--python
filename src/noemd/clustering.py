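"""HFIP aggregate detection and aggregation statistics.

A pair of HFIP molecules is linked when their minimum interatomic
(minimum-image) distance is at or below a cutoff; aggregates are the
connected components. The emulated fluoroalcohol-water system gives no
first-principles criterion for the cutoff, so it is a first-class
parameter (default 0.35 nm, a typical first RDF-minimum contact distance
for small molecules) and every output records the value used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .trajectory import ROLE_FLUORINE, Trajectory

DEFAULT_CLUSTER_CUTOFF = 0.35  # nm
LIFETIME_OVERLAP = 0.5  # fraction of shared molecules for cluster identity


def _hfip_coordinates(traj: Trajectory, frame: int):
    """(mol_ids, list of per-molecule atom coordinate blocks) for one frame."""
    idx = traj.role_indices(ROLE_FLUORINE)
    if idx.size == 0:
        raise ValueError("no HFIP fluorines in trajectory")
    mols = traj.atoms["molecule_id"].to_numpy()[idx]
    coords = traj.coords[frame, idx, :].astype(np.float64)
    uniq = np.unique(mols)
    blocks = [coords[mols == m] for m in uniq]
    return uniq, blocks


def find_clusters(
    traj_or_blocks,
    frame: int | None = None,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    box_edge: float | None = None,
) -> np.ndarray:
    """Cluster labels for HFIP molecules in one frame.

    Accepts either (Trajectory, frame) or a list of per-molecule atom
    coordinate blocks plus ``box_edge``. The label of every molecule in a
    connected component is the smallest molecule *position* (0-based) in
    that component, so labels are deterministic and canonical under
    re-ordering of the distance checks.
    """
    if isinstance(traj_or_blocks, Trajectory):
        if frame is None:
            raise ValueError("frame index required with a Trajectory input")
        box_edge = traj_or_blocks.box_edge
        _, blocks = _hfip_coordinates(traj_or_blocks, frame)
    else:
        blocks = [np.asarray(b, dtype=np.float64) for b in traj_or_blocks]
        if box_edge is None:
            raise ValueError("box_edge required with raw coordinate blocks")
    if cutoff >= box_edge / 2:
        raise ValueError("cluster cutoff must stay below half the box edge")
    n = len(blocks)
    if n == 0:
        raise ValueError("need at least one molecule")
    centers = np.array([b.mean(axis=0) for b in blocks])
    spans = np.array([np.linalg.norm(b - c, axis=1).max() for b, c in zip(blocks, centers)])
    dc = centers[:, None, :] - centers[None, :, :]
    dc -= box_edge * np.round(dc / box_edge)
    center_dist = np.sqrt((dc**2).sum(axis=2))
    reach = spans[:, None] + spans[None, :] + cutoff
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if center_dist[i, j] > reach[i, j]:
                continue
            d = blocks[i][:, None, :] - blocks[j][None, :, :]
            d -= box_edge * np.round(d / box_edge)
            if (d**2).sum(axis=2).min() <= cutoff**2:
                rows.append(i)
                cols.append(j)
    graph = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    _, comp = connected_components(graph, directed=False)
    # canonical label: smallest member position per component
    first = {}
    labels = np.empty(n, dtype=np.int64)
    for i, c in enumerate(comp):
        if c not in first:
            first[c] = i
        labels[i] = first[c]
    return labels


@dataclass
class ClusterStats:
    """Time-averaged aggregation summary."""

    fraction_aggregated: float  # share of HFIP in clusters of size >= 2
    max_size: int
    size_histogram: pd.DataFrame  # columns size, frames_observed
    mean_lifetime_frames: float
    cutoff: float
    n_frames: int
    n_molecules: int

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_aggregated <= 1:
            raise ValueError("fraction out of [0, 1]")
        if self.max_size > self.n_molecules:
            raise ValueError("cluster larger than the system")


def aggregation_stats(
    traj: Trajectory,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    stride: int = 1,
) -> ClusterStats:
    """Per-frame clustering, time-averaged.

    Cluster lifetimes chain components across consecutive analysed frames
    when they share at least half of the larger component's molecules
    (aggregates of size >= 2 only) -- a robust reading of clusters that
    continually form and re-form.
    """
    frames = range(0, traj.n_frames, stride)
    if len(frames) == 0:
        raise ValueError("stride leaves no frames")
    frac, sizes_all = [], {}
    max_size = 0
    prev: list[set] | None = None
    lifetimes: list[int] = []
    open_runs: list[tuple[set, int]] = []
    n_mol = 0
    for f in frames:
        labels = find_clusters(traj, f, cutoff=cutoff)
        n_mol = labels.size
        comps: dict[int, set] = {}
        for i, lab in enumerate(labels):
            comps.setdefault(int(lab), set()).add(i)
        clusters = [c for c in comps.values() if len(c) >= 2]
        agg = sum(len(c) for c in clusters)
        frac.append(agg / n_mol)
        for c in clusters:
            sizes_all[len(c)] = sizes_all.get(len(c), 0) + 1
            max_size = max(max_size, len(c))
        # lifetime chaining
        new_runs: list[tuple[set, int]] = []
        used = [False] * len(clusters)
        for members, length in open_runs:
            matched = False
            for k, c in enumerate(clusters):
                if used[k]:
                    continue
                if len(members & c) >= LIFETIME_OVERLAP * max(len(members), len(c)):
                    new_runs.append((c, length + 1))
                    used[k] = True
                    matched = True
                    break
            if not matched:
                lifetimes.append(length)
        for k, c in enumerate(clusters):
            if not used[k]:
                new_runs.append((c, 1))
        open_runs = new_runs
        prev = clusters
    lifetimes.extend(length for _, length in open_runs)
    hist = pd.DataFrame(
        sorted(sizes_all.items()), columns=["size", "frames_observed"]
    )
    return ClusterStats(
        fraction_aggregated=float(np.mean(frac)),
        max_size=max_size,
        size_histogram=hist,
        mean_lifetime_frames=float(np.mean(lifetimes)) if lifetimes else 0.0,
        cutoff=cutoff,
        n_frames=len(frames),
        n_molecules=n_mol,
    )
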