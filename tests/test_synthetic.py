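"""Synthetic Brownian generator: dynamics, boundaries, ground truth."""

import numpy as np
import pytest
from scipy import stats

from noemd import (
    SimulationSpec,
    StickySpec,
    einstein_diffusion,
    generate_free_trajectory,
    generate_sticky_trajectory,
)
from noemd.constants import d_si_to_nm2_per_ps


def test_zero_diffusion_is_a_fixed_point():
    spec = SimulationSpec(
        box_edge=4.0, n_hfip=5, n_water=3, d_hfip=0.0, d_water=0.0,
        closest_approach_b=0.3, n_frames=6, seed=1,
    )
    traj, _ = generate_free_trajectory(spec)
    assert np.array_equal(traj.coords[0], traj.coords[-1])


def test_reflecting_boundary_keeps_sites_outside_solute():
    spec = SimulationSpec(
        box_edge=4.0, n_hfip=20, n_water=0, d_hfip=4.8e-10,
        closest_approach_b=1.0, n_frames=300, seed=2, site_offset=0.2,
    )
    traj, _ = generate_free_trajectory(spec)
    d = traj.coords[:, 1:, :] - traj.coords[:, :1, :]
    d -= spec.box_edge * np.round(d / spec.box_edge)
    r = np.sqrt((d.astype(np.float64) ** 2).sum(axis=2))
    # fluorine sites may sit up to site_offset inside the centre-exclusion zone
    assert r.min() >= spec.closest_approach_b - spec.site_offset - 1e-6


def test_substep_resolution_guard_names_required_substeps():
    with pytest.raises(ValueError, match="substeps_per_snapshot >="):
        SimulationSpec(
            box_edge=4.0, n_hfip=1, n_water=0, d_hfip=17e-10,
            closest_approach_b=0.1, n_frames=10, substeps_per_snapshot=1,
        )


def test_identical_seed_gives_bit_identical_trajectories():
    spec = SimulationSpec(
        box_edge=4.0, n_hfip=10, n_water=10, closest_approach_b=0.4,
        n_frames=50, seed=7,
    )
    a, _ = generate_free_trajectory(spec)
    b, _ = generate_free_trajectory(spec)
    assert np.array_equal(a.coords, b.coords)
    assert np.array_equal(a.unwrapped, b.unwrapped)


def test_snapshot_displacements_are_gaussian():
    """Per-snapshot displacements: Gaussian, variance 2 D dt per dimension."""
    d_si = 4.8e-10
    spec = SimulationSpec(
        box_edge=50.0, n_hfip=0, n_water=200, d_water=d_si,
        closest_approach_b=0.2, snapshot_dt=10.0, n_frames=251, seed=11,
    )
    traj, _ = generate_free_trajectory(spec)
    steps = np.diff(traj.unwrapped[:, 1:, :].astype(np.float64), axis=0).ravel()
    assert steps.size >= 1e5
    sigma = np.sqrt(2 * d_si_to_nm2_per_ps(d_si) * 10.0)
    _, p = stats.kstest(steps, "norm", args=(0.0, sigma))
    assert p > 0.01
    assert np.std(steps) == pytest.approx(sigma, rel=0.02)


def test_long_run_radial_density_is_uniform_outside_b():
    """r^3 of free particles is uniform beyond the reflecting sphere."""
    b, edge = 1.0, 5.0
    spec = SimulationSpec(
        box_edge=edge, n_hfip=0, n_water=60, d_water=17e-10,
        closest_approach_b=b, n_frames=2501, seed=13,
        substeps_per_snapshot=40,  # keeps first-order wall bias below noise
    )
    traj, _ = generate_free_trajectory(spec)
    rel = traj.coords[::10, 1:, :] - edge / 2  # thin to decorrelate samples
    rel -= edge * np.round(rel / edge)
    r = np.sqrt((rel.astype(np.float64) ** 2).sum(axis=2)).ravel()
    r_hi = edge / 2  # sphere of this radius fits fully inside the box
    x = r[(r >= b) & (r < r_hi)] ** 3
    counts, _ = np.histogram(x, bins=8, range=(b**3, r_hi**3))
    n = counts.sum()
    expect = n / 8
    sigma = np.sqrt(n * (1 / 8) * (7 / 8))
    assert np.all(np.abs(counts - expect) < 3 * sigma)


def test_ground_truth_records_inputs():
    spec = SimulationSpec(
        box_edge=6.0, n_hfip=100, n_water=0, closest_approach_b=0.3,
        n_frames=2, seed=1,
    )
    _, gt = generate_free_trajectory(spec)
    assert gt.fluorine_density == pytest.approx(600 / 216.0)
    assert gt.closest_approach_b == 0.3


def test_sticky_mode_with_unit_scale_and_fast_unbinding_degenerates_to_free():
    """bound_d_scale=1, k_off -> inf: step noise is shared, so the sticky
    run reproduces the free run except for rare boundary-substep events."""
    base = dict(
        box_edge=4.0, n_hfip=40, n_water=0, d_hfip=4.8e-10,
        closest_approach_b=0.3, n_frames=300, seed=21, site_offset=0.0,
    )
    free, _ = generate_free_trajectory(SimulationSpec(**base))
    sticky, _ = generate_sticky_trajectory(
        SimulationSpec(**base, sticky=StickySpec(k_off=1e9, capture_shell=0.8,
                                                 bound_d_scale=1.0))
    )
    same = np.isclose(free.coords, sticky.coords, atol=1e-6).mean()
    assert same > 0.999
    d_free = einstein_diffusion(free, "hfip").d
    d_sticky = einstein_diffusion(sticky, "hfip").d
    assert d_sticky == pytest.approx(d_free, rel=0.01)


def test_sticky_bound_durations_are_exponential_with_mean_1_over_koff():
    """k_off = 0.5 ns^-1 -> 2 ns mean bound duration (censoring-corrected
    exponential MLE over several hundred events)."""
    k_off = 0.5
    spec = SimulationSpec(
        box_edge=5.0, n_hfip=150, n_water=0, d_hfip=4.8e-10,
        closest_approach_b=0.3, n_frames=3000, seed=23, site_offset=0.0,
        sticky=StickySpec(k_off=k_off, capture_shell=0.8, bound_d_scale=0.2),
    )
    _, gt = generate_sticky_trajectory(spec)
    ev = gt.bound_intervals
    n_unbind = int((~ev["censored_end"]).sum())
    assert n_unbind >= 200
    mle_ns = ev["duration_ps"].sum() * 1e-3 / n_unbind
    assert mle_ns == pytest.approx(1.0 / k_off, rel=0.15)


def test_sticky_requires_sticky_spec():
    spec = SimulationSpec(box_edge=4.0, n_hfip=2, n_water=0,
                          closest_approach_b=0.3, n_frames=3)
    with pytest.raises(ValueError, match="sticky"):
        generate_sticky_trajectory(spec)


def test_spec_invariants_rejected():
    with pytest.raises(ValueError):
        SimulationSpec(box_edge=0.5, n_hfip=1, closest_approach_b=0.3, n_frames=5)
    with pytest.raises(ValueError):
        SimulationSpec(box_edge=4.0, n_hfip=1, closest_approach_b=0.3, n_frames=1)
    with pytest.raises(ValueError):
        StickySpec(k_off=0.1, capture_shell=1.0, bound_d_scale=1.5)
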