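"""Dipolar correlation functions: fixtures, shell additivity, theory match."""

import numpy as np
import pandas as pd
import pytest

from noemd import (
    HardSphereParams,
    SelectionSpec,
    ShellDefinition,
    SimulationSpec,
    Trajectory,
    compute_dipolar_correlation,
    generate_free_trajectory,
    hard_sphere_correlation,
    make_distance_fixture,
    shell_resolved_correlation,
)
from noemd.trajectory import ROLE_FLUORINE, ROLE_PEPTIDE_H

REF = "1PepHREF"


def _orbit_fixture(radius=0.5, quarter_frames=10, n_frames=81, dt=10.0, edge=10.0):
    """One fluorine orbiting the reference H at fixed radius; the H-F angle
    advances 90 degrees every ``quarter_frames`` frames."""
    half = edge / 2
    coords = np.full((n_frames, 2, 3), half)
    phi = 0.5 * np.pi * np.arange(n_frames) / quarter_frames
    coords[:, 1, 0] = half + radius * np.cos(phi)
    coords[:, 1, 1] = half + radius * np.sin(phi)
    atoms = pd.DataFrame(
        {
            "name": ["HREF", "F1"],
            "resname": ["PEP", "HFP"],
            "resid": [1, 2],
            "role": [ROLE_PEPTIDE_H, ROLE_FLUORINE],
            "molecule_id": [0, 1],
        }
    )
    return Trajectory(coords, edge, dt, atoms, unwrapped=coords.copy())


def test_static_fluorine_gives_flat_g_equal_inverse_r6():
    fx = make_distance_fixture([0.5] * 40)
    corr = compute_dipolar_correlation(fx, SelectionSpec(REF), max_lag=200.0)
    assert np.allclose(corr.values, 1 / 0.5**6, rtol=1e-6)
    assert corr.g0 == pytest.approx(64.0, rel=1e-6)


def test_orthogonal_orbit_gives_minus_half_p2():
    fx = _orbit_fixture(radius=0.5, quarter_frames=10)
    corr = compute_dipolar_correlation(fx, SelectionSpec(REF), max_lag=100.0)
    # at lag = quarter period the H->F vectors are orthogonal: P2(0) = -1/2
    lag_idx = 10
    assert corr.values[lag_idx] == pytest.approx(64.0 * (-0.5), rel=1e-5)
    assert corr.values[0] == pytest.approx(64.0, rel=1e-6)


def test_g0_identity_with_direct_inverse_r6_average(small_free_system, ref_selection):
    _, traj, _ = small_free_system
    sel = SelectionSpec(REF, cutoff_radius=1.5)
    corr = compute_dipolar_correlation(traj, sel, max_lag=100.0)
    # direct time-average of sum 1/r^6 over the same origins
    ih = traj.atom_index(REF)
    idx = traj.role_indices(ROLE_FLUORINE)
    d = traj.coords[:, idx, :] - traj.coords[:, ih, None, :]
    d -= traj.box_edge * np.round(d / traj.box_edge)
    r2 = (d.astype(np.float64) ** 2).sum(axis=2)
    inside = r2 <= sel.cutoff_radius**2
    direct = (np.where(inside, 1.0 / r2**3, 0.0).sum(axis=1))[: corr.n_evaluations[0]]
    assert corr.g0 == pytest.approx(direct.mean(), rel=1e-4)


def test_shell_decomposition_sums_to_total_exactly(small_free_system):
    _, traj, _ = small_free_system
    shells = ShellDefinition(width=0.556, n_shells=3)
    per_shell = shell_resolved_correlation(traj, SelectionSpec(REF), shells, max_lag=150.0)
    total = compute_dipolar_correlation(
        traj, SelectionSpec(REF, cutoff_radius=shells.outer_radius), max_lag=150.0
    )
    summed = np.sum([c.values for c in per_shell], axis=0)
    assert np.allclose(summed, total.values, rtol=1e-12, atol=1e-12)


def test_single_shell_equals_plain_correlation(small_free_system):
    _, traj, _ = small_free_system
    shells = ShellDefinition(width=1.5, n_shells=1)
    (one,) = shell_resolved_correlation(traj, SelectionSpec(REF), shells, max_lag=100.0)
    plain = compute_dipolar_correlation(
        traj, SelectionSpec(REF, cutoff_radius=1.5), max_lag=100.0
    )
    assert np.array_equal(one.values, plain.values)


def test_inner_shell_dominates_g0_as_volume_integral_predicts():
    """G(0) per shell tracks the analytic 4 pi Int r^-4 dr over shell bounds."""
    spec = SimulationSpec(
        box_edge=5.0, n_hfip=300, n_water=0, d_hfip=21.8e-10,
        closest_approach_b=0.3, n_frames=4000, seed=31, site_offset=0.0,
    )
    traj, gt = generate_free_trajectory(spec)
    shells = ShellDefinition(width=0.556, n_shells=3)
    per_shell = shell_resolved_correlation(traj, SelectionSpec(REF), shells, max_lag=50.0)
    g0 = np.array([c.g0 for c in per_shell])

    def shell_integral(lo, hi):
        lo = max(lo, spec.closest_approach_b)
        return 4 * np.pi * gt.fluorine_density * (lo**-3 - hi**-3) / 3

    edges = shells.edges
    expect = np.array([shell_integral(edges[k], edges[k + 1]) for k in range(3)])
    assert g0[0] > 10 * g0[2]
    np.testing.assert_allclose(g0, expect, rtol=0.25)


def test_free_diffusion_g_matches_propagator_quadrature():
    """Simulated G(t) tracks the reflecting-boundary propagator quadrature
    within 10% for t <= 3 tau_b (5 independent seeds, pooled)."""
    b, d_si = 0.4, 10e-10
    tau_b = b * b / (d_si * 1e6)
    sims = []
    for seed in range(5):
        spec = SimulationSpec(
            box_edge=5.0, n_hfip=150, n_water=0, d_hfip=d_si,
            closest_approach_b=b, n_frames=4000, seed=100 + seed, site_offset=0.0,
        )
        traj, gt = generate_free_trajectory(spec)
        corr = compute_dipolar_correlation(
            traj, SelectionSpec(REF, cutoff_radius=2.4), float(3 * tau_b)
        )
        sims.append(corr.values)
    mean_g = np.mean(sims, axis=0)
    p = HardSphereParams(b, d_si, gt.fluorine_density)
    theory = hard_sphere_correlation(p, corr.lags, origin_cutoff=2.4)
    np.testing.assert_allclose(mean_g, theory, rtol=0.10)


def test_free_diffusion_g_statistically_monotone(small_free_system):
    _, traj, _ = small_free_system
    corr = compute_dipolar_correlation(traj, SelectionSpec(REF, cutoff_radius=1.8), 400.0)
    rises = np.diff(corr.values) - 3 * np.sqrt(2) * corr.stderr[1:]
    assert np.all(rises < 0)


def test_g_linear_in_fluorine_density():
    base = dict(box_edge=5.0, n_water=0, d_hfip=21.8e-10, closest_approach_b=0.4,
                n_frames=2500, site_offset=0.0)
    g0s = []
    for n, seed in ((60, 51), (120, 52)):
        traj, _ = generate_free_trajectory(SimulationSpec(n_hfip=n, seed=seed, **base))
        corr = compute_dipolar_correlation(traj, SelectionSpec(REF, cutoff_radius=2.0), 100.0)
        g0s.append(corr.g0)
    assert g0s[1] / g0s[0] == pytest.approx(2.0, rel=0.2)


def test_error_paths(small_free_system):
    _, traj, _ = small_free_system
    with pytest.raises(ValueError, match="max_lag"):
        compute_dipolar_correlation(traj, SelectionSpec(REF), max_lag=1e6)
    fx = make_distance_fixture([5.0] * 50, box_edge=12.0)
    with pytest.raises(ValueError, match="cutoff"):
        compute_dipolar_correlation(fx, SelectionSpec(REF, cutoff_radius=3.0), 100.0)
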