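"""Shell occupancies and contact persistence."""

import numpy as np
import pandas as pd
import pytest

from noemd import (
    SelectionSpec,
    ShellDefinition,
    SimulationSpec,
    Trajectory,
    composition_summary,
    contact_events,
    contact_stats,
    generate_free_trajectory,
    make_distance_fixture,
    shell_average_table,
    shell_occupancy_series,
)
from noemd.solvation import ContactEvent
from noemd.trajectory import ROLE_FLUORINE, ROLE_PEPTIDE_H, ROLE_WATER_O

REF = "1PepHREF"


def _fixture_traj(f_dists, w_dists, edge=8.0, n_frames=4):
    """Static fixture with fluorines and water oxygens at given distances."""
    n_atoms = 1 + len(f_dists) + len(w_dists)
    half = edge / 2
    coords = np.full((n_frames, n_atoms, 3), half)
    rows = [("HREF", "PEP", 1, ROLE_PEPTIDE_H, 0)]
    for i, d in enumerate(f_dists):
        coords[:, 1 + i, 0] = half + d
        rows.append((f"F{i+1}", "HFP", 2, ROLE_FLUORINE, 1))
    for i, d in enumerate(w_dists):
        coords[:, 1 + len(f_dists) + i, 1] = half + d
        rows.append(("OW", "SOL", 3 + i, ROLE_WATER_O, 2 + i))
    atoms = pd.DataFrame(rows, columns=["name", "resname", "resid", "role", "molecule_id"])
    return Trajectory(coords, edge, 10.0, atoms)


def test_composition_arithmetic_matches_box_composition():
    c = composition_summary(482, 7434)
    assert round(c["water_to_fluorine_ratio"], 2) == 2.57
    assert round(c["hfip_mole_fraction"], 3) == 0.061


def test_constructed_binning():
    traj = _fixture_traj([0.3, 0.3, 0.3], [0.8, 0.8])
    occ = shell_occupancy_series(traj, SelectionSpec(REF), ShellDefinition(0.556, 3))
    mean = occ.mean_counts()
    assert mean.loc["shell1", "F"] == 3 and mean.loc["shell1", "Ow"] == 0
    assert mean.loc["shell2", "Ow"] == 2 and mean.loc["shell2", "F"] == 0
    assert mean.loc["shell3", "F"] == 0 and mean.loc["shell3", "Ow"] == 0


def test_shell_partition_conserves_total_count(small_free_system):
    _, traj, _ = small_free_system
    shells = ShellDefinition(0.4, 4)
    occ = shell_occupancy_series(traj, SelectionSpec(REF), shells)
    ih = traj.atom_index(REF)
    for role, col in ((ROLE_FLUORINE, 0), (ROLE_WATER_O, 1)):
        idx = traj.role_indices(role)
        d = traj.coords[:, idx, :] - traj.coords[:, ih, None, :]
        d -= traj.box_edge * np.round(d / traj.box_edge)
        r = np.sqrt((d.astype(np.float64) ** 2).sum(axis=2))
        within = (r < shells.outer_radius).sum(axis=1)
        assert np.array_equal(occ.counts[:, :, col].sum(axis=1), within)


def test_shells_beyond_half_box_rejected(small_free_system):
    _, traj, _ = small_free_system
    with pytest.raises(ValueError, match="half the box"):
        shell_occupancy_series(traj, SelectionSpec(REF), ShellDefinition(0.556, 5))


def test_average_table_arithmetic():
    traj = _fixture_traj([0.3, 0.3, 0.3], [0.3, 0.3])
    occ = shell_occupancy_series(traj, SelectionSpec(REF), ShellDefinition(0.556, 2))
    table = shell_average_table([occ])
    row = table[(table.shell == 1)].iloc[0]
    assert row.F_mean == 3.0 and row.Ow_mean == 2.0 and row.F_mean_dev == 0.0
    assert row.water_to_F_ratio == pytest.approx(2 / 3)
    assert row.enrichment == "hfip"


def test_average_table_replicate_mean_deviation():
    t1 = _fixture_traj([0.3] * 6, [])
    t2 = _fixture_traj([0.3] * 8, [])
    occs = [
        shell_occupancy_series(t, SelectionSpec(REF), ShellDefinition(0.556, 2))
        for t in (t1, t2)
    ]
    row = shell_average_table(occs).query("shell == 1").iloc[0]
    assert row.F_mean == 7.0 and row.F_mean_dev == 1.0


def test_uniform_system_shell_ratio_matches_bulk_and_unenriched():
    """With no preferential interactions every shell's water:F ratio sits at
    the box-wide ratio (within counting noise)."""
    spec = SimulationSpec(
        box_edge=6.0, n_hfip=80, n_water=160, d_hfip=21.8e-10, d_water=21.8e-10,
        closest_approach_b=0.2, n_frames=1500, seed=61, site_offset=0.0,
        substeps_per_snapshot=20,
    )
    traj, _ = generate_free_trajectory(spec)
    shells = ShellDefinition(0.556, 5)
    occ = shell_occupancy_series(traj, SelectionSpec(REF), shells)
    bulk = 160 / (80 * 6)
    ratio5 = occ.water_to_fluorine_ratio(shell=5)
    # 3 sigma of the per-frame count noise, propagated to the mean ratio
    f5 = occ.counts[:, 4, 0]
    n_eff = len(f5) / 20  # decorrelation stride for 10 ps snapshots
    se = bulk * np.sqrt(1 / f5.mean() + 1 / occ.counts[:, 4, 1].mean()) / np.sqrt(n_eff)
    assert abs(ratio5 - bulk) < 3 * se
    table = shell_average_table([occ], bulk_ratio=2.57)
    # uniform mixture at bulk ratio 1/3 is HFIP-rich by the 2.57 standard
    assert set(table.enrichment) == {"hfip"}


def test_contact_run_length_definition():
    fx = make_distance_fixture([0.45, 0.45, 0.55, 0.45])
    ev = contact_events(fx, SelectionSpec(REF))
    durations = [e.duration_ps for e in ev]
    assert durations == [20.0, 10.0]
    assert ev[0].censored_start and not ev[0].censored_end
    assert ev[1].censored_end


def test_all_frames_contact_is_fully_censored():
    fx = make_distance_fixture([0.3] * 100)
    ev = contact_events(fx, SelectionSpec(REF))
    assert len(ev) == 1
    assert ev[0].duration_ps == 1000.0
    assert ev[0].censored_start and ev[0].censored_end


def test_water_uses_its_own_cutoff():
    fx = make_distance_fixture([0.45, 0.45], species="water")
    assert contact_events(fx, SelectionSpec(REF)) == []
    fx2 = make_distance_fixture([0.35, 0.35], species="water")
    assert len(contact_events(fx2, SelectionSpec(REF))) == 1


def test_unknown_species_cutoff_rejected(small_free_system):
    _, traj, _ = small_free_system
    with pytest.raises(ValueError, match="unknown species"):
        contact_events(traj, SelectionSpec(REF), cutoffs={"argon": 0.5})


def test_contact_stats_arithmetic():
    events = [
        ContactEvent(1, "fluorine", 10 * i, 1, d, False, False)
        for i, d in enumerate([10.0] * 8 + [70.0, 90.0])
    ]
    st = contact_stats(events, trajectory_length_ns=2.0, threshold_ps=60.0)
    assert st.contacts_per_ns == pytest.approx(5.0)
    assert st.percent_longer_than_threshold == pytest.approx(20.0)
    assert st.mean_long_duration_ps == pytest.approx(80.0)


def test_contact_stats_no_events_flagged():
    st = contact_stats([], 1.0)
    assert st.no_events and st.contacts_per_ns == 0.0
    with pytest.raises(ValueError):
        contact_stats([], 0.0)


def test_contact_events_deterministic_under_rereading(tmp_path, small_free_system):
    _, traj, _ = small_free_system
    p = tmp_path / "t.noemd"
    traj.write_internal(p)
    reread = Trajectory.read_internal(p)
    a = contact_events(traj, SelectionSpec(REF))
    b = contact_events(reread, SelectionSpec(REF))
    assert a == b


def test_occupancy_and_contact_rate_scale_linearly_with_density():
    """Across densities, mean shell-1 occupancy and contact rate correlate
    nearly perfectly (both are linear in solvent density)."""
    occs, rates = [], []
    for i, n in enumerate((20, 40, 60, 80, 100)):
        spec = SimulationSpec(
            box_edge=5.0, n_hfip=n, n_water=0, d_hfip=21.8e-10,
            closest_approach_b=0.25, n_frames=1200, seed=70 + i, site_offset=0.0,
        )
        traj, _ = generate_free_trajectory(spec)
        occ = shell_occupancy_series(traj, SelectionSpec(REF), ShellDefinition(0.556, 2))
        occs.append(occ.counts[:, 0, 0].mean())
        ev = [e for e in contact_events(traj, SelectionSpec(REF)) if e.species == "fluorine"]
        rates.append(len(ev) / ((traj.n_frames - 1) * traj.dt * 1e-3))
    r = np.corrcoef(occs, rates)[0, 1]
    assert r > 0.95
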