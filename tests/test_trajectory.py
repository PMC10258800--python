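"""Trajectory container, periodic distances and format round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from noemd import (
    SimulationSpec,
    Trajectory,
    distance_series,
    generate_free_trajectory,
    make_distance_fixture,
    min_image_distance,
)
from noemd.trajectory import (
    ROLE_FLUORINE,
    ROLE_OTHER,
    ROLE_PEPTIDE_H,
    ROLE_WATER_O,
    assign_roles,
    min_image_vector,
    parse_atom_label,
    read_trajectory,
)


def _two_atom_traj(pos_a, pos_b, edge=6.7):
    coords = np.array([[pos_a, pos_b]], dtype=np.float64)
    atoms = pd.DataFrame(
        {
            "name": ["HE1", "F1"],
            "resname": ["Trp", "HFP"],
            "resid": [6, 7],
            "role": [ROLE_PEPTIDE_H, ROLE_FLUORINE],
            "molecule_id": [0, 1],
        }
    )
    return Trajectory(coords, edge, 10.0, atoms)


def test_min_image_wraps_across_the_boundary():
    traj = _two_atom_traj([0.1, 0.0, 0.0], [6.6, 0.0, 0.0], edge=6.7)
    assert min_image_distance(traj, 0, 0, 1) == pytest.approx(0.2, abs=1e-12)
    assert min_image_distance(traj, 0, 0, 0) == 0.0


def test_min_image_matches_27_image_enumeration():
    rng = np.random.default_rng(5)
    edge = 5.0
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    ) * edge
    for _ in range(200):
        a, b = rng.uniform(0, edge, size=(2, 3))
        brute = np.min(np.linalg.norm(b + shifts - a, axis=1))
        fast = np.linalg.norm(min_image_vector(b - a, edge))
        assert fast == pytest.approx(brute, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 5.0), min_size=9, max_size=9))
def test_min_image_symmetry_and_triangle_inequality(flat):
    edge = 5.0
    a, b, c = (np.array(flat[i : i + 3]) for i in (0, 3, 6))
    d = lambda u, v: np.linalg.norm(min_image_vector(v - u, edge))
    assert d(a, b) == pytest.approx(d(b, a), abs=1e-12)
    assert d(a, c) <= d(a, b) + d(b, c) + 1e-12


def test_distance_series_reports_mean_and_range():
    fx = make_distance_fixture([0.44] * 10)
    ds = distance_series(fx, "1PepHREF", "2HfpF1")
    assert ds.mean == pytest.approx(0.44, abs=1e-9)

    fx2 = make_distance_fixture([0.22, 1.10])
    ds2 = distance_series(fx2, "1PepHREF", "2HfpF1")
    assert ds2.range == (pytest.approx(0.22, abs=1e-9), pytest.approx(1.10, abs=1e-9))

    same = distance_series(fx, "1PepHREF", "1PepHREF")
    assert np.all(same.values == 0.0)


def test_distance_fixture_input_validation():
    with pytest.raises(ValueError):
        make_distance_fixture([])
    with pytest.raises(ValueError):
        make_distance_fixture([0.4, -0.1])


def test_atom_label_parsing():
    assert parse_atom_label("6TrpHE1") == (6, "Trp", "HE1")
    assert parse_atom_label("17ProHA") == (17, "Pro", "HA")
    with pytest.raises(ValueError):
        parse_atom_label("nonsense")


def test_role_assignment_rules():
    atoms = pd.DataFrame(
        {
            "name": ["F3", "OW", "HA", "CA", "O"],
            "resname": ["HFP", "SOL", "TRP", "TRP", "SOL"],
            "resid": [2, 3, 6, 6, 4],
        }
    )
    out = assign_roles(atoms)
    assert list(out["role"]) == [
        ROLE_FLUORINE,
        ROLE_WATER_O,
        ROLE_PEPTIDE_H,
        ROLE_OTHER,
        ROLE_WATER_O,
    ]


def test_internal_format_round_trips_bit_identically(tmp_path, small_free_system):
    _, traj, _ = small_free_system
    p = tmp_path / "traj.noemd"
    traj.write_internal(p)
    back = Trajectory.read_internal(p)
    assert np.array_equal(back.coords, traj.coords)
    assert np.array_equal(back.unwrapped, traj.unwrapped)
    assert back.dt == traj.dt and back.box_edge == traj.box_edge
    assert list(back.atoms["role"]) == list(traj.atoms["role"])
    # writing again is idempotent byte-for-byte
    p2 = tmp_path / "traj2.noemd"
    back.write_internal(p2)
    assert p.read_bytes() == p2.read_bytes()


def test_read_trajectory_dispatches_to_internal_format(tmp_path):
    fx = make_distance_fixture([0.3, 0.4])
    p = tmp_path / "fx.noemd"
    fx.write_internal(p)
    back = read_trajectory(p)
    assert back.n_frames == 2


def test_gro_reading_assigns_water_role(tmp_path):
    gro = tmp_path / "one_water.gro"
    gro.write_text(
        "single water\n"
        "    3\n"
        "    1SOL     OW    1   1.000   1.000   1.000\n"
        "    1SOL    HW1    2   1.080   1.000   1.000\n"
        "    1SOL    HW2    3   1.000   1.080   1.000\n"
        "   3.00000   3.00000   3.00000\n"
    )
    traj = read_trajectory(gro, dt=10.0)
    roles = list(traj.atoms["role"])
    assert roles[0] == ROLE_WATER_O
    assert roles.count(ROLE_WATER_O) == 1
    assert traj.box_edge == pytest.approx(3.0)
    assert traj.coords[0, 0, 0] == pytest.approx(1.0)


def test_atom_count_mismatch_rejected(small_free_system):
    _, traj, _ = small_free_system
    with pytest.raises(ValueError, match="atom table"):
        Trajectory(traj.coords[:, :-1, :], traj.box_edge, traj.dt, traj.atoms)


def test_unwrap_reconstructs_continuous_paths():
    spec = SimulationSpec(
        box_edge=3.0,
        n_hfip=0,
        n_water=20,
        d_water=17e-10,
        closest_approach_b=0.3,
        n_frames=300,
        seed=9,
    )
    traj, _ = generate_free_trajectory(spec)
    stored = traj.unwrapped
    traj.unwrapped = None
    rebuilt = traj.unwrap()
    # same continuous paths up to a constant image offset per atom
    diff = rebuilt - stored
    assert np.allclose(diff - diff[0:1], 0.0, atol=2e-4)
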