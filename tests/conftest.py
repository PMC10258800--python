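import numpy as np
import pytest

from noemd import SelectionSpec, SimulationSpec, generate_free_trajectory

REF_H = "1PepHREF"


@pytest.fixture(scope="session")
def small_free_system():
    """Small mixed HFIP/water free-diffusion system reused across tests."""
    spec = SimulationSpec(
        box_edge=4.0,
        n_hfip=30,
        n_water=40,
        d_hfip=4.8e-10,
        d_water=17e-10,
        closest_approach_b=0.4,
        snapshot_dt=10.0,
        n_frames=400,
        seed=42,
    )
    traj, gt = generate_free_trajectory(spec)
    return spec, traj, gt


@pytest.fixture()
def ref_selection():
    return SelectionSpec(REF_H)
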