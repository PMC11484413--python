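import numpy as np
import pytest

from vmatqa.plan_model import MachineSpec, default_machine
from vmatqa.synth_data import SimConfig, make_dataset, simulate_regular_plan


@pytest.fixture(scope="session")
def machine():
    return default_machine()


@pytest.fixture(scope="session")
def small_machine():
    """4 pairs of 10 mm leaves; min_gap 0 so hand examples stay simple."""
    return MachineSpec(
        n_leaf_pairs=4,
        leaf_widths=(10.0,) * 4,
        field_width=40.0,
        field_height=60.0,
        max_leaf_speed=5.0,
        min_gap=0.0,
    )


@pytest.fixture(scope="session")
def coarse_machine():
    """16 pairs of 25 mm leaves on a 400 mm field: rasterizes to 16 x 16 at
    25 mm, the smallest shape the conv models accept."""
    return MachineSpec(
        n_leaf_pairs=16,
        leaf_widths=(25.0,) * 16,
        field_width=400.0,
        field_height=400.0,
        max_leaf_speed=5.0,
        min_gap=5.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_plan(machine):
    cfg = SimConfig(n_regular=1, n_anomalous=0, seed=7, machine=machine)
    return simulate_regular_plan(cfg, np.random.default_rng(7), plan_id="sim0")


@pytest.fixture(scope="session")
def tiny_dataset(coarse_machine):
    """10 regular + 4 anomalous short plans on the coarse machine."""
    cfg = SimConfig(
        n_regular=10,
        n_anomalous=4,
        cps_per_arc=10,
        machine=coarse_machine,
        seed=3,
    )
    return make_dataset(cfg)
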