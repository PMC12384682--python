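import numpy as np
import pytest

from wardtrig.config import SimulationConfig
from wardtrig.dataset import SensorTable
from wardtrig.layout import Room, WardLayout
from wardtrig.simulate import simulate_study


@pytest.fixture(scope="session")
def tiny_layout() -> WardLayout:
    """Five rooms, one per group; exercises 0-, 1- and 2-sensor paths."""
    return WardLayout([
        Room("living_room", "living room", 2),
        Room("dining_room", "dining room", 1),
        Room("hall", "hallway", 1),
        Room("room_a", "patient room", 1),
        Room("quiet_room", "other", 0),
    ])


@pytest.fixture()
def tiny_config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_patients=4, days_per_patient=1)


@pytest.fixture(scope="session")
def small_dataset():
    """One reusable simulated study: 12 patients, 2 days, default ward."""
    cfg = SimulationConfig(seed=42, n_patients=12, days_per_patient=2)
    return simulate_study(cfg)


def constant_sensor_table(room_values: dict[str, dict[str, float]],
                          n: int = 3600, period: int = 1,
                          two_sensor_rooms: tuple[str, ...] = ()) -> SensorTable:
    """Hand-built table with constant per-room values for each modality.

    ``room_values[room][modality] = c``; rooms in ``two_sensor_rooms`` get
    two sensors at c-1 and c+1 (their aligned mean is c).
    """
    values, sensor_room = {}, {}
    for room, mods in room_values.items():
        n_sensors = 2 if room in two_sensor_rooms else 1
        for i in range(n_sensors):
            sid = f"{room}__s{i}"
            sensor_room[sid] = room
            for mod, c in mods.items():
                offset = (-1.0 + 2.0 * i) if n_sensors == 2 else 0.0
                values[(sid, mod)] = np.full(n, c + offset, dtype=np.float32)
    return SensorTable(0, period, n, values, sensor_room)
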