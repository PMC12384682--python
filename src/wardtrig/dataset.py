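"""In-memory containers for one ward study and their CSV serialization.

Timestamps are kept as integer seconds on the ward's local clock, counted
from local midnight of the study's first day; CSVs carry ISO-8601 strings
anchored at a nominal start date.  The sensor streams are synchronized and
regularly sampled, so they are stored as one value array per
(sensor, modality) on a shared grid rather than as a 10^7-row long table;
:meth:`SensorTable.to_frame` materializes the long format when needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .layout import OFF_MAP, Room, WardLayout

MODALITIES = ("light", "sound", "temperature")

#: nominal ward-local start of the study (a Monday, midnight)
EPOCH = np.datetime64("2024-03-04T00:00:00", "s")


def to_datetime(seconds) -> np.ndarray:
    return EPOCH + np.asarray(seconds, dtype="timedelta64[s]")


def from_datetime(ts) -> np.ndarray:
    return (np.asarray(ts, dtype="datetime64[s]") - EPOCH).astype(np.int64)


class SensorTable:
    """Synchronized regular-grid sensor readings for one ward.

    Parameters
    ----------
    start_s, period_s, n :
        Shared sampling grid: readings at ``start_s + k * period_s`` for
        ``k = 0..n-1`` (seconds from study start).
    values :
        ``(sensor_id, modality) -> float array of length n``.
    sensor_room :
        ``sensor_id -> room_id``.
    """

    def __init__(self, start_s: int, period_s: int, n: int,
                 values: dict[tuple[str, str], np.ndarray],
                 sensor_room: dict[str, str]):
        self.start_s = int(start_s)
        self.period_s = int(period_s)
        self.n = int(n)
        self.values = values
        self.sensor_room = sensor_room
        for key, arr in values.items():
            if len(arr) != n:
                raise ValueError(f"stream {key} has length {len(arr)} != {n}")

    @property
    def end_s(self) -> int:
        """One past the last grid point."""
        return self.start_s + self.n * self.period_s

    def grid_slice(self, t0: float, t1: float) -> tuple[int, int]:
        """Index range [i0, i1) of grid points with t0 <= t < t1."""
        i0 = int(np.ceil((t0 - self.start_s) / self.period_s))
        i1 = int(np.ceil((t1 - self.start_s) / self.period_s))
        return max(i0, 0), min(max(i1, 0), self.n)

    def times_s(self, i0: int, i1: int) -> np.ndarray:
        return self.start_s + np.arange(i0, i1, dtype=np.int64) * self.period_s

    def room_streams(self, room_id: str, modality: str) -> list[np.ndarray]:
        """Value arrays of every sensor mounted in a room (layout order)."""
        return [self.values[(s, modality)]
                for s, r in sorted(self.sensor_room.items()) if r == room_id]

    # -- long-format interchange ------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long format: timestamp, sensor_id, room_id, modality, value."""
        parts = []
        ts = to_datetime(self.times_s(0, self.n))
        for (sensor, modality), arr in sorted(self.values.items()):
            parts.append(pd.DataFrame({
                "timestamp": ts,
                "sensor_id": sensor,
                "room_id": self.sensor_room[sensor],
                "modality": modality,
                "value": np.asarray(arr, dtype=np.float64),
            }))
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, period_s: int) -> "SensorTable":
        """Rebuild the grid representation from the long format.

        Readings are snapped to the regular grid implied by ``period_s`` and
        the earliest timestamp; each (sensor, modality) must cover the grid.
        """
        t = from_datetime(df["timestamp"].to_numpy())
        start = int(t.min())
        idx = (t - start) // period_s
        n = int(idx.max()) + 1
        values: dict[tuple[str, str], np.ndarray] = {}
        sensor_room: dict[str, str] = {}
        for (sensor, modality), sub in df.groupby(["sensor_id", "modality"],
                                                  sort=True):
            arr = np.full(n, np.nan, dtype=np.float32)
            si = (from_datetime(sub["timestamp"].to_numpy()) - start) // period_s
            arr[si] = sub["value"].to_numpy(dtype=np.float32)
            values[(str(sensor), str(modality))] = arr
            sensor_room[str(sensor)] = str(sub["room_id"].iloc[0])
        return cls(start, period_s, n, values, sensor_room)


@dataclass
class LocationTrace:
    """Contiguous room-occupancy intervals for one patient.

    ``starts``/``ends`` are seconds from study start, half-open intervals
    ``[start, end)`` with ``ends[k] == starts[k+1]``; ``rooms`` holds room
    ids including the reserved ``off_map``.
    """

    patient_id: str
    starts: np.ndarray
    ends: np.ndarray
    rooms: np.ndarray      # dtype=object / str

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.rooms = np.asarray(self.rooms, dtype=object)
        if not (len(self.starts) == len(self.ends) == len(self.rooms)):
            raise ValueError("ragged trace")
        if len(self.starts) and not np.array_equal(self.ends[:-1], self.starts[1:]):
            raise ValueError("trace intervals must be contiguous")
        if np.any(self.ends <= self.starts):
            raise ValueError("empty or inverted interval in trace")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_id,
            "start": to_datetime(self.starts),
            "end": to_datetime(self.ends),
            "room_id": self.rooms.astype(str),
        })


@dataclass
class StudyDataset:
    """One complete (synthetic or loaded) study."""

    layout: WardLayout
    sensors: SensorTable
    traces: dict[str, LocationTrace]
    surveys: pd.DataFrame      # survey_id, patient_id, t_s, pas_* columns
    config: SimulationConfig | None = None
    #: generator-side internals (true z-features, random intercepts, ...)
    truth: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)

    # -- serialization -----------------------------------------------------
    def write_csvs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sensors.to_frame().to_csv(out / "sensors.csv", index=False)
        pd.concat([t.to_frame() for t in self.traces.values()],
                  ignore_index=True).to_csv(out / "locations.csv", index=False)
        sv = self.surveys.copy()
        sv["timestamp"] = to_datetime(sv.pop("t_s"))
        sv[["patient_id", "timestamp", "pas_motor", "pas_verbal",
            "pas_resist", "pas_aggr"]].to_csv(out / "surveys.csv", index=False)
        truth = {
            "config": None if self.config is None
            else json.loads(self.config.model_dump_json()),
            "layout": [[r.room_id, r.group, r.n_sensors]
                       for r in self.layout.rooms],
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))

    @classmethod
    def read_csvs(cls, in_dir: str | Path,
                  sample_period: int | None = None) -> "StudyDataset":
        src = Path(in_dir)
        truth = json.loads((src / "truth.json").read_text())
        config = (SimulationConfig(**truth["config"])
                  if truth.get("config") else None)
        layout = WardLayout([Room(*r) for r in truth["layout"]])
        period = sample_period or (config.sample_period if config else 1)
        sensors = SensorTable.from_frame(pd.read_csv(src / "sensors.csv"),
                                         period)
        loc = pd.read_csv(src / "locations.csv")
        traces = {}
        for pid, sub in loc.groupby("patient_id", sort=True):
            sub = sub.sort_values("start")
            traces[str(pid)] = LocationTrace(
                str(pid), from_datetime(sub["start"].to_numpy()),
                from_datetime(sub["end"].to_numpy()),
                sub["room_id"].to_numpy())
        sv = pd.read_csv(src / "surveys.csv")
        sv["t_s"] = from_datetime(sv.pop("timestamp").to_numpy())
        sv.insert(0, "survey_id",
                  [f"{p}_{i:04d}" for i, p in enumerate(sv["patient_id"])])
        return cls(layout, sensors, traces, sv, config=config)
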