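"""Location-conditioned extraction of pre-survey environmental windows.

For a survey at ward-clock time ``t`` and a window of ``length`` minutes
ending ``buffer`` minutes before it, the analyzed interval is the half-open
``[t - (buffer+length)*60, t - buffer*60)``.  The buffer separates
prediction from detection: an ongoing verbal-agitation episode raises the
sound level at the survey moment itself, so the window must end well before
it.  Extraction conditions on the patient's room: each occupied room
contributes its own sensor readings (averaged across the two enclosures of
large rooms), rooms without sensors and off-map time contribute nothing,
and the concatenated series is smoothed with a short trailing moving
average so room transitions do not introduce artificial steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SMOOTHING_SPAN_S
from .dataset import MODALITIES, LocationTrace, SensorTable, StudyDataset
from .layout import OFF_MAP, WardLayout


class DataIntegrityError(ValueError):
    """A referenced room or sensor is unknown to the layout."""


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry, both offsets measured back from the survey time."""

    length_min: float
    buffer_min: float = 12.0

    def __post_init__(self) -> None:
        if self.buffer_min < 0:
            raise ValueError("buffer must be >= 0")
        if self.length_min <= 0:
            raise ValueError("length must be > 0")

    def interval(self, t_s: float) -> tuple[float, float]:
        """Half-open [w0, w1) in seconds for a survey at ``t_s``."""
        w1 = t_s - self.buffer_min * 60.0
        return w1 - self.length_min * 60.0, w1


@dataclass
class Occupancy:
    """Partition of one window into room segments (off_map included)."""

    rooms: list[str]                 # segment room ids, chronological
    starts: np.ndarray               # segment starts (s), clipped to window
    ends: np.ndarray
    seconds_by_room: dict[str, float]
    majority_room: str
    off_map_fraction: float


def locate_rooms(trace: LocationTrace, w0: float, w1: float) -> Occupancy:
    """Room occupancy of ``[w0, w1)`` from a patient's location trace.

    Time not covered by the trace counts as off-map.  The majority room is
    the room with the most seconds; ties break to the room entered earliest
    within the window (deterministic).
    """
    if w1 <= w0:
        raise ValueError("window must have positive duration")
    rooms: list[str] = []
    segs: list[tuple[float, float]] = []

    def push(room: str, a: float, b: float) -> None:
        if b <= a:
            return
        if rooms and rooms[-1] == room and segs[-1][1] == a:
            segs[-1] = (segs[-1][0], b)      # merge adjacent same-room
        else:
            rooms.append(room)
            segs.append((a, b))

    if len(trace.starts):
        lo = int(np.searchsorted(trace.ends, w0, side="right"))
        hi = int(np.searchsorted(trace.starts, w1, side="left"))
        push(OFF_MAP, w0, min(trace.starts[0], w1) if lo == 0 else w0)
        for k in range(lo, hi):
            push(str(trace.rooms[k]), max(float(trace.starts[k]), w0),
                 min(float(trace.ends[k]), w1))
        if trace.ends[-1] < w1:
            push(OFF_MAP, max(float(trace.ends[-1]), w0), w1)
    else:
        push(OFF_MAP, w0, w1)

    seconds: dict[str, float] = {}
    first_entry: dict[str, float] = {}
    for room, (a, b) in zip(rooms, segs):
        seconds[room] = seconds.get(room, 0.0) + (b - a)
        first_entry.setdefault(room, a)
    majority = min(seconds, key=lambda r: (-seconds[r], first_entry[r]))
    duration = w1 - w0
    off = seconds.get(OFF_MAP, 0.0) / duration
    starts = np.array([s for s, _ in segs], dtype=np.float64)
    ends = np.array([e for _, e in segs], dtype=np.float64)
    assert abs(float(ends.sum() - starts.sum()) - duration) < 1e-6
    return Occupancy(rooms, starts, ends, seconds, majority, off)


def fuse_sensor_series(
    sensors: SensorTable, occupancy: Occupancy, modality: str,
    layout: WardLayout,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate per-segment sensor readings for one modality.

    Returns (times_s, values, source_rooms), chronological.  Dual-enclosure
    rooms contribute the timestamp-aligned mean of their two sensors;
    sensorless rooms and off-map segments contribute no points.
    """
    known = set(layout.room_ids)
    t_parts: list[np.ndarray] = []
    v_parts: list[np.ndarray] = []
    r_parts: list[np.ndarray] = []
    for room, a, b in zip(occupancy.rooms, occupancy.starts, occupancy.ends):
        if room == OFF_MAP:
            continue
        if room not in known:
            raise DataIntegrityError(f"room {room!r} not in layout")
        streams = sensors.room_streams(room, modality)
        if not streams:
            continue
        i0, i1 = sensors.grid_slice(a, b)
        if i1 <= i0:
            continue
        if len(streams) == 1:
            vals = streams[0][i0:i1].astype(np.float64)
        else:
            vals = np.mean([s[i0:i1] for s in streams], axis=0,
                           dtype=np.float64)
        t_parts.append(sensors.times_s(i0, i1))
        v_parts.append(vals)
        r_parts.append(np.full(i1 - i0, room, dtype=object))
    if not t_parts:
        z = np.array([], dtype=np.float64)
        return z.astype(np.int64), z, np.array([], dtype=object)
    return (np.concatenate(t_parts), np.concatenate(v_parts),
            np.concatenate(r_parts))


def smooth(times_s: np.ndarray, values: np.ndarray,
           span_s: float = SMOOTHING_SPAN_S) -> np.ndarray:
    """Trailing moving average over the previous ``span_s`` seconds.

    Each output point averages all input points with timestamp in
    ``(t - span_s, t]`` — causal (no future samples) and applied to the
    concatenated series, so it runs across room-transition boundaries,
    which is its purpose.  Length-preserving; empty in, empty out.
    """
    n = len(values)
    if n == 0:
        return np.asarray(values, dtype=np.float64)
    t = np.asarray(times_s, dtype=np.float64)
    j0 = np.searchsorted(t, t - span_s, side="right")
    cs = np.concatenate(([0.0], np.cumsum(np.asarray(values, dtype=np.float64))))
    idx = np.arange(1, n + 1)
    return (cs[idx] - cs[j0]) / (idx - j0)


@dataclass
class WindowData:
    """Everything extracted for one survey at one window length."""

    survey_id: str
    spec: WindowSpec
    t_survey_s: int
    w0: float
    w1: float
    series: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = \
        field(default_factory=dict)      # modality -> (times, values, rooms)
    seconds_by_room: dict[str, float] = field(default_factory=dict)
    majority_room: str = OFF_MAP
    majority_room_seconds: float = 0.0
    off_map_fraction: float = 1.0
    precedes_study_start: bool = False

    @property
    def n_points(self) -> dict[str, int]:
        return {m: len(v[0]) for m, v in self.series.items()}


def extract_window(
    dataset: StudyDataset, survey_id: str, patient_id: str, t_s: int,
    spec: WindowSpec, modalities: tuple[str, ...] = MODALITIES,
) -> WindowData:
    """Compose locate → fuse (per modality) → smooth for one survey."""
    w0, w1 = spec.interval(t_s)
    occ = locate_rooms(dataset.traces[patient_id], w0, w1)
    wd = WindowData(
        survey_id=survey_id, spec=spec, t_survey_s=int(t_s), w0=w0, w1=w1,
        seconds_by_room=occ.seconds_by_room,
        majority_room=occ.majority_room,
        majority_room_seconds=occ.seconds_by_room[occ.majority_room],
        off_map_fraction=occ.off_map_fraction,
        precedes_study_start=w0 < dataset.sensors.start_s,
    )
    for m in modalities:
        t, v, r = fuse_sensor_series(dataset.sensors, occ, m, dataset.layout)
        wd.series[m] = (t, smooth(t, v) if len(v) else v, r)
    return wd
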