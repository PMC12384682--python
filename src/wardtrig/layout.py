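"""Ward layout: rooms, room groups, and sensor enclosures.

The modelled setting is a closed neuropsychiatric ward: communal living
spaces and patient rooms connected by hallways, with fixed environmental
sensor enclosures (light / sound / temperature) mounted in most — but not
all — rooms.  Large rooms carry two enclosures whose readings are averaged
downstream; rooms without an enclosure contribute no environmental data, and
time spent outside the tracked area is the reserved pseudo-room ``off_map``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ROOM_GROUPS = ("living room", "dining room", "hallway", "patient room", "other")

#: reserved pseudo-room: patient location unknown / untracked
OFF_MAP = "off_map"


@dataclass(frozen=True)
class Room:
    room_id: str
    group: str          # one of ROOM_GROUPS
    n_sensors: int      # 0, 1 or 2 enclosures

    def __post_init__(self) -> None:
        if self.group not in ROOM_GROUPS:
            raise ValueError(f"unknown room group {self.group!r}")
        if self.n_sensors not in (0, 1, 2):
            raise ValueError("n_sensors must be 0, 1 or 2")
        if self.room_id == OFF_MAP:
            raise ValueError(f"{OFF_MAP!r} is reserved")


@dataclass
class WardLayout:
    """Set of rooms making up one ward.

    Invariants (checked in :meth:`validate`): unique room ids, every room
    group represented, and at least one sensorless room and one dual-sensor
    room so the averaging and no-data code paths are always exercised.
    """

    rooms: list[Room] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [r.room_id for r in self.rooms]
        if len(ids) != len(set(ids)):
            raise ValueError("room_ids must be unique")
        groups = {r.group for r in self.rooms}
        missing = set(ROOM_GROUPS) - groups
        if missing:
            raise ValueError(f"missing room groups: {sorted(missing)}")
        counts = {r.n_sensors for r in self.rooms}
        if 0 not in counts or 2 not in counts:
            raise ValueError(
                "layout must contain at least one sensorless room and one "
                "dual-sensor room"
            )

    # -- lookups -----------------------------------------------------------
    @property
    def room_ids(self) -> list[str]:
        return [r.room_id for r in self.rooms]

    def room(self, room_id: str) -> Room:
        for r in self.rooms:
            if r.room_id == room_id:
                return r
        raise KeyError(room_id)

    def group_of(self, room_id: str) -> str | None:
        """Room group, or None for off_map."""
        if room_id == OFF_MAP:
            return None
        return self.room(room_id).group

    def sensors_of(self, room_id: str) -> list[str]:
        """Sensor ids for a room: ``<room>__s0``, ``<room>__s1``."""
        if room_id == OFF_MAP:
            return []
        r = self.room(room_id)
        return [f"{r.room_id}__s{i}" for i in range(r.n_sensors)]

    def has_sensor(self, room_id: str) -> bool:
        return room_id != OFF_MAP and self.room(room_id).n_sensors > 0

    @property
    def all_sensors(self) -> list[tuple[str, str]]:
        """(sensor_id, room_id) pairs in layout order."""
        out = []
        for r in self.rooms:
            for s in self.sensors_of(r.room_id):
                out.append((s, r.room_id))
        return out


def default_layout() -> WardLayout:
    """Default ward: 13 rooms, 16 sensors, four dual-enclosure rooms.

    Mirrors a ward with centralized communal spaces (the dual-enclosure
    rooms are the above-average-area ones), two hallways, eight patient
    rooms (one without an enclosure) and a sensorless therapy room.
    """
    rooms = [
        Room("living_room", "living room", 2),
        Room("dining_room", "dining room", 2),
        Room("activity_room", "other", 2),
        Room("therapy_room", "other", 0),
        Room("hallway_north", "hallway", 1),
        Room("hallway_south", "hallway", 1),
        Room("patient_01", "patient room", 2),
    ]
    rooms += [Room(f"patient_{i:02d}", "patient room", 1) for i in range(2, 8)]
    rooms.append(Room("patient_08", "patient room", 0))
    return WardLayout(rooms)
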