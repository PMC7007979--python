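"""Ethogram and enclosure zone-map definitions.

An ethogram partitions the behavioural repertoire into three classes:

* ``state`` -- mutually exclusive behavioural states recorded at scan
  points (locomotion, rest, ...),
* ``event`` -- discrete behaviours that can also be tallied on an
  all-occurrence basis (groom, sniff, ...),
* ``arb``   -- aberrant repetitive behaviours / stereotypies (pacing,
  swaying, head bobbing, nose rubbing), which are excluded from the
  species-typical repertoire.

A :class:`ZoneMap` divides an enclosure into categorical zones with area
fractions; the default is ten equal zones, which is the layout the
spread-of-participation index (SPI) assumes unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

BEHAVIOUR_CLASSES = ("state", "event", "arb")


@dataclass(frozen=True)
class Ethogram:
    """Immutable behaviour -> class mapping.

    Parameters
    ----------
    states, events, arb
        Tuples of behaviour names.  Names must be unique across all three
        classes, there must be at least one state, and the ARB set is by
        construction disjoint from the species-typical (state + event) set.
    """

    states: tuple[str, ...]
    events: tuple[str, ...] = ()
    arb: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = list(self.states) + list(self.events) + list(self.arb)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate behaviour names in ethogram: {dupes}")
        if not self.states:
            raise ValidationError("ethogram must define at least one behavioural state")

    @property
    def species_typical(self) -> tuple[str, ...]:
        """States and events; excludes aberrant repetitive behaviours."""
        return tuple(self.states) + tuple(self.events)

    @property
    def behaviours(self) -> tuple[str, ...]:
        return self.species_typical + tuple(self.arb)

    def classify(self, behaviour: str) -> str:
        if behaviour in self.states:
            return "state"
        if behaviour in self.events:
            return "event"
        if behaviour in self.arb:
            return "arb"
        raise KeyError(f"behaviour {behaviour!r} not in ethogram")

    def __contains__(self, behaviour: object) -> bool:
        return behaviour in self.behaviours

    def to_frame(self) -> pd.DataFrame:
        rows = [(b, "state") for b in self.states]
        rows += [(b, "event") for b in self.events]
        rows += [(b, "arb") for b in self.arb]
        return pd.DataFrame(rows, columns=["behaviour", "class"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Ethogram":
        missing = {"behaviour", "class"} - set(frame.columns)
        if missing:
            raise ValidationError(f"ethogram table missing columns: {sorted(missing)}")
        bad = frame.loc[~frame["class"].isin(BEHAVIOUR_CLASSES)]
        if not bad.empty:
            raise ValidationError(
                f"unknown behaviour class {bad['class'].iloc[0]!r} "
                f"for behaviour {bad['behaviour'].iloc[0]!r}"
            )
        by = {c: tuple(frame.loc[frame["class"] == c, "behaviour"]) for c in BEHAVIOUR_CLASSES}
        return cls(states=by["state"], events=by["event"], arb=by["arb"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Ethogram":
        return cls.from_frame(pd.read_csv(path))


#: Felid ethogram used throughout: five states, fourteen discrete
#: behaviours, four stereotypy categories.
DEFAULT_ETHOGRAM = Ethogram(
    states=("locomotion", "rest", "sit", "sleep", "climb"),
    events=(
        "defecate",
        "drink",
        "groom",
        "lick",
        "mark",
        "grab",
        "roll",
        "rub",
        "scratch",
        "sniff",
        "vocalize",
        "yawn",
        "stalk",
        "other",
    ),
    arb=("pacing", "swaying", "head_bobbing", "nose_rubbing"),
)

DEFAULT_N_ZONES = 10


@dataclass(frozen=True)
class ZoneMap:
    """Categorical division of one enclosure into zones with area fractions."""

    enclosure_id: str
    zones: tuple[str, ...] = field(
        default_factory=lambda: tuple(f"z{i + 1:02d}" for i in range(DEFAULT_N_ZONES))
    )
    area_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.zones)) != len(self.zones):
            raise ValidationError(f"duplicate zone ids in enclosure {self.enclosure_id}")
        if len(self.zones) < 2:
            raise ValidationError("a zone map needs at least two zones")
        if self.area_fractions is None:
            object.__setattr__(
                self, "area_fractions", tuple([1.0 / len(self.zones)] * len(self.zones))
            )
        fracs = self.area_fractions
        if len(fracs) != len(self.zones):
            raise ValidationError("area_fractions length does not match zones")
        if any(f <= 0 for f in fracs):
            raise ValidationError("zone area fractions must all be > 0")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError(f"zone area fractions sum to {sum(fracs)!r}, expected 1")

    @property
    def n_zones(self) -> int:
        return len(self.zones)


def default_zone_maps(enclosure_ids) -> dict[str, ZoneMap]:
    """One ten-equal-zone map per enclosure id."""
    return {e: ZoneMap(enclosure_id=e) for e in dict.fromkeys(enclosure_ids)}


def zone_maps_to_frame(zone_maps: dict[str, ZoneMap]) -> pd.DataFrame:
    rows = []
    for zm in zone_maps.values():
        for z, f in zip(zm.zones, zm.area_fractions):
            rows.append((zm.enclosure_id, z, f))
    return pd.DataFrame(rows, columns=["enclosure_id", "zone_id", "area_fraction"])


def zone_maps_from_frame(frame: pd.DataFrame) -> dict[str, ZoneMap]:
    missing = {"enclosure_id", "zone_id", "area_fraction"} - set(frame.columns)
    if missing:
        raise ValidationError(f"zones table missing columns: {sorted(missing)}")
    out: dict[str, ZoneMap] = {}
    for enc, grp in frame.groupby("enclosure_id", sort=False):
        out[str(enc)] = ZoneMap(
            enclosure_id=str(enc),
            zones=tuple(grp["zone_id"].astype(str)),
            area_fractions=tuple(grp["area_fraction"].astype(float)),
        )
    return out


def read_zone_maps(path) -> dict[str, ZoneMap]:
    return zone_maps_from_frame(pd.read_csv(path))


def write_zone_maps(zone_maps: dict[str, ZoneMap], path) -> None:
    zone_maps_to_frame(zone_maps).to_csv(path, index=False)
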