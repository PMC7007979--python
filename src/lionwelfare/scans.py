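"""Instantaneous-scan observation records.

The unit of observation is one subject x one minute within a one-hour
session: the behavioural state of the subject (any ethogram behaviour),
the enclosure zone it occupied, and optional context flags (pre-feeding,
keeper activity, conspecific interaction) that mark observer-discernible
causes for repetitive behaviour.

Scan tables are plain CSV with columns::

    subject_id, session_id, time_block, minute_index, behaviour, zone_id, context

``context`` is a semicolon-joined flag set and may be empty.  In memory a
scan table is a validated :class:`pandas.DataFrame`; per-session views are
available as :class:`ObservationSession` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError, ValidationError
from .ethogram import Ethogram, ZoneMap

TIME_BLOCKS = ("0500-1100", "1300-1800", "2200-0500")
CONTEXT_FLAGS = ("pre_feeding", "keeper_activity", "conspecific_interaction")
SCAN_COLUMNS = [
    "subject_id",
    "session_id",
    "time_block",
    "minute_index",
    "behaviour",
    "zone_id",
    "context",
]
SCANS_PER_HOUR = 60


@dataclass
class ObservationSession:
    """One hour of instantaneous scans for one subject.

    ``scans`` is a minute-sorted slice of the scan table; ``event_tallies``
    optionally carries separately recorded all-occurrence event counts.
    """

    session_id: str
    subject_id: str
    time_block: str
    scans: pd.DataFrame
    event_tallies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.scans) > SCANS_PER_HOUR:
            raise ValidationError(
                f"session {self.session_id}: {len(self.scans)} scans exceed the "
                f"{SCANS_PER_HOUR}-scan hour"
            )
        if not self.scans["minute_index"].is_monotonic_increasing:
            self.scans = self.scans.sort_values("minute_index").reset_index(drop=True)

    @property
    def n_scans(self) -> int:
        return len(self.scans)


def join_context(flags) -> str:
    return ";".join(sorted(flags))


def split_context(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return frozenset()
    return frozenset(str(value).split(";"))


def validate_scans(
    frame: pd.DataFrame,
    ethogram: Ethogram,
    zone_maps: dict[str, ZoneMap] | None = None,
    roster: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Validate a scan table in place and return it.

    Errors name the offending row (0-based position in the table).  Zone ids
    are checked against the subject's own zone map when a roster is given,
    otherwise against the union of all zone maps.
    """
    missing = set(SCAN_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"scan table missing columns: {sorted(missing)}")
    frame = frame.copy()
    frame["context"] = frame["context"].fillna("")
    frame["minute_index"] = frame["minute_index"].astype(int)

    bad_minute = ~frame["minute_index"].between(0, SCANS_PER_HOUR - 1)
    if bad_minute.any():
        i = int(np.flatnonzero(bad_minute)[0])
        raise ValidationError(
            f"row {i}: minute_index {frame['minute_index'].iloc[i]} outside 0-59"
        )

    known = set(ethogram.behaviours)
    bad = ~frame["behaviour"].isin(known)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"row {i}: unknown behaviour {frame['behaviour'].iloc[i]!r}")

    if zone_maps is not None:
        if roster is not None:
            enclosure_of = dict(zip(roster["subject_id"], roster["enclosure_id"]))
            for subj, grp in frame.groupby("subject_id", sort=False):
                enc = enclosure_of.get(subj)
                if enc is None or enc not in zone_maps:
                    raise ValidationError(f"subject {subj!r} has no zone map")
                zones = set(zone_maps[enc].zones)
                bad = ~grp["zone_id"].isin(zones)
                if bad.any():
                    i = int(grp.index[np.flatnonzero(bad)[0]])
                    raise ValidationError(
                        f"row {i}: zone {frame['zone_id'].iloc[i]!r} not in the "
                        f"zone map of enclosure {enc!r}"
                    )
        else:
            zones = {z for zm in zone_maps.values() for z in zm.zones}
            bad = ~frame["zone_id"].isin(zones)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(f"row {i}: unknown zone {frame['zone_id'].iloc[i]!r}")

    dup = frame.duplicated(subset=["subject_id", "session_id", "minute_index"])
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        r = frame.iloc[i]
        raise ValidationError(
            f"row {i}: duplicate scan for subject {r['subject_id']!r}, "
            f"session {r['session_id']!r}, minute {int(r['minute_index'])}"
        )

    bad_flags = frame["context"].map(lambda v: bool(split_context(v) - set(CONTEXT_FLAGS)))
    if bad_flags.any():
        i = int(np.flatnonzero(bad_flags)[0])
        raise ValidationError(f"row {i}: unknown context flag in {frame['context'].iloc[i]!r}")

    return frame.sort_values(["subject_id", "session_id", "minute_index"]).reset_index(drop=True)


def read_scan_table(
    path,
    ethogram: Ethogram,
    zone_maps: dict[str, ZoneMap] | None = None,
    roster: pd.DataFrame | None = None,
    as_sessions: bool = False,
):
    """Read and validate a scans.csv file.

    Returns the validated DataFrame, or a list of :class:`ObservationSession`
    when ``as_sessions`` is true.
    """
    frame = pd.read_csv(path, dtype={"context": "string"})
    frame = validate_scans(frame, ethogram, zone_maps, roster)
    if as_sessions:
        return sessions_from_frame(frame)
    return frame


def write_scan_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def sessions_from_frame(frame: pd.DataFrame) -> list[ObservationSession]:
    out = []
    for (subj, sess), grp in frame.groupby(["subject_id", "session_id"], sort=False):
        out.append(
            ObservationSession(
                session_id=str(sess),
                subject_id=str(subj),
                time_block=str(grp["time_block"].iloc[0]),
                scans=grp.reset_index(drop=True),
            )
        )
    return out


def _as_frame(scans) -> pd.DataFrame:
    """Accept a scan DataFrame, one session, or a list of sessions."""
    if isinstance(scans, pd.DataFrame):
        return scans
    if isinstance(scans, ObservationSession):
        return scans.scans
    frames = [s.scans for s in scans]
    if not frames:
        return pd.DataFrame(columns=SCAN_COLUMNS)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ZoneUsageSummary:
    """Observed vs expected zone frequencies for one subject's pooled scans."""

    zones: tuple[str, ...]
    f_obs: np.ndarray
    f_exp: np.ndarray
    n: int
    f_exp_min: float

    def __post_init__(self) -> None:
        if int(self.f_obs.sum()) != self.n:
            raise ValidationError("observed zone frequencies do not sum to N")
        if abs(float(self.f_exp.sum()) - self.n) > 1e-6:
            raise ValidationError("expected zone frequencies do not sum to N")


def zone_counts(scans, zone_map: ZoneMap) -> ZoneUsageSummary:
    """Tally zone usage and the area-proportional expected frequencies.

    The expected frequency of each zone is its area fraction times the
    total number of scans; ``f_exp_min`` is the expected frequency of the
    smallest zone, the correction term in the SPI denominator.
    """
    frame = _as_frame(scans)
    n = len(frame)
    if n == 0:
        raise UndefinedIndexError("zone usage undefined with zero scans")
    unknown = set(frame["zone_id"]) - set(zone_map.zones)
    if unknown:
        raise ValidationError(f"scans reference zones not in the map: {sorted(unknown)}")
    counts = frame["zone_id"].value_counts()
    f_obs = np.array([int(counts.get(z, 0)) for z in zone_map.zones], dtype=float)
    f_exp = np.asarray(zone_map.area_fractions, dtype=float) * n
    return ZoneUsageSummary(
        zones=zone_map.zones,
        f_obs=f_obs,
        f_exp=f_exp,
        n=n,
        f_exp_min=float(f_exp.min()),
    )


def behaviour_counts(
    scans,
    ethogram: Ethogram,
    include_events: bool = True,
    exclude_arb: bool = False,
) -> pd.Series:
    """Pool per-behaviour frequencies for a subject.

    Scan-point records of any class are counted; all-occurrence event
    tallies attached to sessions are added when ``include_events`` is true.
    With ``include_events`` false, event-class observations are dropped
    entirely (states-only mode); with ``exclude_arb`` true the aberrant
    repetitive categories are removed, leaving the species-typical
    repertoire used by the diversity index.
    """
    frame = _as_frame(scans)
    if frame.empty:
        raise UndefinedIndexError("behaviour counts undefined with zero scans")
    counts = frame["behaviour"].value_counts().astype(int)

    if include_events and not isinstance(scans, pd.DataFrame):
        sessions = [scans] if isinstance(scans, ObservationSession) else list(scans)
        for sess in sessions:
            for name, k in sess.event_tallies.items():
                if name not in ethogram.events:
                    raise ValidationError(
                        f"event tally {name!r} in session {sess.session_id} is not an "
                        "ethogram event"
                    )
                counts[name] = counts.get(name, 0) + int(k)

    keep = set(ethogram.states)
    if include_events:
        keep |= set(ethogram.events)
    if not exclude_arb:
        keep |= set(ethogram.arb)
    counts = counts[counts.index.isin(keep)]
    return counts.sort_index()
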