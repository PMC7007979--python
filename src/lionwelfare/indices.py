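"""The four behavioural welfare indices.

* **SPI** (spread of participation index): enclosure-use evenness,
  ``sum(|f_o - f_e|) / (2 * (N - f_e_min))``, where ``f_o``/``f_e`` are
  observed/area-expected zone frequencies, ``N`` the total scans and
  ``f_e_min`` the expected frequency of the smallest zone.  0 means
  perfectly even use, 1 means all observations in a single zone.
* **SWI** (Shannon-Weiner index): entropy ``-sum(p_i * ln p_i)`` of the
  subject's pooled species-typical behaviour frequencies, in nats.
* **ARB%**: the percentage of scans falling inside aberrant-repetitive-
  behaviour bouts -- maximal runs of the same stereotypy over at least
  five consecutive recorded minutes with no observer-discernible cause
  (no exclusion context flag on any scan of the run).
* **Latency**: seconds to first approach in the novel-object test,
  censored at the 600 s test length and averaged over repeated trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedIndexError, ValidationError
from .ethogram import Ethogram, ZoneMap
from .scans import ObservationSession, ZoneUsageSummary, _as_frame, behaviour_counts, split_context, zone_counts

DEFAULT_PERSISTENCE = 5
DEFAULT_EXCLUSION_FLAGS = frozenset(
    {"pre_feeding", "keeper_activity", "conspecific_interaction"}
)
LATENCY_CAP_S = 600.0
SHY_CUTOFF_S = 300.0


def compute_spi(summary: ZoneUsageSummary) -> float:
    """Spread of participation index of one zone-usage summary.

    Raises :class:`UndefinedIndexError` when the denominator degenerates
    (no scans, or N not exceeding the smallest zone's expected frequency).
    """
    if summary.n == 0:
        raise UndefinedIndexError("SPI undefined with zero scans")
    if summary.n <= summary.f_exp_min:
        raise UndefinedIndexError(
            f"SPI undefined: N={summary.n} must exceed f_e_min={summary.f_exp_min}"
        )
    numer = float(np.abs(summary.f_obs - summary.f_exp).sum())
    return numer / (2.0 * (summary.n - summary.f_exp_min))


def shannon_diversity(counts) -> float:
    """Shannon-Weiner diversity in nats; zero-count behaviours are ignored."""
    values = np.asarray(
        counts.values if isinstance(counts, pd.Series) else list(
            counts.values() if isinstance(counts, dict) else counts
        ),
        dtype=float,
    )
    if values.size == 0 or values.sum() <= 0:
        raise UndefinedIndexError("diversity undefined for an all-zero frequency table")
    if (values < 0).any():
        raise ValidationError("behaviour frequencies must be non-negative")
    return float(sps.entropy(values))  # natural log


@dataclass(frozen=True)
class ArbBout:
    """One detected stereotypy bout within a session."""

    behaviour: str
    start_minute: int
    end_minute: int
    session_id: str = ""
    subject_id: str = ""

    @property
    def length(self) -> int:
        return self.end_minute - self.start_minute + 1


def _bout_scan_mask(
    frame: pd.DataFrame,
    ethogram: Ethogram,
    persistence: int = DEFAULT_PERSISTENCE,
    exclusion_flags: frozenset[str] = DEFAULT_EXCLUSION_FLAGS,
) -> np.ndarray:
    """Boolean mask over rows of a minute-sorted scan frame: True where the
    scan belongs to a qualifying ARB bout.

    A run qualifies when all its scans share one ARB-class behaviour, sit on
    consecutive recorded minutes of one session, carry no exclusion flag,
    and the run length is at least ``persistence``.  Flagged scans break
    runs; gaps in recorded minutes are never bridged.
    """
    if frame.empty:
        return np.zeros(0, dtype=bool)
    arb_set = set(ethogram.arb)
    is_arb = frame["behaviour"].isin(arb_set).to_numpy()
    flagged = frame["context"].map(
        lambda v: bool(split_context(v) & exclusion_flags)
    ).to_numpy()
    eligible = is_arb & ~flagged

    minute = frame["minute_index"].to_numpy()
    subj = frame["subject_id"].to_numpy()
    sess = frame["session_id"].to_numpy()
    beh = frame["behaviour"].to_numpy()

    n = len(frame)
    new_run = np.ones(n, dtype=bool)
    if n > 1:
        contiguous = (
            (subj[1:] == subj[:-1])
            & (sess[1:] == sess[:-1])
            & (minute[1:] == minute[:-1] + 1)
            & (beh[1:] == beh[:-1])
            & eligible[1:]
            & eligible[:-1]
        )
        new_run[1:] = ~contiguous
    run_id = np.cumsum(new_run) - 1
    run_len = np.bincount(run_id)
    in_bout = eligible & (run_len[run_id] >= persistence)
    return in_bout


def detect_arb_bouts(
    session,
    ethogram: Ethogram,
    persistence: int = DEFAULT_PERSISTENCE,
    exclusion_flags: Iterable[str] = DEFAULT_EXCLUSION_FLAGS,
) -> list[ArbBout]:
    """Maximal qualifying stereotypy runs within one session (or scan frame)."""
    frame = session.scans if isinstance(session, ObservationSession) else session
    frame = frame.sort_values(["subject_id", "session_id", "minute_index"]).reset_index(
        drop=True
    )
    mask = _bout_scan_mask(frame, ethogram, persistence, frozenset(exclusion_flags))
    bouts: list[ArbBout] = []
    if not mask.any():
        return bouts
    idx = np.flatnonzero(mask)
    minute = frame["minute_index"].to_numpy()
    beh = frame["behaviour"].to_numpy()
    sess = frame["session_id"].to_numpy()
    subj = frame["subject_id"].to_numpy()
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        same_run = (
            i == prev + 1
            and sess[i] == sess[prev]
            and subj[i] == subj[prev]
            and beh[i] == beh[prev]
            and minute[i] == minute[prev] + 1
        )
        if not same_run:
            bouts.append(
                ArbBout(beh[start], int(minute[start]), int(minute[prev]), sess[start], subj[start])
            )
            start = i
        prev = i
    bouts.append(
        ArbBout(beh[start], int(minute[start]), int(minute[prev]), sess[start], subj[start])
    )
    return bouts


def arb_percent(
    scans,
    ethogram: Ethogram,
    persistence: int = DEFAULT_PERSISTENCE,
    exclusion_flags: Iterable[str] = DEFAULT_EXCLUSION_FLAGS,
) -> float:
    """Percentage of a subject's scans spent inside detected ARB bouts."""
    frame = _as_frame(scans)
    if frame.empty:
        raise UndefinedIndexError("ARB percentage undefined with zero scans")
    frame = frame.sort_values(["subject_id", "session_id", "minute_index"]).reset_index(
        drop=True
    )
    mask = _bout_scan_mask(frame, ethogram, persistence, frozenset(exclusion_flags))
    return 100.0 * float(mask.sum()) / len(frame)


class LatencyScore(NamedTuple):
    latency_s: float
    censored: bool
    shy_flagged: bool


def latency_score(
    approach_s: float | None,
    cap_s: float = LATENCY_CAP_S,
    shy_cutoff_s: float = SHY_CUTOFF_S,
) -> LatencyScore:
    """Score one novel-object trial.

    ``approach_s`` is seconds from stimulus presentation to first approach,
    or None/NaN when the subject never approached within the test.  A
    non-approach is censored at the test length; failing to approach within
    the (five-minute) cutoff flags the trial as behaviourally shy.
    """
    if approach_s is None or (isinstance(approach_s, float) and np.isnan(approach_s)):
        return LatencyScore(float(cap_s), True, True)
    t = float(approach_s)
    if t < 0:
        raise ValidationError(f"approach time {t} precedes the trial start")
    if t > cap_s:
        raise ValidationError(f"approach time {t} exceeds the {cap_s} s test length")
    return LatencyScore(t, False, t > shy_cutoff_s)


def subject_latency(
    trials: pd.DataFrame,
    test_type: str = "novel_object",
    cap_s: float = LATENCY_CAP_S,
    shy_cutoff_s: float = SHY_CUTOFF_S,
) -> tuple[float, bool]:
    """Average latency over one subject's repeated trials of ``test_type``.

    Returns (mean latency, censored) where censored is True when any
    contributing trial was a non-approach scored at the cap.
    """
    sel = trials.loc[trials["test_type"] == test_type]
    if sel.empty:
        raise UndefinedIndexError(f"no {test_type!r} trials for subject")
    scores = [latency_score(v, cap_s, shy_cutoff_s) for v in sel["approach_s"]]
    return float(np.mean([s.latency_s for s in scores])), any(s.censored for s in scores)


@dataclass(frozen=True)
class WelfareIndexSet:
    """Per-subject welfare indices."""

    subject_id: str
    spi: float
    swi: float
    arb_percent: float
    latency_s: float
    latency_censored: bool
    n_scans: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.arb_percent <= 100.0:
            raise ValidationError(f"{self.subject_id}: arb_percent outside [0, 100]")
        if self.swi < 0:
            raise ValidationError(f"{self.subject_id}: diversity must be >= 0")
        if not 0.0 < self.latency_s <= LATENCY_CAP_S:
            raise ValidationError(f"{self.subject_id}: latency outside (0, {LATENCY_CAP_S}]")


def compute_index_set(
    subject_id: str,
    scans,
    zone_map: ZoneMap,
    ethogram: Ethogram,
    trials: pd.DataFrame,
    persistence: int = DEFAULT_PERSISTENCE,
    exclusion_flags: Iterable[str] = DEFAULT_EXCLUSION_FLAGS,
    include_events: bool = True,
) -> WelfareIndexSet:
    """Combine the four indices for one subject.

    Diversity is computed on the pooled species-typical frequencies
    (ARB categories excluded); latency averages the repeated novel-object
    trials.  Component errors are re-raised with subject context.
    """
    try:
        summary = zone_counts(scans, zone_map)
        spi = compute_spi(summary)
        counts = behaviour_counts(
            scans, ethogram, include_events=include_events, exclude_arb=True
        )
        swi = shannon_diversity(counts)
        arb = arb_percent(scans, ethogram, persistence, exclusion_flags)
        lat, censored = subject_latency(trials)
    except (UndefinedIndexError, ValidationError) as exc:
        raise type(exc)(f"subject {subject_id!r}: {exc}") from exc
    return WelfareIndexSet(
        subject_id=subject_id,
        spi=spi,
        swi=swi,
        arb_percent=arb,
        latency_s=lat,
        latency_censored=censored,
        n_scans=summary.n,
    )


def compute_indices(
    scans: pd.DataFrame,
    roster: pd.DataFrame,
    zone_maps: dict[str, ZoneMap],
    ethogram: Ethogram,
    trials: pd.DataFrame,
    persistence: int = DEFAULT_PERSISTENCE,
    exclusion_flags: Iterable[str] = DEFAULT_EXCLUSION_FLAGS,
    include_events: bool = True,
) -> pd.DataFrame:
    """Per-subject welfare index table for a whole study (roster order)."""
    rows = []
    for _, subj in roster.iterrows():
        sid = subj["subject_id"]
        sub_scans = scans.loc[scans["subject_id"] == sid]
        sub_trials = trials.loc[trials["subject_id"] == sid]
        s = compute_index_set(
            sid,
            sub_scans,
            zone_maps[subj["enclosure_id"]],
            ethogram,
            sub_trials,
            persistence=persistence,
            exclusion_flags=exclusion_flags,
            include_events=include_events,
        )
        rows.append(s.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "spi",
            "swi",
            "arb_percent",
            "latency_s",
            "latency_censored",
            "n_scans",
        ],
    )


def per_session_diversity(scans: pd.DataFrame, ethogram: Ethogram) -> pd.DataFrame:
    """Diagnostic: SWI per (subject, session) instead of pooled."""
    rows = []
    for (sid, sess), grp in scans.groupby(["subject_id", "session_id"], sort=False):
        counts = behaviour_counts(grp, ethogram, include_events=True, exclude_arb=True)
        if counts.sum() == 0:
            continue
        rows.append({"subject_id": sid, "session_id": sess, "swi": shannon_diversity(counts)})
    return pd.DataFrame(rows, columns=["subject_id", "session_id", "swi"])
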