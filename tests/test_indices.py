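import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lionwelfare import (
    UndefinedIndexError,
    ZoneMap,
    arb_percent,
    compute_index_set,
    compute_spi,
    detect_arb_bouts,
    latency_score,
    shannon_diversity,
)
from lionwelfare.indices import subject_latency
from lionwelfare.scans import ZoneUsageSummary, zone_counts


def make_summary(f_obs, fractions=None):
    f_obs = np.asarray(f_obs, dtype=float)
    k = len(f_obs)
    fractions = np.asarray(fractions if fractions is not None else [1.0 / k] * k)
    n = int(f_obs.sum())
    f_exp = fractions * n
    return ZoneUsageSummary(
        zones=tuple(f"z{i:02d}" for i in range(k)),
        f_obs=f_obs,
        f_exp=f_exp,
        n=n,
        f_exp_min=float(f_exp.min()),
    )


class TestSPI:
    def test_maximal_bias_is_one(self):
        assert compute_spi(make_summary([100] + [0] * 9)) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        assert compute_spi(make_summary([10] * 10)) == pytest.approx(0.0)

    def test_hand_evaluated_case(self):
        # |30-10| + 10 + 10 = 40 over 2*(100-10) = 180
        summary = make_summary([30, 10, 10, 10, 10, 10, 10, 10, 0, 0])
        assert compute_spi(summary) == pytest.approx(40 / 180)

    @given(
        counts=st.lists(st.integers(0, 50), min_size=10, max_size=10).filter(
            lambda c: sum(c) > 10
        ),
        factor=st.integers(2, 7),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, counts, factor):
        """Multiplying all zone counts by a positive integer leaves SPI unchanged."""
        a = compute_spi(make_summary(counts))
        b = compute_spi(make_summary([c * factor for c in counts]))
        assert a == pytest.approx(b)
        assert -1e-12 <= a <= 1.0 + 1e-12

    def test_undefined_with_zero_scans(self):
        with pytest.raises(UndefinedIndexError):
            compute_spi(make_summary([0] * 10))


class TestShannonDiversity:
    def test_single_behaviour_zero(self):
        assert shannon_diversity({"rest": 17}) == pytest.approx(0.0)

    def test_uniform_equals_log_k(self):
        assert shannon_diversity([5, 5, 5, 5]) == pytest.approx(np.log(4))
        assert shannon_diversity([5, 5, 5, 5]) == pytest.approx(1.3863, abs=1e-4)

    def test_hand_evaluated_mixture(self):
        # -(0.5 ln 0.5 + 0.3 ln 0.3 + 0.2 ln 0.2) = 1.0297
        got = shannon_diversity({"rest": 50, "locomotion": 30, "groom": 20})
        assert got == pytest.approx(1.0297, abs=1e-4)

    def test_zero_count_behaviour_ignored(self):
        assert shannon_diversity([50, 30, 20, 0]) == pytest.approx(
            shannon_diversity([50, 30, 20])
        )

    def test_bounded_by_log_support_size(self, rng):
        counts = rng.integers(1, 100, size=12)
        h = shannon_diversity(counts)
        assert 0.0 <= h <= np.log(12) + 1e-12

    def test_all_zero_is_an_error(self):
        with pytest.raises(UndefinedIndexError):
            shannon_diversity([0, 0])


def oracle_bouts(frame, ethogram, persistence=5, exclusion_flags=frozenset(
    {"pre_feeding", "keeper_activity", "conspecific_interaction"})):
    """Definition-level bout enumeration, independent of the detector.

    Walks every maximal chain of eligible scans linked by consecutive
    minutes and equal behaviour, then keeps those of sufficient length.
    """
    rows = frame.sort_values(["session_id", "minute_index"]).to_dict("records")
    arb = set(ethogram.arb)

    def eligible(r):
        flags = set(str(r["context"]).split(";")) if r["context"] else set()
        return r["behaviour"] in arb and not (flags & exclusion_flags)

    def chained(a, b):
        return (
            eligible(a)
            and eligible(b)
            and a["behaviour"] == b["behaviour"]
            and b["minute_index"] == a["minute_index"] + 1
            and a["session_id"] == b["session_id"]
        )

    out = []
    n = len(rows)
    for i in range(n):
        if not eligible(rows[i]):
            continue
        if i > 0 and chained(rows[i - 1], rows[i]):
            continue  # not a maximal-run start
        j = i
        while j + 1 < n and chained(rows[j], rows[j + 1]):
            j += 1
        if j - i + 1 >= persistence:
            out.append(
                (rows[i]["behaviour"], rows[i]["minute_index"], rows[j]["minute_index"])
            )
    return out


class TestArbBouts:
    def test_threshold_boundary_five_scans(self, make_scans, ethogram):
        frame = make_scans(["pacing"] * 5 + ["rest"] * 55)
        bouts = detect_arb_bouts(frame, ethogram)
        assert [(b.behaviour, b.start_minute, b.end_minute) for b in bouts] == [
            ("pacing", 0, 4)
        ]
        assert bouts[0].length == 5

    def test_four_scans_below_persistence(self, make_scans, ethogram):
        frame = make_scans(["pacing"] * 4 + ["rest"] * 10)
        assert detect_arb_bouts(frame, ethogram) == []

    def test_gap_in_minutes_breaks_run(self, make_scans, ethogram):
        minutes = [0, 1, 2, 4, 5, 6]  # minute 3 unrecorded
        frame = make_scans(["pacing"] * 6, minutes=minutes)
        assert detect_arb_bouts(frame, ethogram) == []

    def test_exclusion_flag_breaks_run(self, make_scans, ethogram):
        contexts = [""] * 11
        contexts[5] = "pre_feeding"
        frame = make_scans(["pacing"] * 11, contexts=contexts)
        bouts = detect_arb_bouts(frame, ethogram)
        assert {(b.start_minute, b.end_minute) for b in bouts} == {(0, 4), (6, 10)}

    def test_behaviour_change_breaks_run(self, make_scans, ethogram):
        frame = make_scans(["pacing"] * 4 + ["swaying"] * 4)
        assert detect_arb_bouts(frame, ethogram) == []

    def test_bouts_never_span_sessions(self, make_scans, ethogram):
        a = make_scans(["pacing"] * 3, minutes=[57, 58, 59], session_id="sA")
        b = make_scans(["pacing"] * 3, minutes=[0, 1, 2], session_id="sB")
        frame = pd.concat([a, b], ignore_index=True)
        assert detect_arb_bouts(frame, ethogram) == []

    def test_matches_exhaustive_oracle_on_random_sequences(self, make_scans, ethogram, rng):
        """Sticky random 200-scan sequences with gaps and flags: detector == oracle."""
        alphabet = ["pacing", "swaying", "rest", "locomotion", "nose_rubbing"]
        for _ in range(150):
            global_minutes = np.sort(rng.choice(250, size=200, replace=False))
            minutes = global_minutes % 60
            sessions = [f"s{m // 60}" for m in global_minutes]
            behaviours = [str(rng.choice(alphabet))]
            for _ in range(199):
                if rng.random() < 0.8:
                    behaviours.append(behaviours[-1])
                else:
                    behaviours.append(str(rng.choice(alphabet)))
            contexts = [
                "pre_feeding" if rng.random() < 0.05 else "" for _ in range(200)
            ]
            frame = pd.DataFrame(
                {
                    "subject_id": "a1",
                    "session_id": sessions,
                    "time_block": "0500-1100",
                    "minute_index": minutes,
                    "behaviour": behaviours,
                    "zone_id": "z01",
                    "context": contexts,
                }
            )
            got = [
                (b.behaviour, b.start_minute, b.end_minute)
                for b in detect_arb_bouts(frame, ethogram)
            ]
            assert got == oracle_bouts(frame, ethogram)


class TestArbPercent:
    def test_one_bout_in_sixty_scans(self, make_scans, ethogram):
        frame = make_scans(["pacing"] * 5 + ["rest"] * 55)
        assert arb_percent(frame, ethogram) == pytest.approx(100 * 5 / 60)

    def test_no_arb_behaviour(self, make_scans, ethogram):
        assert arb_percent(make_scans(["rest"] * 30), ethogram) == 0.0

    def test_monotone_in_flag_removal(self, make_scans, ethogram):
        """Unflagging a scan inside a qualifying run never decreases ARB%."""
        contexts = [""] * 12
        contexts[6] = "keeper_activity"
        flagged = make_scans(["pacing"] * 12, contexts=contexts)
        unflagged = make_scans(["pacing"] * 12)
        assert arb_percent(unflagged, ethogram) >= arb_percent(flagged, ethogram)


class TestLatency:
    def test_prompt_approach(self):
        assert latency_score(12.4) == (12.4, False, False)

    def test_no_approach_censored_and_shy(self):
        assert latency_score(None) == (600.0, True, True)
        assert latency_score(float("nan")) == (600.0, True, True)

    def test_slow_approach_flags_shy_only(self):
        lat, censored, shy = latency_score(420.0)
        assert (lat, censored, shy) == (420.0, False, True)

    def test_negative_approach_rejected(self):
        with pytest.raises(Exception, match="precede"):
            latency_score(-1.0)

    def test_repeated_trials_averaged(self):
        trials = pd.DataFrame(
            {
                "subject_id": "a1",
                "session": [1, 2],
                "test_type": "novel_object",
                "approach_s": [10.0, 20.0],
            }
        )
        lat, censored = subject_latency(trials)
        assert lat == pytest.approx(15.0)
        assert not censored


class TestIndexSet:
    def test_composition_equals_components(self, make_scans, ethogram, zone_map):
        frame = pd.concat(
            [
                make_scans(
                    ["pacing"] * 6 + ["rest"] * 30 + ["locomotion"] * 24,
                    zones=[f"z{(i % 10) + 1:02d}" for i in range(60)],
                    session_id="sA",
                ),
                make_scans(["rest"] * 60, session_id="sB"),
            ],
            ignore_index=True,
        )
        trials = pd.DataFrame(
            {"subject_id": "a1", "session": [1, 2], "test_type": "novel_object",
             "approach_s": [30.0, 50.0]}
        )
        s = compute_index_set("a1", frame, zone_map, ethogram, trials)
        assert s.spi == pytest.approx(compute_spi(zone_counts(frame, zone_map)))
        assert s.arb_percent == pytest.approx(arb_percent(frame, ethogram))
        assert s.latency_s == pytest.approx(40.0)
        assert s.n_scans == 120
        expected_swi = shannon_diversity({"rest": 90, "locomotion": 24})
        assert s.swi == pytest.approx(expected_swi)

    def test_degenerate_fixture_gives_zero_indices(self, make_scans, ethogram, zone_map):
        """Uniform zones, a single behaviour, no stereotypy -> (0, 0, 0)."""
        frame = make_scans(["rest"] * 10, zones=[f"z{i + 1:02d}" for i in range(10)])
        trials = pd.DataFrame(
            {"subject_id": "a1", "session": [1, 2], "test_type": "novel_object",
             "approach_s": [5.0, 5.0]}
        )
        s = compute_index_set("a1", frame, zone_map, ethogram, trials)
        assert (s.spi, s.swi, s.arb_percent) == (0.0, 0.0, 0.0)

    def test_error_carries_subject_context(self, make_scans, ethogram, zone_map):
        trials = pd.DataFrame(
            {"subject_id": [], "session": [], "test_type": [], "approach_s": []}
        )
        with pytest.raises(UndefinedIndexError, match="a1"):
            compute_index_set(
                "a1", make_scans(["rest"] * 5), zone_map, ethogram, trials
            )
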