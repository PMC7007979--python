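"""Synthetic-study generator.

Generates complete studies -- roster, latent welfare profiles, scan
records, keeper ratings and novel-object trial logs -- with the
statistical structure the analysis pipeline assumes, so that every stage
is testable without the original raw observations.

The default study conditions mirror the published lion study: 35 subjects
(21 bold / 14 shy, 16 captive-raised / 19 wild-rescued, 14 M / 21 F,
17 pair- / 18 group-housed), 57 one-hour sessions of 60 one-minute scans
per subject, and per-group welfare-index targets equal to the published
group summaries (mean +/- SD of SPI, SWI, ARB% and latency by personality
and by rearing history).  Personality x origin cell targets are solved
from those marginal summaries by least squares at run time.

Generative model per subject, given the latent profile:

* zones: i.i.d. draws from a one-preferred-zone distribution whose
  preference weight is calibrated numerically (Brent root-finding on a
  folded-normal approximation of the expected sample SPI);
* species-typical behaviours: i.i.d. draws from a power-tilted base
  repertoire distribution, the tilt solved so the distribution's entropy
  equals the latent diversity;
* stereotypy: geometric-length bouts (minimum length = the persistence
  threshold) placed uniformly at random within sessions at a rate
  calibrated to the latent ARB fraction; pre-feeding displacement bouts
  are planted with context flags in a fraction of afternoon sessions and
  must be ignored by a correct detector;
* latencies: lognormal per personality x origin cell, with the group
  variance split between and within subjects and censoring at the 600 s
  test length;
* ratings: group-dependent trait base values plus independent rater
  noise, rounded and clipped to the 1-9 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy import stats as sps

from .errors import ValidationError
from .ethogram import DEFAULT_ETHOGRAM, default_zone_maps, zone_maps_to_frame
from .roster import ROSTER_COLUMNS, default_roster, validate_roster
from .scans import SCAN_COLUMNS, TIME_BLOCKS

#: Published group summaries used as generator targets: index ->
#: group label -> (n, mean, sd).  ARB is in % of scans, latency in seconds.
PUBLISHED_GROUP_SUMMARIES = {
    "spi": {
        "bold": (21, 0.50, 0.12),
        "shy": (14, 0.71, 0.15),
        "captive_raised": (16, 0.47, 0.12),
        "wild_rescued": (19, 0.67, 0.15),
    },
    "swi": {
        "bold": (21, 1.23, 0.26),
        "shy": (14, 0.73, 0.34),
        "captive_raised": (16, 1.26, 0.30),
        "wild_rescued": (19, 0.83, 0.35),
    },
    "arb_percent": {
        "bold": (21, 7.01, 3.9),
        "shy": (14, 16.13, 5.4),
        "captive_raised": (16, 7.74, 5.3),
        "wild_rescued": (19, 13.12, 6.25),
    },
    "latency_s": {
        "bold": (21, 11.13, 3.65),
        "shy": (14, 102.71, 17.4),
        "captive_raised": (16, 18.61, 21.55),
        "wild_rescued": (19, 72.30, 48.7),
    },
}

#: Published % bold behaviour in novel-object focal observations.
PCT_BOLD_TARGETS = {"bold": (87.24, 8.74), "shy": (15.86, 9.5)}

#: Base species-typical repertoire frequencies (rest-dominated felid
#: activity budget); the tilt solved per subject reshapes this vector.
BASE_BEHAVIOUR_FREQS = {
    "rest": 0.41,
    "sleep": 0.18,
    "locomotion": 0.12,
    "sit": 0.10,
    "climb": 0.01,
    "groom": 0.045,
    "sniff": 0.03,
    "drink": 0.015,
    "yawn": 0.015,
    "lick": 0.01,
    "mark": 0.01,
    "roll": 0.01,
    "rub": 0.01,
    "vocalize": 0.01,
    "defecate": 0.005,
    "grab": 0.005,
    "scratch": 0.005,
    "stalk": 0.005,
    "other": 0.005,
}

ARB_BEHAVIOUR_WEIGHTS = {"pacing": 0.6, "swaying": 0.2, "head_bobbing": 0.1, "nose_rubbing": 0.1}

#: legal ranges for latent index values (truncation bounds for draws)
LATENT_RANGES = {
    "spi": (0.02, 0.98),
    "swi": (0.08, float(np.log(len(BASE_BEHAVIOUR_FREQS))) - 0.02),
    "arb_percent": (0.0, 60.0),
    "latency_s": (1.0, 600.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    ``index_targets`` maps index -> group label -> (n, mean, sd) marginal
    summaries by personality and by origin; defaults to the published
    group summaries.  ``within_subject_sd_frac`` apportions the group
    variance of latency between subjects and within (trial-to-trial);
    ``n_inconsistent`` appends extra subjects whose repeat novel-object
    sessions disagree, exercising the consistency screen.
    """

    n_subjects: int = 35
    sessions_per_subject: int = 57
    scans_per_session: int = 60
    persistence: int = 5
    arb_run_geom_p: float = 0.35
    n_raters: int = 3
    n_bold_traits: int = 10
    n_shy_traits: int = 10
    rater_noise_sd: float = 0.7
    trait_spread_sd: float = 0.4
    trait_high_base: float = 8.0
    trait_low_base: float = 2.5
    within_subject_sd_frac: float = 0.5
    displacement_session_rate: float = 0.15
    n_inconsistent: int = 0
    index_targets: dict = field(default_factory=lambda: PUBLISHED_GROUP_SUMMARIES)
    composition: dict | None = None  # (personality, origin, sex, grouping) -> count

    def __post_init__(self) -> None:
        # normalise target triples (YAML yields lists) so configs compare equal
        self.index_targets = {
            idx: {grp: tuple(v) for grp, v in groups.items()}
            for idx, groups in self.index_targets.items()
        }
        if self.composition is not None:
            total = sum(self.composition.values())
            if total != self.n_subjects:
                raise ValidationError(
                    f"composition counts sum to {total}, expected n_subjects={self.n_subjects}"
                )
        for idx, groups in self.index_targets.items():
            for label, (_, _, sd) in groups.items():
                if sd <= 0:
                    raise ValidationError(f"target sd for {idx}/{label} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        comp = raw.pop("composition", None)
        if comp is not None:
            comp = {tuple(k.split("|")): int(v) for k, v in comp.items()}
        return cls(composition=comp, **raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        comp = raw.pop("composition", None)
        if comp is not None:
            raw["composition"] = {"|".join(k): v for k, v in comp.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def solve_cell_targets(config: GeneratorConfig, cell_counts: dict) -> dict:
    """Personality x origin cell (mean, sd) targets per index.

    The four marginal equations (bold, shy, captive, wild) are rank-3 and,
    because the published summaries are rounded to two decimals, slightly
    inconsistent; the system is solved as a minimum-norm least-squares
    correction to an additive prior (cell = average of its two margins),
    which keeps the under-determined direction anchored to plausible
    values while reproducing each margin to within about a percent of its
    SD.  Cell variances are solved the same way from the marginal
    variances after removing the between-cell mean spread, floored at
    (0.3 * smallest marginal SD)^2.
    """
    cells = [("bold", "captive_raised"), ("bold", "wild_rescued"),
             ("shy", "captive_raised"), ("shy", "wild_rescued")]
    n = np.array([cell_counts.get(c, 0) for c in cells], dtype=float)
    if (n <= 0).any():
        # degenerate composition: fall back to personality margins only
        out = {}
        for idx, groups in config.index_targets.items():
            out[idx] = {}
            for p, o in cells:
                _, m, s = groups[p]
                out[idx][(p, o)] = (m, s)
        return out

    margins = ["bold", "shy", "captive_raised", "wild_rescued"]
    A = np.zeros((4, 4))
    for r, margin in enumerate(margins):
        for c, (p, o) in enumerate(cells):
            if margin in (p, o):
                A[r, c] = n[c]
    row_n = A.sum(axis=1)
    A_norm = A / row_n[:, None]

    def _solve_anchored(b: np.ndarray, prior: np.ndarray) -> np.ndarray:
        delta, *_ = np.linalg.lstsq(A_norm, b - A_norm @ prior, rcond=None)
        return prior + delta

    out = {}
    for idx, groups in config.index_targets.items():
        b_mean = np.array([groups[m][1] for m in margins], dtype=float)
        prior_mean = np.array(
            [(groups[p][1] + groups[o][1]) / 2.0 for p, o in cells]
        )
        mu = _solve_anchored(b_mean, prior_mean)
        lo, hi = LATENT_RANGES[idx]
        mu = np.clip(mu, lo + 1e-6 if idx == "latency_s" else lo, hi)
        # variances: var_margin = sum_c w_c (v_c + (mu_c - mean_margin)^2)
        b_var = []
        for r, margin in enumerate(margins):
            w = A[r] / row_n[r]
            dev2 = float(np.dot(w, (mu - b_mean[r]) ** 2))
            b_var.append(groups[margin][2] ** 2 - dev2)
        prior_var = np.array(
            [(groups[p][2] ** 2 + groups[o][2] ** 2) / 2.0 for p, o in cells]
        )
        v = _solve_anchored(np.array(b_var), prior_var)
        floor = (0.3 * min(groups[m][2] for m in margins)) ** 2
        v = np.maximum(v, floor)
        out[idx] = {cell: (float(mu[c]), float(np.sqrt(v[c]))) for c, cell in enumerate(cells)}
    return out


# ---------------------------------------------------------------------------
# calibrations


def _folded_normal_mean(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """E|X| for X ~ N(mu, sigma^2)."""
    sigma = np.maximum(sigma, 1e-12)
    return sigma * np.sqrt(2.0 / np.pi) * np.exp(-(mu**2) / (2 * sigma**2)) + mu * (
        2 * sps.norm.cdf(mu / sigma) - 1
    )


def expected_spi(q: float, n_scans: int, n_zones: int = 10) -> float:
    """Expected sample SPI of n i.i.d. zone draws from the one-preferred-zone
    family (preferred zone probability q, the rest uniform), equal areas.

    Uses the normal approximation of the binomial zone counts; accurate to
    ~1e-3 for the scan totals used here, which is the calibration tolerance.
    """
    e = n_scans / n_zones
    p_oth = (1.0 - q) / (n_zones - 1)
    mu = np.array([n_scans * q - e, n_scans * p_oth - e])
    sig = np.sqrt(n_scans * np.array([q * (1 - q), p_oth * (1 - p_oth)]))
    terms = _folded_normal_mean(mu, sig)
    total = terms[0] + (n_zones - 1) * terms[1]
    return float(total / (2.0 * (n_scans - e)))


def calibrate_zone_weight(target_spi: float, n_scans: int, n_zones: int = 10) -> float:
    """Preferred-zone probability q whose expected sample SPI equals the target.

    Clamped to the sampling-noise floor (q = 1/n_zones, i.e. uniform use)
    when the target lies below the smallest achievable expected SPI.
    """
    lo, hi = 1.0 / n_zones, 1.0 - 1e-9
    f_lo = expected_spi(lo, n_scans, n_zones) - target_spi
    f_hi = expected_spi(hi, n_scans, n_zones) - target_spi
    if f_lo >= 0:
        return lo
    if f_hi <= 0:
        return hi
    return float(optimize.brentq(
        lambda q: expected_spi(q, n_scans, n_zones) - target_spi, lo, hi, xtol=1e-6
    ))


def tilt_for_entropy(target_h: float, base: dict | None = None) -> np.ndarray:
    """Probability vector from power-tilting the base repertoire so its
    Shannon entropy (nats) equals ``target_h``.

    The family p_i(theta) ~ base_i ** theta runs from uniform (theta -> 0,
    entropy ln k) towards the modal behaviour (theta large); the tilt is
    solved by Brent root-finding.  Targets outside the achievable range
    are clamped to the nearest endpoint.
    """
    if base is None:
        base = BASE_BEHAVIOUR_FREQS
    b = np.asarray(list(base.values()), dtype=float)
    b = b / b.sum()

    def entropy_at(theta: float) -> float:
        w = b**theta
        p = w / w.sum()
        return float(sps.entropy(p))

    lo, hi = 1e-8, 60.0
    if target_h >= entropy_at(lo):
        theta = lo
    elif target_h <= entropy_at(hi):
        theta = hi
    else:
        theta = float(optimize.brentq(lambda t: entropy_at(t) - target_h, lo, hi, xtol=1e-9))
    w = b**theta
    return w / w.sum()


# ---------------------------------------------------------------------------
# generators


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _extra_subject_rows(config: GeneratorConfig) -> list[dict]:
    """Roster rows for subjects planted to fail the consistency screen."""
    rows = []
    sexes = ["M", "F", "F"]
    pers = ["shy", "bold", "shy"]
    for j in range(config.n_inconsistent):
        rows.append(
            {
                "subject_id": f"x{j + 1:02d}",
                "name": f"Extra{j + 1}",
                "sex": sexes[j % 3],
                "origin": "wild_rescued",
                "social_grouping": "group_housed",
                "enclosure_id": f"ex{j + 1:02d}",
                "enclosure_area": 1424.0,
                "age_days": 2500.0,
                "age_class": "prime",
                "personality": pers[j % 3],
            }
        )
    return rows


def _roster_from_composition(config: GeneratorConfig, rng) -> pd.DataFrame:
    base = default_roster()
    rows = []
    i = 0
    for (pers, origin, sex, grouping), count in config.composition.items():
        for _ in range(count):
            i += 1
            rows.append(
                {
                    "subject_id": f"s{i:03d}",
                    "name": f"Subject{i}",
                    "sex": sex,
                    "origin": origin,
                    "social_grouping": grouping,
                    "enclosure_id": f"en{i:02d}",
                    "enclosure_area": float(rng.choice(base["enclosure_area"])),
                    "age_days": float(rng.choice(base["age_days"])),
                    "age_class": str(rng.choice(["sub", "prime", "old"], p=[0.15, 0.45, 0.4])),
                    "personality": pers,
                }
            )
    frame = pd.DataFrame(rows, columns=ROSTER_COLUMNS)
    validate_roster(frame)
    return frame


def generate_roster(config: GeneratorConfig, seed) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roster plus latent welfare profiles (the simulation ground truth).

    With the default configuration the roster is the 35-subject study
    population verbatim; a ``composition`` mapping generates an arbitrary
    factorial make-up instead.  Latent index values are truncated-normal
    (lognormal for latency) draws at the subject's personality x origin
    cell targets.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if config.composition is None:
        if config.n_subjects != 35:
            raise ValidationError(
                "n_subjects != 35 requires an explicit composition mapping"
            )
        roster = default_roster()
    else:
        roster = _roster_from_composition(config, rng)
    if config.n_inconsistent:
        roster = pd.concat(
            [roster, pd.DataFrame(_extra_subject_rows(config))], ignore_index=True
        )

    counts = (
        roster.groupby(["personality", "origin"]).size().to_dict()
        if config.n_inconsistent == 0
        else roster.iloc[: config.n_subjects].groupby(["personality", "origin"]).size().to_dict()
    )
    cell_targets = solve_cell_targets(config, counts)

    truth_rows = []
    for _, subj in roster.iterrows():
        cell = (subj["personality"], subj["origin"])
        row = {"subject_id": subj["subject_id"], "personality": cell[0], "origin": cell[1]}
        for idx in ("spi", "swi", "arb_percent"):
            m, s = cell_targets[idx][cell]
            lo, hi = LATENT_RANGES[idx]
            row[f"true_{idx}"] = float(_truncnorm(rng, m, s, lo, hi))
        m, s = cell_targets["latency_s"][cell]
        mu, sigma = _lognormal_params(m, s)
        w = config.within_subject_sd_frac
        truth_log = rng.normal(mu + w * sigma**2 / 2.0, sigma * np.sqrt(1.0 - w))
        row["true_latency_s"] = float(np.clip(np.exp(truth_log), *LATENT_RANGES["latency_s"]))
        row["latency_log_sigma"] = sigma
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return roster, truth


def _place_runs(rng, n_minutes: int, lengths: list[int], taken: np.ndarray) -> list[tuple[int, int]]:
    """Place runs of the given lengths at random non-overlapping starts.

    Overlapping placements are re-drawn (up to 30 attempts each); runs that
    cannot be placed are dropped.
    """
    placed = []
    for length in lengths:
        if length > n_minutes:
            continue
        for _ in range(30):
            start = int(rng.integers(0, n_minutes - length + 1))
            if not taken[start : start + length].any():
                taken[start : start + length] = True
                placed.append((start, length))
                break
    return placed


def generate_scans(
    profile: pd.Series | dict,
    config: GeneratorConfig,
    seed,
    zone_ids: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Scan records for one subject from its latent profile.

    Returns a validated-schema DataFrame of
    sessions_per_subject x scans_per_session rows.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sid = profile["subject_id"]
    S, m = config.sessions_per_subject, config.scans_per_session
    total = S * m
    if zone_ids is None:
        zone_ids = tuple(f"z{i + 1:02d}" for i in range(10))
    n_zones = len(zone_ids)

    # zones
    q = calibrate_zone_weight(float(profile["true_spi"]), total, n_zones)
    preferred = int(rng.integers(n_zones))
    probs = np.full(n_zones, (1.0 - q) / (n_zones - 1))
    probs[preferred] = q
    zones = rng.choice(np.array(zone_ids), size=total, p=probs)

    # species-typical behaviours
    beh_probs = tilt_for_entropy(float(profile["true_swi"]))
    beh_names = np.array(list(BASE_BEHAVIOUR_FREQS.keys()), dtype=object)
    behaviours = rng.choice(beh_names, size=total, p=beh_probs)
    context = np.full(total, "", dtype=object)

    # stereotypy bouts + pre-feeding displacement
    arb_frac = float(profile["true_arb_percent"]) / 100.0
    mean_len = config.persistence + (1.0 - config.arb_run_geom_p) / config.arb_run_geom_p
    lam = arb_frac * m / mean_len
    arb_names = np.array(list(ARB_BEHAVIOUR_WEIGHTS.keys()), dtype=object)
    arb_w = np.array(list(ARB_BEHAVIOUR_WEIGHTS.values()))
    blocks = [TIME_BLOCKS[(k // 4) % 3] for k in range(S)]
    for k in range(S):
        off = k * m
        taken = np.zeros(m, dtype=bool)
        if lam > 0:
            n_runs = int(rng.poisson(lam))
            lengths = [
                config.persistence + int(rng.geometric(config.arb_run_geom_p)) - 1
                for _ in range(n_runs)
            ]
            for start, length in _place_runs(rng, m, lengths, taken):
                behaviours[off + start : off + start + length] = rng.choice(
                    arb_names, p=arb_w
                )
        if blocks[k] == "1300-1800" and rng.random() < config.displacement_session_rate:
            length = int(rng.integers(config.persistence, config.persistence + 4))
            start = m - length
            if not taken[start:].any():
                behaviours[off + start : off + m] = "pacing"
                context[off + start : off + m] = "pre_feeding"

    frame = pd.DataFrame(
        {
            "subject_id": sid,
            "session_id": [f"{sid}-s{k + 1:03d}" for k in range(S) for _ in range(m)],
            "time_block": [blocks[k] for k in range(S) for _ in range(m)],
            "minute_index": np.tile(np.arange(m), S),
            "behaviour": behaviours,
            "zone_id": zones,
            "context": context,
        },
        columns=SCAN_COLUMNS,
    )
    return frame


def generate_ratings_and_trials(
    roster: pd.DataFrame,
    truth: pd.DataFrame,
    config: GeneratorConfig,
    seed,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keeper rating sheets and novel-object trial logs.

    Ratings: per subject and trait, a latent trait level (high on the
    subject's own class, low on the other) plus independent per-rater
    noise, rounded and clipped to 1-9.  Trials: latencies around the
    subject's latent value with the within-subject share of the log-scale
    variance; the last ``n_inconsistent`` subjects get repeat sessions
    that straddle the five-minute shy cutoff.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    traits = [(f"bold_{i + 1:02d}", "bold") for i in range(config.n_bold_traits)]
    traits += [(f"shy_{i + 1:02d}", "shy") for i in range(config.n_shy_traits)]
    raters = [f"keeper_{r + 1}" for r in range(config.n_raters)]

    truth_by_id = truth.set_index("subject_id")
    inconsistent_ids = {
        r["subject_id"] for r in _extra_subject_rows(config)
    }

    rating_rows = []
    trial_rows = []
    for _, subj in roster.iterrows():
        sid = subj["subject_id"]
        pers = subj["personality"]
        for trait, tclass in traits:
            # a subject scores high on its own trait class, low on the other
            base = config.trait_high_base if tclass == pers else config.trait_low_base
            level = base + rng.normal(0.0, config.trait_spread_sd)
            for rater in raters:
                score = int(np.clip(round(level + rng.normal(0.0, config.rater_noise_sd)), 1, 9))
                rating_rows.append(
                    {"rater_id": rater, "subject_id": sid, "trait": trait,
                     "trait_class": tclass, "score": score}
                )

        t_row = truth_by_id.loc[sid]
        truth_lat = float(t_row["true_latency_s"])
        sigma = float(t_row["latency_log_sigma"])
        w = config.within_subject_sd_frac
        s_within = sigma * np.sqrt(w)

        def draw_latency() -> float:
            v = truth_lat * np.exp(rng.normal(-s_within**2 / 2.0, s_within))
            return float(np.clip(v, 0.5, None))

        pct_m, pct_sd = PCT_BOLD_TARGETS["bold" if pers == "bold" else "shy"]
        pct = float(np.clip(rng.normal(pct_m, pct_sd), 1.0, 99.0))

        plan = [("conspecific", 1), ("unknown_human", 1), ("unknown_human", 2),
                ("novel_object", 1), ("novel_object", 2)]
        for test_type, session in plan:
            if sid in inconsistent_ids and test_type == "novel_object":
                lat = float(rng.uniform(20, 120)) if session == 1 else float(rng.uniform(330, 580))
            else:
                lat = draw_latency()
            approach = np.nan if lat > 600.0 else lat
            active = float(np.clip(rng.normal(300.0, 60.0), 60.0, 590.0))
            trial_rows.append(
                {
                    "subject_id": sid,
                    "session": session,
                    "test_type": test_type,
                    "approach_s": approach,
                    "bold_s": active * pct / 100.0,
                    "shy_s": active * (100.0 - pct) / 100.0,
                }
            )

    ratings = pd.DataFrame(rating_rows)
    trials = pd.DataFrame(trial_rows)
    return ratings, trials


@dataclass
class StudyBundle:
    """All tables of one synthetic study, re-readable by the pipeline."""

    roster: pd.DataFrame
    truth: pd.DataFrame
    scans: pd.DataFrame
    ratings: pd.DataFrame
    trials: pd.DataFrame
    ethogram: pd.DataFrame
    zones: pd.DataFrame

    FILES = {
        "roster": "roster.csv",
        "truth": "truth.csv",
        "scans": "scans.csv",
        "ratings": "ratings.csv",
        "trials": "trials.csv",
        "ethogram": "ethogram.csv",
        "zones": "zones.csv",
    }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for attr, fname in self.FILES.items():
            getattr(self, attr).to_csv(out / fname, index=False)


def generate_study(config: GeneratorConfig, seed, out_dir=None) -> StudyBundle:
    """Generate a complete study; optionally write the CSV bundle.

    Fixed seed implies byte-identical output (a single generator stream is
    threaded through roster, scans, ratings and trials in a fixed order).
    """
    rng = np.random.default_rng(seed)
    roster, truth = generate_roster(config, rng)
    zone_maps = default_zone_maps(roster["enclosure_id"])
    scan_frames = [
        generate_scans(
            truth_row,
            config,
            rng,
            zone_ids=zone_maps[roster.iloc[i]["enclosure_id"]].zones,
        )
        for i, (_, truth_row) in enumerate(truth.iterrows())
    ]
    scans = pd.concat(scan_frames, ignore_index=True)
    ratings, trials = generate_ratings_and_trials(roster, truth, config, rng)
    bundle = StudyBundle(
        roster=roster,
        truth=truth.drop(columns=["latency_log_sigma"]),
        scans=scans,
        ratings=ratings,
        trials=trials,
        ethogram=DEFAULT_ETHOGRAM.to_frame(),
        zones=zone_maps_to_frame(zone_maps),
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
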