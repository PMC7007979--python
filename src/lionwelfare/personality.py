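"""Keeper-rating personality assessment and its behavioural validation.

Three keepers rate each subject on ten bold and ten shy trait adjectives
(1-9).  Ratings are averaged over raters and then over the traits of each
class; a subject whose mean bold rating exceeds 7 (and whose mean shy
rating does not) is labelled bold, mirrored for shy, and anything else is
left unclassified.  Inter-rater agreement is quantified with Cronbach's
alpha treating raters as items and subject x trait pairs as rows.  Labels
are validated (never overridden) against novel-object test behaviour:
approach latency and the percentage of bold-class focal behaviour, with a
repeat session a month later screening for trait consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError, ValidationError
from .indices import SHY_CUTOFF_S, latency_score

TRAIT_CLASSES = ("bold", "shy")
CLASSIFICATION_THRESHOLD = 7.0
RATING_COLUMNS = ["rater_id", "subject_id", "trait", "trait_class", "score"]
TRIAL_TEST_TYPES = ("conspecific", "unknown_human", "novel_object")


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    k_items: int
    n_rows: int


def cronbach_alpha(matrix) -> ReliabilityResult:
    """Cronbach's alpha of an items-in-columns matrix.

    ``matrix`` is a DataFrame or 2-D array with one column per item (here:
    rater) and one row per observation (here: subject x trait).  Uses sample
    variances:  alpha = k/(k-1) * (1 - sum(col variances) / var(row sums)).
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValidationError("Cronbach's alpha needs at least two item columns")
    if arr.shape[0] < 2:
        raise ValidationError("Cronbach's alpha needs at least two rows")
    if np.isnan(arr).any():
        raise ValidationError("Cronbach's alpha requires a complete matrix (no missing cells)")
    k = arr.shape[1]
    col_var = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedIndexError("alpha undefined: row sums have zero variance")
    alpha = k / (k - 1) * (1.0 - col_var.sum() / total_var)
    return ReliabilityResult(alpha=float(alpha), k_items=k, n_rows=arr.shape[0])


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    missing = set(RATING_COLUMNS) - set(ratings.columns)
    if missing:
        raise ValidationError(f"ratings table missing columns: {sorted(missing)}")
    bad = ~ratings["score"].between(1, 9)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"ratings row {i}: score {ratings['score'].iloc[i]} outside 1-9")
    bad = ~ratings["trait_class"].isin(TRAIT_CLASSES)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"ratings row {i}: trait_class {ratings['trait_class'].iloc[i]!r} "
            f"not in {TRAIT_CLASSES}"
        )
    dup = ratings.duplicated(subset=["rater_id", "subject_id", "trait"])
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        r = ratings.iloc[i]
        raise ValidationError(
            f"ratings row {i}: duplicate rating by {r['rater_id']!r} for "
            f"({r['subject_id']!r}, {r['trait']!r})"
        )
    return ratings


def ratings_matrix(ratings: pd.DataFrame) -> pd.DataFrame:
    """Pivot to rows = subject x trait, columns = raters (for reliability)."""
    validate_ratings(ratings)
    wide = ratings.pivot_table(
        index=["subject_id", "trait"], columns="rater_id", values="score", aggfunc="first"
    )
    if wide.isna().any().any():
        sub, trait = wide.index[wide.isna().any(axis=1)][0]
        raise ValidationError(
            f"incomplete rating sheet: missing rater score for ({sub!r}, {trait!r})"
        )
    return wide


def rater_reliability(ratings: pd.DataFrame) -> ReliabilityResult:
    """Inter-rater Cronbach's alpha over all subject x trait rows."""
    return cronbach_alpha(ratings_matrix(ratings))


def per_trait_reliability(ratings: pd.DataFrame) -> pd.DataFrame:
    """Diagnostic: alpha computed separately per trait (rows = subjects)."""
    validate_ratings(ratings)
    rows = []
    for trait, grp in ratings.groupby("trait", sort=True):
        wide = grp.pivot_table(index="subject_id", columns="rater_id", values="score")
        try:
            res = cronbach_alpha(wide)
            rows.append({"trait": trait, "alpha": res.alpha, "n_subjects": res.n_rows})
        except UndefinedIndexError:
            rows.append({"trait": trait, "alpha": np.nan, "n_subjects": len(wide)})
    return pd.DataFrame(rows)


def classify_personality(
    ratings: pd.DataFrame, threshold: float = CLASSIFICATION_THRESHOLD
) -> pd.DataFrame:
    """Subject-wise bold/shy labels from keeper ratings.

    Scores are first averaged over raters per trait, then over the traits
    of each class.  The label rule is strict: bold iff mean bold > threshold
    and mean shy <= threshold (mirrored for shy); a subject exceeding the
    threshold on both scales, or neither, stays unclassified.
    """
    validate_ratings(ratings)
    trait_class = ratings.drop_duplicates("trait").set_index("trait")["trait_class"]
    conflicting = ratings.groupby("trait")["trait_class"].nunique()
    if (conflicting > 1).any():
        t = conflicting.index[conflicting > 1][0]
        raise ValidationError(f"trait {t!r} assigned to more than one trait class")

    expected_traits = set(trait_class.index)
    rows = []
    for sid, grp in ratings.groupby("subject_id", sort=True):
        missing = expected_traits - set(grp["trait"])
        if missing:
            raise ValidationError(
                f"subject {sid!r} is missing ratings for trait {sorted(missing)[0]!r}"
            )
        per_trait = grp.groupby("trait")["score"].mean()
        mean_bold = float(per_trait[trait_class.loc[per_trait.index] == "bold"].mean())
        mean_shy = float(per_trait[trait_class.loc[per_trait.index] == "shy"].mean())
        if mean_bold > threshold and mean_shy <= threshold:
            label = "bold"
        elif mean_shy > threshold and mean_bold <= threshold:
            label = "shy"
        else:
            label = "unclassified"
        rows.append(
            {"subject_id": sid, "mean_bold": mean_bold, "mean_shy": mean_shy, "label": label}
        )
    return pd.DataFrame(rows, columns=["subject_id", "mean_bold", "mean_shy", "label"])


def percent_bold_behaviour(durations, bold_set=None, shy_set=None) -> float:
    """Percentage of classified focal time spent in bold-class behaviour.

    ``durations`` maps behaviour -> seconds; alternatively pass a mapping
    with just ``bold``/``shy`` totals (the trial-log form).  Only time in
    the two classified sets enters the denominator.
    """
    if bold_set is None or shy_set is None:
        bold_set, shy_set = {"bold"}, {"shy"}
    bold_set, shy_set = set(bold_set), set(shy_set)
    if bold_set & shy_set:
        raise ValidationError("bold and shy behaviour sets must be disjoint")
    bold_s = float(sum(v for k, v in durations.items() if k in bold_set))
    shy_s = float(sum(v for k, v in durations.items() if k in shy_set))
    if bold_s + shy_s <= 0:
        raise UndefinedIndexError("no classified focal seconds to score")
    return 100.0 * bold_s / (bold_s + shy_s)


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "session", "test_type", "approach_s"}
    missing = required - set(trials.columns)
    if missing:
        raise ValidationError(f"trials table missing columns: {sorted(missing)}")
    bad = ~trials["test_type"].isin(TRIAL_TEST_TYPES)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"trials row {i}: unknown test_type {trials['test_type'].iloc[i]!r}"
        )
    return trials


def consistency_screen(
    trials: pd.DataFrame,
    test_type: str = "novel_object",
    shy_cutoff_s: float = SHY_CUTOFF_S,
) -> pd.Series:
    """Per-subject consistency of the behavioural bold/shy categorisation.

    A subject is consistent when its repeated sessions of ``test_type``
    all agree on the shy flag (approach within the five-minute cutoff or
    not).  Subjects flagged inconsistent are excluded from downstream
    group statistics, mirroring a pre-analysis veterinary/behavioural
    screen.  Raises when any subject has fewer than two sessions.
    """
    validate_trials(trials)
    sel = trials.loc[trials["test_type"] == test_type]
    out = {}
    for sid, grp in sel.groupby("subject_id", sort=True):
        if grp["session"].nunique() < 2:
            raise ValidationError(
                f"subject {sid!r} has fewer than two {test_type!r} sessions; "
                "consistency needs a repeat"
            )
        flags = {
            latency_score(v, shy_cutoff_s=shy_cutoff_s).shy_flagged
            for v in grp["approach_s"]
        }
        out[sid] = len(flags) == 1
    return pd.Series(out, name="consistent")


def build_profiles(
    ratings: pd.DataFrame,
    trials: pd.DataFrame,
    threshold: float = CLASSIFICATION_THRESHOLD,
) -> pd.DataFrame:
    """Full personality profile table: keeper means, label, behavioural
    validation metrics (per-test mean latency, % bold behaviour) and the
    consistency flag."""
    profiles = classify_personality(ratings, threshold)
    validate_trials(trials)
    consistent = consistency_screen(trials)

    lat_rows = {}
    for sid, grp in trials.groupby("subject_id", sort=True):
        row = {}
        for tt in TRIAL_TEST_TYPES:
            sel = grp.loc[grp["test_type"] == tt, "approach_s"]
            if sel.empty:
                row[f"latency_{tt}"] = np.nan
            else:
                row[f"latency_{tt}"] = float(
                    np.mean([latency_score(v).latency_s for v in sel])
                )
        if {"bold_s", "shy_s"} <= set(grp.columns) and grp[["bold_s", "shy_s"]].notna().any().any():
            durations = {
                "bold": float(grp["bold_s"].fillna(0).sum()),
                "shy": float(grp["shy_s"].fillna(0).sum()),
            }
            row["pct_bold_behaviour"] = percent_bold_behaviour(durations)
        else:
            row["pct_bold_behaviour"] = np.nan
        lat_rows[sid] = row

    extra = pd.DataFrame.from_dict(lat_rows, orient="index")
    extra.index.name = "subject_id"
    profiles = profiles.merge(extra.reset_index(), on="subject_id", how="left")
    profiles = profiles.merge(
        consistent.rename_axis("subject_id").reset_index(), on="subject_id", how="left"
    )
    profiles["consistent"] = profiles["consistent"].fillna(True).astype(bool)
    return profiles
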