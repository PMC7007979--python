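"""Subject roster: domain type, validation, CSV I/O and the default study roster.

The default roster describes a 35-subject Asiatic lion
conservation-breeding study population: sex (14 M / 21 F), origin
(16 captive-raised / 19 wild-rescued), housing sex-ratio (17 pair-housed /
18 group-housed), enclosure size, age in days, age class and keeper-assessed
personality (21 bold / 14 shy).  It doubles as the default composition of
the synthetic-study generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

SEXES = ("M", "F")
ORIGINS = ("captive_raised", "wild_rescued")
GROUPINGS = ("pair_housed", "group_housed")
AGE_CLASSES = ("sub", "prime", "old")
PERSONALITIES = ("bold", "shy", "unclassified")

ROSTER_COLUMNS = [
    "subject_id",
    "name",
    "sex",
    "origin",
    "social_grouping",
    "enclosure_id",
    "enclosure_area",
    "age_days",
    "age_class",
    "personality",
]


@dataclass(frozen=True)
class Subject:
    subject_id: str
    name: str
    sex: str
    origin: str
    social_grouping: str
    enclosure_id: str
    enclosure_area: float
    age_days: float
    age_class: str
    personality: str = "unclassified"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"{self.subject_id}: sex must be one of {SEXES}")
        if self.origin not in ORIGINS:
            raise ValidationError(f"{self.subject_id}: origin must be one of {ORIGINS}")
        if self.social_grouping not in GROUPINGS:
            raise ValidationError(f"{self.subject_id}: social_grouping must be one of {GROUPINGS}")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(f"{self.subject_id}: age_class must be one of {AGE_CLASSES}")
        if self.personality not in PERSONALITIES:
            raise ValidationError(f"{self.subject_id}: personality must be one of {PERSONALITIES}")
        if not self.enclosure_area > 0:
            raise ValidationError(f"{self.subject_id}: enclosure_area must be > 0")
        if not self.age_days > 0:
            raise ValidationError(f"{self.subject_id}: age_days must be > 0")


# (name, sex, origin C/W, housing sex-ratio, enclosure m^2, age days, age class, personality)
_DEFAULT_ROSTER_ROWS = [
    ("A1", "M", "W", "1:1", 1300, 3414.00, "old", "shy"),
    ("Aftab", "M", "W", "1:1", 1200, 3500.00, "old", "bold"),
    ("Amal", "M", "C", "1:2", 1576, 2214.74, "prime", "bold"),
    ("Ambica", "F", "C", "0:2", 1123, 3984.56, "old", "bold"),
    ("Amiya", "F", "C", "0:2", 1123, 2037.56, "prime", "bold"),
    ("Ani", "F", "W", "1:1", 1600, 1946.00, "prime", "shy"),
    ("Bahadur", "M", "C", "1:2", 1600, 653.33, "sub", "bold"),
    ("Bigtwin", "F", "W", "1:2", 1600, 800.33, "sub", "shy"),
    ("Dharicub", "M", "W", "1:2", 1100, 619.50, "sub", "bold"),
    ("Dheer", "M", "W", "2:0", 1600, 5389.08, "old", "bold"),
    ("Gina", "F", "C", "1:1", 1100, 1316.90, "prime", "shy"),
    ("Girm", "M", "W", "1:1", 1123, 3337.92, "old", "bold"),
    ("Hemal", "M", "W", "1:2", 1700, 2029.00, "prime", "shy"),
    ("Hemali", "F", "W", "1:2", 1271, 2149.00, "prime", "shy"),
    ("Jenifer", "F", "C", "1:1", 1700, 1491.33, "prime", "bold"),
    ("Jesal", "M", "W", "1:2", 1300, 5722.18, "old", "bold"),
    ("Maheswari", "F", "C", "1:2", 1300, 3411.26, "old", "bold"),
    ("Mariyam", "F", "C", "1:2", 1300, 3423.35, "old", "bold"),
    ("Maytri", "F", "C", "1:1", 1123, 3072.90, "old", "bold"),
    ("Nagraj", "M", "W", "1:2", 6542, 3227.00, "old", "shy"),
    ("Patvad", "F", "W", "1:1", 1200, 3729.00, "old", "shy"),
    ("Patvadm", "M", "W", "1:1", 1271, 1537.00, "prime", "shy"),
    ("Radha", "F", "C", "1:2", 1576, 1291.30, "prime", "bold"),
    ("Rani", "F", "C", "1:2", 1576, 1291.30, "prime", "bold"),
    ("Ranita", "F", "C", "1:2", 6542, 2119.00, "prime", "bold"),
    ("Ranshi", "F", "W", "1:2", 6542, 5109.00, "old", "shy"),
    ("Rudi", "F", "W", "1:1", 1600, 4700.00, "old", "shy"),
    ("Smt", "F", "W", "1:2", 1600, 800.33, "sub", "shy"),
    ("Subhi", "F", "C", "1:1", 1700, 2240.33, "prime", "shy"),
    ("Sujan", "F", "W", "1:1", 1300, 2790.80, "prime", "shy"),
    ("Taukir", "M", "C", "1:1", 1303, 2448.00, "prime", "bold"),
    ("Teeta", "F", "C", "1:2", 1700, 2166.93, "prime", "bold"),
    ("Tejaswini", "F", "C", "1:2", 1700, 4320.93, "old", "bold"),
    ("Trakuda", "M", "W", "1:2", 1700, 3956.93, "old", "bold"),
    ("Veer", "M", "W", "2:0", 1600, 5387.30, "old", "bold"),
]

_ORIGIN_CODE = {"C": "captive_raised", "W": "wild_rescued"}


def _grouping_from_ratio(ratio: str) -> str:
    # 1:2 sex-ratio housing is a trio; everything else (1:1, 2:0, 0:2) a pair
    return "group_housed" if ratio == "1:2" else "pair_housed"


def default_roster() -> pd.DataFrame:
    """The 35-subject study roster as a validated DataFrame."""
    rows = []
    for i, (name, sex, origin, ratio, area, age, age_class, pers) in enumerate(
        _DEFAULT_ROSTER_ROWS, start=1
    ):
        rows.append(
            {
                "subject_id": name.lower(),
                "name": name,
                "sex": sex,
                "origin": _ORIGIN_CODE[origin],
                "social_grouping": _grouping_from_ratio(ratio),
                "enclosure_id": f"en{i:02d}",
                "enclosure_area": float(area),
                "age_days": float(age),
                "age_class": age_class,
                "personality": pers,
            }
        )
    frame = pd.DataFrame(rows, columns=ROSTER_COLUMNS)
    validate_roster(frame)
    return frame


def validate_roster(frame: pd.DataFrame) -> list[Subject]:
    """Validate a roster table row-by-row; returns the Subject objects."""
    missing = set(ROSTER_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"roster missing columns: {sorted(missing)}")
    if frame["subject_id"].duplicated().any():
        dupes = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject ids in roster: {dupes}")
    subjects = []
    for i, row in frame.iterrows():
        try:
            subjects.append(Subject(**{c: row[c] for c in ROSTER_COLUMNS}))
        except ValidationError as exc:
            raise ValidationError(f"roster row {i}: {exc}") from exc
    return subjects


def read_roster(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    validate_roster(frame)
    return frame


def write_roster(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
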