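"""End-to-end welfare study: model object, fitted results, report bundle.

:class:`WelfareStudy` holds the validated input tables (roster, scans,
keeper ratings, trial logs, ethogram, zone maps); :meth:`WelfareStudy.fit`
runs the full pipeline -- personality profiles, the four welfare indices,
the consistency-screen exclusions, group comparisons, the index
correlation matrix and the diversity regression -- and returns a
:class:`WelfareStudyResults` carrying the estimates and diagnostics, with
``summary()`` rendering the familiar report tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .ethogram import DEFAULT_ETHOGRAM, Ethogram, ZoneMap, default_zone_maps, read_zone_maps, zone_maps_to_frame
from .indices import DEFAULT_EXCLUSION_FLAGS, DEFAULT_PERSISTENCE, compute_indices
from .personality import build_profiles, per_trait_reliability, rater_reliability
from .roster import read_roster, validate_roster
from .scans import read_scan_table, validate_scans
from .stats import (
    FACTORS,
    INDEX_NAMES,
    compare_all,
    correlation_matrix,
    normality_screen,
    ols_fit,
)

CORRELATION_VARIABLES = ("spi", "swi", "arb_percent", "latency_s", "age_days", "enclosure_area")

#: column order contract for the comparison report
COMPARISON_GRID_COLUMNS = [
    "factor",
    "index",
    "group_a",
    "summary_a",
    "group_b",
    "summary_b",
    "test",
    "statistic",
    "df",
    "p",
    "cohens_d",
    "direction",
]


class WelfareStudy:
    """A behavioural welfare study ready to be fitted.

    Parameters
    ----------
    roster, scans, ratings, trials
        Validated input tables (see the CSV schemas in the module docs).
    ethogram
        Behaviour classification; defaults to the felid ethogram.
    zone_maps
        enclosure_id -> :class:`ZoneMap`; defaults to ten equal zones per
        enclosure in the roster.
    """

    def __init__(
        self,
        roster: pd.DataFrame,
        scans: pd.DataFrame,
        ratings: pd.DataFrame,
        trials: pd.DataFrame,
        ethogram: Ethogram = DEFAULT_ETHOGRAM,
        zone_maps: dict[str, ZoneMap] | None = None,
    ) -> None:
        validate_roster(roster)
        self.roster = roster
        self.ethogram = ethogram
        self.zone_maps = zone_maps or default_zone_maps(roster["enclosure_id"])
        self.scans = validate_scans(scans, ethogram, self.zone_maps, roster)
        self.ratings = ratings
        self.trials = trials
        self.input_digests: dict[str, str] = {}

    @classmethod
    def from_dir(cls, path) -> "WelfareStudy":
        """Load a study from a directory of CSV tables.

        Expects roster.csv, scans.csv, ratings.csv and trials.csv;
        ethogram.csv and zones.csv are optional (defaults used when absent).
        """
        p = Path(path)
        ethogram = (
            Ethogram.read_csv(p / "ethogram.csv")
            if (p / "ethogram.csv").exists()
            else DEFAULT_ETHOGRAM
        )
        zone_maps = read_zone_maps(p / "zones.csv") if (p / "zones.csv").exists() else None
        roster = read_roster(p / "roster.csv")
        scans = read_scan_table(p / "scans.csv", ethogram)
        ratings = pd.read_csv(p / "ratings.csv")
        trials = pd.read_csv(p / "trials.csv")
        study = cls(roster, scans, ratings, trials, ethogram, zone_maps)
        for name in ("roster", "scans", "ratings", "trials", "ethogram", "zones"):
            f = p / f"{name}.csv"
            if f.exists():
                study.input_digests[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        return study

    def fit(
        self,
        persistence: int = DEFAULT_PERSISTENCE,
        exclusion_flags=DEFAULT_EXCLUSION_FLAGS,
        threshold: float = 7.0,
        equal_var: bool = True,
        d_method: str = "rms",
        exclude_inconsistent: bool = True,
        include_events: bool = True,
    ) -> "WelfareStudyResults":
        """Run the full analysis and return the fitted results.

        Indices are computed for every rostered subject; subjects failing
        the trait-consistency screen are then excluded before the group
        statistics, and personality contrasts use the keeper-derived
        labels.
        """
        profiles = build_profiles(self.ratings, self.trials, threshold=threshold)
        reliability = rater_reliability(self.ratings)
        indices = compute_indices(
            self.scans,
            self.roster,
            self.zone_maps,
            self.ethogram,
            self.trials,
            persistence=persistence,
            exclusion_flags=exclusion_flags,
            include_events=include_events,
        )

        table = self.roster.merge(
            indices, on="subject_id", how="inner", validate="one_to_one"
        ).merge(
            profiles[["subject_id", "mean_bold", "mean_shy", "label", "consistent"]],
            on="subject_id",
            how="left",
        )
        # keeper-derived label drives the personality factor; the roster
        # column is retained as 'personality_roster' for reference
        table = table.rename(columns={"personality": "personality_roster"})
        table["personality"] = table["label"].fillna("unclassified")
        table["consistent"] = table["consistent"].fillna(True).astype(bool)

        excluded = tuple(table.loc[~table["consistent"], "subject_id"])
        analysis = table.loc[table["consistent"]].reset_index(drop=True)
        if len(analysis) < 4:
            raise ValidationError("fewer than four consistent subjects; nothing to compare")

        normality = normality_screen(
            analysis,
            columns=list(INDEX_NAMES),
            factors=analysis[list(FACTORS)],
        )
        comparisons = compare_all(
            analysis, equal_var=equal_var, d_method=d_method
        )
        correlations = correlation_matrix(analysis, CORRELATION_VARIABLES)
        regression = ols_fit(analysis, response="swi", predictors=("spi", "arb_percent"))

        manifest = {
            "tool": "lionwelfare",
            "version": __version__,
            "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
            "input_digests": self.input_digests,
            "config": {
                "persistence": persistence,
                "exclusion_flags": sorted(exclusion_flags),
                "threshold": threshold,
                "equal_var": equal_var,
                "d_method": d_method,
                "exclude_inconsistent": exclude_inconsistent,
                "include_events": include_events,
            },
            "n_subjects_input": int(len(self.roster)),
            "n_subjects_analysed": int(len(analysis)),
            "excluded_subjects": list(excluded),
            "inter_rater_alpha": reliability.alpha,
        }
        return WelfareStudyResults(
            model=self,
            profiles=profiles,
            indices=indices,
            analysis_table=analysis,
            excluded_subjects=excluded,
            normality=normality,
            comparisons=comparisons,
            correlations=correlations,
            regression=regression,
            reliability=reliability,
            manifest=manifest,
        )


@dataclass
class WelfareStudyResults:
    """Fitted study: per-subject estimates, group statistics, diagnostics."""

    model: WelfareStudy = field(repr=False)
    profiles: pd.DataFrame
    indices: pd.DataFrame
    analysis_table: pd.DataFrame
    excluded_subjects: tuple[str, ...]
    normality: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: object
    regression: object
    reliability: object
    manifest: dict

    def summarize_comparisons(self) -> pd.DataFrame:
        """Comparison grid: 4 factors x 4 indices with mean +/- sd cells."""
        rows = []
        for _, r in self.comparisons.iterrows():
            skipped = str(r["test"]).startswith("skipped")

            def cell(mean, sd):
                return "" if skipped else f"{mean:.2f} ± {sd:.2f}"

            rows.append(
                {
                    "factor": r["factor"],
                    "index": r["index"],
                    "group_a": r["group_a"],
                    "summary_a": cell(r["mean_a"], r["sd_a"]),
                    "group_b": r["group_b"],
                    "summary_b": cell(r["mean_b"], r["sd_b"]),
                    "test": r["test"],
                    "statistic": np.nan if skipped else round(float(r["statistic"]), 4),
                    "df": r["df"],
                    "p": r["p"],
                    "cohens_d": r["cohens_d"],
                    "direction": r["direction"],
                }
            )
        return pd.DataFrame(rows, columns=COMPARISON_GRID_COLUMNS)

    def summary(self) -> str:
        """Human-readable report of the fitted study."""
        lines = []
        n = self.manifest["n_subjects_analysed"]
        lines.append(f"Welfare study summary ({n} subjects analysed, "
                     f"{len(self.excluded_subjects)} excluded by consistency screen)")
        lines.append(f"Inter-rater reliability (Cronbach's alpha): "
                     f"{self.reliability.alpha:.3f} over {self.reliability.k_items} raters")
        lines.append("")
        lines.append("Group comparisons (welfare index by factor):")
        lines.append(self.summarize_comparisons().to_string(index=False))
        lines.append("")
        lines.append("Pearson correlations between indices (and age, enclosure size):")
        lines.append(self.correlations.r.round(3).to_string())
        reg = self.regression
        lines.append("")
        coefs = reg.coefficients["estimate"]
        eq = f"swi = {coefs['const']:.3f}"
        for name in reg.predictors:
            eq += f" + ({coefs[name]:.3f}) x {name}"
        lines.append("Diversity regression: " + eq)
        lines.append(
            f"  R^2 = {reg.r_squared:.3f}, F({reg.f_df[0]}, {reg.f_df[1]}) = "
            f"{reg.f_statistic:.2f}, p = {reg.f_p:.2g}, DW = {reg.durbin_watson:.2f}"
        )
        lines.append(f"  VIF: " + ", ".join(f"{k} = {v:.2f}" for k, v in reg.vif.items()))
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write the report bundle (floats at 4 decimal places)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.4f"
        self.profiles.to_csv(out / "profiles.csv", index=False, float_format=fmt)
        self.indices.to_csv(out / "indices.csv", index=False, float_format=fmt)
        self.comparisons.to_csv(out / "comparisons.csv", index=False, float_format=fmt)
        corr = self.correlations.r.round(4)
        corr.to_csv(out / "correlations.csv")
        with open(out / "regression.json", "w") as fh:
            json.dump(self.regression.as_dict(), fh, indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)

    def plot_correlations(self, path=None):
        """Optional scatter-matrix of the welfare indices (matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        axes = pd.plotting.scatter_matrix(
            self.analysis_table[list(INDEX_NAMES)], figsize=(8, 8), diagonal="hist"
        )
        fig = axes[0, 0].get_figure()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def run_pipeline(input_dir, out_dir, **fit_kwargs) -> WelfareStudyResults:
    """Load a study directory, fit it, and write the report bundle."""
    study = WelfareStudy.from_dir(input_dir)
    results = study.fit(**fit_kwargs)
    results.save(out_dir)
    return results
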