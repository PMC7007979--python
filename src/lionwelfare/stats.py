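"""Group comparisons, correlations and the welfare-index regression.

Conventions follow common practice in applied ethology reports:

* two-group contrasts use the pooled-variance Student t (df = n1 + n2 - 2)
  for indices screened as normal, with an unequal-variance (Welch) variant
  available behind ``equal_var=False``;
* latency contrasts use the two-sample Kolmogorov-Smirnov test, reported
  as z = D * sqrt(n1*n2/(n1+n2)) with the asymptotic two-sided p;
* effect sizes are Cohen's d standardised by the root-mean-square of the
  two group SDs (``sqrt((s1^2 + s2^2)/2)``) and reported as magnitudes
  with an explicit direction field; the pooled-SD variant is available;
* no multiple-testing correction is applied by default (a Holm-adjusted
  column can be requested).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

from .errors import UndefinedIndexError, ValidationError

FACTORS = ("personality", "origin", "sex", "social_grouping")
INDEX_NAMES = ("spi", "swi", "arb_percent", "latency_s")


@dataclass(frozen=True)
class GroupSummary:
    """(n, mean, sd) summary of one group on one index."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise ValidationError(f"group {self.label!r}: sd must be >= 0")

    @classmethod
    def from_sample(cls, label: str, sample) -> "GroupSummary":
        x = np.asarray(sample, dtype=float)
        return cls(label=label, n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


def combine_summaries(*groups: GroupSummary, label: str = "combined") -> GroupSummary:
    """Exact pooled (n, mean, sd) of several disjoint groups."""
    n = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n
    ss = sum((g.n - 1) * g.sd**2 + g.n * (g.mean - mean) ** 2 for g in groups)
    return GroupSummary(label=label, n=n, mean=mean, sd=float(np.sqrt(ss / (n - 1))))


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group test on one welfare index for one grouping factor."""

    index_name: str
    factor: str
    group_a: GroupSummary
    group_b: GroupSummary
    statistic: float  # |t| or KS z
    df: float | None
    p: float
    cohens_d: float
    test: str  # "pooled_t" | "welch_t" | "ks"
    direction: str  # label of the group with the larger mean
    ks_d: float | None = None

    def as_row(self) -> dict:
        return {
            "index": self.index_name,
            "factor": self.factor,
            "group_a": self.group_a.label,
            "n_a": self.group_a.n,
            "mean_a": self.group_a.mean,
            "sd_a": self.group_a.sd,
            "group_b": self.group_b.label,
            "n_b": self.group_b.n,
            "mean_b": self.group_b.mean,
            "sd_b": self.group_b.sd,
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "cohens_d": self.cohens_d,
            "direction": self.direction,
        }


def _as_summary(g, label: str) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    return GroupSummary.from_sample(label, g)


def pooled_t_test(
    a,
    b,
    index_name: str = "",
    factor: str = "",
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sample t-test from raw samples or (n, mean, sd) summaries.

    The default is the pooled-variance Student form with
    df = n1 + n2 - 2; ``equal_var=False`` gives the Welch form with
    Satterthwaite df.  The statistic is reported as a magnitude with
    ``direction`` naming the larger-mean group.
    """
    ga, gb = _as_summary(a, "a"), _as_summary(b, "b")
    diff = ga.mean - gb.mean
    if equal_var:
        df = ga.n + gb.n - 2
        sp2 = ((ga.n - 1) * ga.sd**2 + (gb.n - 1) * gb.sd**2) / df
        if sp2 == 0:
            if diff == 0:
                t = 0.0
            else:
                raise UndefinedIndexError(
                    "pooled variance is zero with unequal means; t undefined"
                )
        else:
            t = diff / np.sqrt(sp2 * (1.0 / ga.n + 1.0 / gb.n))
        test = "pooled_t"
    else:
        va, vb = ga.sd**2 / ga.n, gb.sd**2 / gb.n
        if va + vb == 0:
            if diff == 0:
                t, df = 0.0, ga.n + gb.n - 2
            else:
                raise UndefinedIndexError("zero variance with unequal means; t undefined")
        else:
            t = diff / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (ga.n - 1) + vb**2 / (gb.n - 1))
        test = "welch_t"
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(
        index_name=index_name,
        factor=factor,
        group_a=ga,
        group_b=gb,
        statistic=abs(float(t)),
        df=float(df),
        p=float(p),
        cohens_d=cohens_d_rms(ga, gb),
        test=test,
        direction=ga.label if diff >= 0 else gb.label,
    )


def cohens_d_rms(a, b) -> float:
    """|mean difference| / RMS of the two group SDs.

    This average-SD standardiser (sqrt((s1^2+s2^2)/2)) is the package
    default; see :func:`cohens_d` for the pooled-SD variant.
    """
    return cohens_d(a, b, method="rms")


def cohens_d(a, b, method: str = "rms") -> float:
    ga, gb = _as_summary(a, "a"), _as_summary(b, "b")
    if ga.sd == 0 and gb.sd == 0:
        raise UndefinedIndexError("effect size undefined: both group SDs are zero")
    if method == "rms":
        denom = np.sqrt((ga.sd**2 + gb.sd**2) / 2.0)
    elif method == "pooled":
        denom = np.sqrt(
            ((ga.n - 1) * ga.sd**2 + (gb.n - 1) * gb.sd**2) / (ga.n + gb.n - 2)
        )
    else:
        raise ValueError(f"unknown effect-size method {method!r}")
    return float(abs(ga.mean - gb.mean) / denom)


def ks_test(a, b, index_name: str = "", factor: str = "", labels=("a", "b")) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov test on raw samples.

    D is the supremum difference of the two empirical CDFs; the normal-
    approximation statistic z = D * sqrt(n1*n2/(n1+n2)) is reported with
    the asymptotic (Kolmogorov) two-sided p-value.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValidationError("KS test needs at least two observations per group")
    d = float(sps.ks_2samp(xa, xb, method="asymp").statistic)
    en = np.sqrt(xa.size * xb.size / (xa.size + xb.size))
    z = d * en
    p = float(sps.kstwobign.sf(z))
    ga = GroupSummary.from_sample(labels[0], xa)
    gb = GroupSummary.from_sample(labels[1], xb)
    return ComparisonResult(
        index_name=index_name,
        factor=factor,
        group_a=ga,
        group_b=gb,
        statistic=float(z),
        df=None,
        p=p,
        cohens_d=cohens_d_rms(ga, gb),
        test="ks",
        direction=ga.label if ga.mean >= gb.mean else gb.label,
        ks_d=d,
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    degenerate: tuple[str, ...] = ()


def correlation_matrix(table: pd.DataFrame, variables=None) -> CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p-values.

    Constant columns are flagged as degenerate (r undefined, NaN) rather
    than silently zero.
    """
    if variables is None:
        variables = tuple(table.columns)
    data = table[list(variables)].astype(float)
    if len(data) < 3:
        raise ValidationError("correlation matrix needs at least 3 complete rows")
    if data.isna().any().any():
        raise ValidationError("correlation matrix requires complete rows")
    degenerate = tuple(c for c in variables if data[c].nunique() == 1)
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = variables[i], variables[j]
            if vi in degenerate or vj in degenerate:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = sps.pearsonr(data[vi], data[vj])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    if degenerate:
        warnings.warn(
            f"constant columns with undefined correlations: {degenerate}", stacklevel=2
        )
    rdf = pd.DataFrame(r, index=list(variables), columns=list(variables))
    pdf = pd.DataFrame(p, index=list(variables), columns=list(variables))
    return CorrelationMatrix(tuple(variables), rdf, pdf, n=len(data), degenerate=degenerate)


def r2_from_correlations(r_y1: float, r_y2: float, r_12: float) -> float:
    """R-squared of a two-predictor linear model from pairwise correlations.

    R^2 = (r_y1^2 + r_y2^2 - 2 r_y1 r_y2 r_12) / (1 - r_12^2).
    """
    for r in (r_y1, r_y2, r_12):
        if abs(r) > 1:
            raise ValidationError(f"correlation {r} outside [-1, 1]")
    if 1.0 - r_12**2 <= 0:
        raise UndefinedIndexError("predictors perfectly collinear (r_12 = +/-1)")
    return (r_y1**2 + r_y2**2 - 2.0 * r_y1 * r_y2 * r_12) / (1.0 - r_12**2)


@dataclass
class RegressionResult:
    """Least-squares fit of one welfare index on others, with diagnostics."""

    response: str
    predictors: tuple[str, ...]
    coefficients: pd.DataFrame  # index: const + predictors; columns: estimate, std_error, t, p
    r_squared: float
    f_statistic: float
    f_df: tuple[int, int]
    f_p: float
    durbin_watson: float
    vif: dict[str, float]
    n: int
    sm_results: object = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "coefficients": {
                name: {
                    "estimate": float(row["estimate"]),
                    "std_error": float(row["std_error"]),
                    "t": float(row["t"]),
                    "p": float(row["p"]),
                }
                for name, row in self.coefficients.iterrows()
            },
            "r_squared": float(self.r_squared),
            "f_statistic": float(self.f_statistic),
            "f_df": list(self.f_df),
            "f_p": float(self.f_p),
            "durbin_watson": float(self.durbin_watson),
            "vif": {k: float(v) for k, v in self.vif.items()},
            "n": int(self.n),
        }


def ols_fit(table: pd.DataFrame, response: str, predictors) -> RegressionResult:
    """OLS of ``response`` on ``predictors`` with the standard diagnostics.

    VIFs are computed on the design before fitting (a VIF above 10 emits a
    collinearity warning); the Durbin-Watson statistic is evaluated on
    residuals in table (roster) order.
    """
    predictors = tuple(predictors)
    data = table[[response, *predictors]].astype(float)
    if data.isna().any().any():
        raise ValidationError("regression table has missing values")
    if len(data) < len(predictors) + 2:
        raise ValidationError("too few rows for the requested regression")
    X = sm.add_constant(data[list(predictors)], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("rank-deficient design matrix")

    vif = {}
    if len(predictors) >= 2:
        for i, name in enumerate(predictors):
            vif[name] = float(variance_inflation_factor(X.to_numpy(), i + 1))
    else:
        vif = {predictors[0]: 1.0}
    high = {k: v for k, v in vif.items() if v > 10}
    if high:
        warnings.warn(f"high collinearity (VIF > 10): {high}", stacklevel=2)

    res = sm.OLS(data[response], X).fit()
    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "std_error": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    return RegressionResult(
        response=response,
        predictors=predictors,
        coefficients=coef,
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_df=(int(res.df_model), int(res.df_resid)),
        f_p=float(res.f_pvalue),
        durbin_watson=float(durbin_watson(res.resid)),
        vif=vif,
        n=int(res.nobs),
        sm_results=res,
    )


def normality_screen(
    table: pd.DataFrame, columns=None, factors: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Shapiro-Wilk per column plus Levene's test per factor split.

    Advisory only: in the analysis pipeline the latency index is routed to
    the KS test regardless, matching standard practice for right-skewed
    approach latencies.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for col in columns:
        x = table[col].dropna().astype(float)
        if x.nunique() <= 1:
            rows.append(
                {"column": col, "factor": None, "test": "shapiro", "statistic": np.nan,
                 "p": np.nan, "note": "degenerate (constant)"}
            )
            continue
        if len(x) < 3:
            raise ValidationError(f"normality screen needs n >= 3 for {col!r}")
        w, p = sps.shapiro(x)
        rows.append(
            {"column": col, "factor": None, "test": "shapiro", "statistic": float(w),
             "p": float(p), "note": ""}
        )
        if factors is not None:
            for fac in factors.columns:
                groups = [
                    g.astype(float).to_numpy()
                    for _, g in table[col].groupby(factors[fac])
                    if len(g) >= 2
                ]
                if len(groups) < 2:
                    continue
                stat, lp = sps.levene(*groups)
                rows.append(
                    {"column": col, "factor": fac, "test": "levene",
                     "statistic": float(stat), "p": float(lp), "note": ""}
                )
    return pd.DataFrame(rows)


#: factor level -> (group_a, group_b) ordering used in reports
FACTOR_LEVELS = {
    "personality": ("bold", "shy"),
    "origin": ("captive_raised", "wild_rescued"),
    "sex": ("M", "F"),
    "social_grouping": ("pair_housed", "group_housed"),
}


def compare_all(
    table: pd.DataFrame,
    factors=FACTORS,
    index_names=INDEX_NAMES,
    equal_var: bool = True,
    d_method: str = "rms",
    holm: bool = False,
) -> pd.DataFrame:
    """All two-group contrasts: each welfare index by each grouping factor.

    ``table`` carries one row per subject with the index columns plus the
    factor label columns.  SPI, SWI and ARB% use the t-test; latency uses
    the KS test.  A factor level with fewer than two subjects skips that
    comparison with a warning.  Returns a tidy report with one row per
    index x factor.
    """
    rows = []
    for factor in factors:
        if factor not in table.columns:
            raise ValidationError(f"missing factor column {factor!r}")
        levels = FACTOR_LEVELS.get(factor)
        if levels is None:
            levels = tuple(sorted(table[factor].dropna().unique()))[:2]
        la, lb = levels
        sub = table.loc[table[factor].isin(levels)]
        na = int((sub[factor] == la).sum())
        nb = int((sub[factor] == lb).sum())
        if na < 2 or nb < 2:
            warnings.warn(
                f"factor {factor!r}: level with n < 2; comparisons skipped", stacklevel=2
            )
            for index_name in index_names:
                rows.append(
                    {"index": index_name, "factor": factor, "group_a": la, "group_b": lb,
                     "n_a": na, "n_b": nb, "test": "skipped (n<2)", "statistic": np.nan,
                     "df": np.nan, "p": np.nan, "cohens_d": np.nan, "direction": "",
                     "mean_a": np.nan, "sd_a": np.nan, "mean_b": np.nan, "sd_b": np.nan}
                )
            continue
        xa_all = sub.loc[sub[factor] == la]
        xb_all = sub.loc[sub[factor] == lb]
        for index_name in index_names:
            xa = xa_all[index_name].astype(float).to_numpy()
            xb = xb_all[index_name].astype(float).to_numpy()
            if index_name == "latency_s":
                result = ks_test(xa, xb, index_name, factor, labels=(la, lb))
            else:
                result = pooled_t_test(
                    GroupSummary.from_sample(la, xa),
                    GroupSummary.from_sample(lb, xb),
                    index_name,
                    factor,
                    equal_var=equal_var,
                )
            row = result.as_row()
            row["cohens_d"] = cohens_d(result.group_a, result.group_b, method=d_method)
            rows.append(row)
    report = pd.DataFrame(rows)
    if holm:
        mask = report["p"].notna()
        from statsmodels.stats.multitest import multipletests

        adj = np.full(len(report), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(report.loc[mask, "p"], method="holm")[1]
        report["p_holm"] = adj
    return report
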