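"""Group statistics for hierarchical vascular-metric panels.

The study design is two glycemia groups of animals, each contributing
several imaging fields (Z-stacks) per retina per eccentricity band.  To
keep heavily imaged retinas from dominating, measurements are aggregated
hierarchically (stack -> retina x eccentricity -> animal) before testing.

Tests implemented:

* Welch's unequal-variance t (from raw samples or printed mean/SD/n
  summaries — the two routes agree exactly by construction);
* two-way between-subjects ANOVA with Type III sums of squares and
  sum-to-zero contrasts, from raw data (statsmodels) or from cell
  summaries (weighted cell-mean regression, authored here);
* Tukey-Kramer studentized-range post-hoc comparisons;
* Pearson correlation with simple linear regression;
* the Wald-Wolfowitz runs test on residual signs (exact enumeration for
  n <= 20, continuity-corrected normal approximation above);
* glycemic severity summaries of a weekly blood-glucose series.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "GroupSummary",
    "GroupStatResult",
    "AggregationPlan",
    "aggregate",
    "welch_from_summary",
    "welch_from_raw",
    "two_way_anova",
    "two_way_anova_from_summary",
    "tukey_kramer",
    "pearson_linreg",
    "runs_test",
    "runs_pmf",
    "severity_measures",
]

AGE_BINS = ("<20", "20-30", "30-40", "40-50", ">50")
AGE_EPOCHS = ("young_adult", "middle_aged")  # <=30 weeks / >30 weeks


@dataclass
class GroupSummary:
    """Sample size, mean and sample SD (n-1 denominator) of one group."""

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
    def from_samples(cls, label: str, values: np.ndarray) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValidationError(f"group {label!r}: need >= 2 samples")
        return cls(label, int(v.size), float(v.mean()), float(v.std(ddof=1)))


@dataclass
class GroupStatResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    comparison: str = ""
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Hierarchical aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregationPlan:
    """Hierarchy and binning used before group tests.

    Z-stacks from the same retina in the same eccentricity band are
    averaged into one value; whole-animal analyses then average those
    band values per animal.  Ages are binned in 10-week bands and into
    the two epochs young adult (<= 30 weeks) and middle-aged (> 30 weeks).
    """

    age_bin_edges: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)
    age_epoch_cut: float = 30.0

    def age_bin(self, weeks: float) -> str:
        for edge, label in zip(self.age_bin_edges, AGE_BINS):
            if weeks < edge:
                return label
        return AGE_BINS[-1]

    def age_epoch(self, weeks: float) -> str:
        return AGE_EPOCHS[0] if weeks <= self.age_epoch_cut else AGE_EPOCHS[1]


def aggregate(
    measurements: pd.DataFrame,
    plan: AggregationPlan | None = None,
    value: str = "value",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage hierarchical mean of a per-stack measurement table.

    Expects columns ``animal_id``, ``eccentricity_mm``, ``age_weeks`` and
    the value column (plus optionally ``glycemia_group``, carried along).
    Returns ``(per_band, per_animal)``: the within retina x eccentricity
    mean and the per-animal mean of those band means — not the pooled
    mean, so unequal stack counts cannot bias an animal's value.
    """
    plan = plan or AggregationPlan()
    required = ["animal_id", "eccentricity_mm", "age_weeks", value]
    for col in required:
        if col not in measurements.columns:
            raise ValidationError(f"aggregate: missing column {col!r}")
        bad = measurements.index[measurements[col].isna()]
        if len(bad):
            raise ValidationError(
                f"aggregate: row {bad[0]} is missing {col!r}"
            )
    carry = [c for c in ("glycemia_group",) if c in measurements.columns]
    keys = ["animal_id", "eccentricity_mm"]
    per_band = (
        measurements.groupby(keys + carry + ["age_weeks"], as_index=False)[value]
        .mean()
    )
    per_animal = (
        per_band.groupby(["animal_id"] + carry + ["age_weeks"], as_index=False)[
            value
        ].mean()
    )
    per_animal["age_bin"] = per_animal["age_weeks"].map(plan.age_bin)
    per_animal["age_epoch"] = per_animal["age_weeks"].map(plan.age_epoch)
    return per_band, per_animal


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_from_summary(a: GroupSummary, b: GroupSummary) -> GroupStatResult:
    """Unpaired two-tailed Welch t-test from mean/SD/n summaries.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with Welch-Satterthwaite
    degrees of freedom; p from the (generally fractional-df) t
    distribution.
    """
    if a.sd == 0 and b.sd == 0:
        raise DegenerateInputError("Welch t undefined: both variances are zero")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupStatResult(
        "welch_t", float(t), float(df), float(p),
        comparison=f"{a.label} vs {b.label}",
    )


def welch_from_raw(
    x: np.ndarray, y: np.ndarray, labels: tuple[str, str] = ("a", "b")
) -> GroupStatResult:
    """Welch t from raw samples; equals ``welch_from_summary`` of their
    summaries exactly."""
    return welch_from_summary(
        GroupSummary.from_samples(labels[0], x),
        GroupSummary.from_samples(labels[1], y),
    )


# ---------------------------------------------------------------------------
# Two-way ANOVA (Type III, sum-to-zero contrasts)
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    table: pd.DataFrame  # rows: factor_a, factor_b, interaction, residual
    ms_within: float
    df_error: float
    cells: pd.DataFrame  # factor_a, factor_b, n, mean, sd
    factors: tuple[str, str]

    def result(self, effect: str) -> GroupStatResult:
        row = self.table.loc[effect]
        return GroupStatResult(
            "two_way_anova_" + effect,
            float(row["F"]),
            (float(row["df"]), self.df_error),
            float(row["p"]),
            comparison=effect,
        )


def _cells_from_raw(
    data: pd.DataFrame, response: str, factors: tuple[str, str]
) -> pd.DataFrame:
    grp = data.groupby(list(factors))[response]
    cells = grp.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
    return cells.reset_index()


def _validate_cells(cells: pd.DataFrame, factors: tuple[str, str]) -> None:
    fa, fb = factors
    la = sorted(cells[fa].unique())
    lb = sorted(cells[fb].unique())
    if len(la) < 2 or len(lb) < 2:
        raise ValidationError("two-way ANOVA needs >= 2 levels per factor")
    full = {(a, b) for a in la for b in lb}
    have = set(zip(cells[fa], cells[fb]))
    if full - have:
        raise ValidationError(f"empty design cells: {sorted(full - have)}")
    if (cells["n"] < 2).any():
        raise ValidationError("every cell needs n >= 2")


def _sum_coding(levels: list, values: pd.Series) -> np.ndarray:
    """Sum-to-zero (deviation) coding columns for one factor."""
    k = len(levels)
    out = np.zeros((len(values), k - 1))
    for j, lev in enumerate(levels[:-1]):
        out[:, j] = (values == lev).astype(float)
    out[(values == levels[-1]).to_numpy()] = -1.0
    return out


def two_way_anova_from_summary(
    cells: pd.DataFrame, factors: tuple[str, str] = ("group", "layer")
) -> AnovaResult:
    """Type III two-way ANOVA reconstructed from per-cell mean/SD/n.

    The within-cell sum of squares is Sum (n_ij - 1) s_ij^2; effect sums
    of squares come from weighted regression on the cell means with
    sum-to-zero contrasts, each effect's SS being the increase in
    weighted residual SS when its columns are dropped from the otherwise
    full model (the Type III comparison).  When summaries are computed
    from raw data this agrees exactly with the raw-data fit.
    """
    cells = cells.copy()
    for col in ("n", "mean", "sd"):
        if col not in cells.columns:
            raise ValidationError(f"cell table missing column {col!r}")
    _validate_cells(cells, factors)
    if (cells["sd"] == 0).any():
        raise DegenerateInputError(
            "cells with zero SD are not supported in summary mode"
        )
    fa, fb = factors
    la = sorted(cells[fa].unique())
    lb = sorted(cells[fb].unique())
    n = cells["n"].to_numpy(dtype=float)
    means = cells["mean"].to_numpy(dtype=float)
    sds = cells["sd"].to_numpy(dtype=float)

    ss_within = float(np.sum((n - 1) * sds**2))
    df_error = float(np.sum(n - 1))
    ms_within = ss_within / df_error

    A = _sum_coding(la, cells[fa])
    B = _sum_coding(lb, cells[fb])
    AB = np.column_stack(
        [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    )
    intercept = np.ones((len(cells), 1))
    blocks = {"factor_a": A, "factor_b": B, "interaction": AB}

    sw = np.sqrt(n)

    def wrss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X * sw[:, None], means * sw, rcond=None)
        resid = means - X @ beta
        return float(np.sum(n * resid**2))

    X_full = np.column_stack([intercept, A, B, AB])
    rss_full = wrss(X_full)
    rows = {}
    for name, block in blocks.items():
        keep = [intercept] + [blk for nm, blk in blocks.items() if nm != name]
        rss_red = wrss(np.column_stack(keep))
        ss = rss_red - rss_full
        df = block.shape[1]
        F = (ss / df) / ms_within
        rows[name] = {"SS": ss, "df": df, "F": F, "p": float(sps.f.sf(F, df, df_error))}
    rows["residual"] = {
        "SS": ss_within, "df": df_error, "F": np.nan, "p": np.nan
    }
    table = pd.DataFrame(rows).T.rename(
        index={"factor_a": fa, "factor_b": fb}
    )
    return AnovaResult(table, ms_within, df_error, cells, factors)


def two_way_anova(
    data: pd.DataFrame,
    response: str = "value",
    factors: tuple[str, str] = ("group", "layer"),
) -> AnovaResult:
    """Type III two-way between-subjects ANOVA from raw observations.

    Fits an OLS model with sum-to-zero contrasts via statsmodels and
    reports Type III sums of squares; unbalanced designs are allowed,
    empty cells are not.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    cells = _cells_from_raw(data, response, factors)
    _validate_cells(cells, factors)
    fa, fb = factors
    df = data.rename(columns={response: "_y", fa: "_fa", fb: "_fb"})
    model = smf.ols("_y ~ C(_fa, Sum) * C(_fb, Sum)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = sm.stats.anova_lm(model, typ=3)
    table = pd.DataFrame(
        {
            "SS": aov["sum_sq"],
            "df": aov["df"],
            "F": aov["F"],
            "p": aov["PR(>F)"],
        }
    )
    table = table.rename(
        index={
            "C(_fa, Sum)": fa,
            "C(_fb, Sum)": fb,
            "C(_fa, Sum):C(_fb, Sum)": "interaction",
            "Residual": "residual",
        }
    ).drop(index="Intercept")
    df_error = float(table.loc["residual", "df"])
    ms_within = float(table.loc["residual", "SS"]) / df_error
    return AnovaResult(table, ms_within, df_error, cells, factors)


def tukey_kramer(anova: AnovaResult) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons over all cells of the design.

    q = |m_i - m_j| / sqrt(MS_within/2 (1/n_i + 1/n_j)), with p from the
    studentized range with k = number of cells and df = error df.  For
    k = 2 balanced groups this reduces to the pooled-variance t-test
    (q = t sqrt(2)).
    """
    cells = anova.cells
    k = len(cells)
    if k < 2:
        raise ValidationError("Tukey-Kramer needs >= 2 cells")
    fa, fb = anova.factors
    labels = [
        f"{row[fa]}:{row[fb]}" if fb in cells.columns else str(row[fa])
        for _, row in cells.iterrows()
    ]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            mi, mj = cells["mean"].iloc[i], cells["mean"].iloc[j]
            ni, nj = cells["n"].iloc[i], cells["n"].iloc[j]
            se = np.sqrt(anova.ms_within / 2.0 * (1.0 / ni + 1.0 / nj))
            q = abs(mi - mj) / se
            p = float(sps.studentized_range.sf(q, k, anova.df_error))
            rows.append(
                {
                    "cell_a": labels[i],
                    "cell_b": labels[j],
                    "mean_diff": mi - mj,
                    "q": q,
                    "p_adj": min(1.0, p),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation / regression / runs test
# ---------------------------------------------------------------------------

def pearson_linreg(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson r with two-tailed p plus least-squares slope/intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson_linreg needs matched n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x is constant; correlation undefined")
    if np.ptp(y) == 0:
        warnings.warn("y is constant; reporting r = 0 by convention")
        slope, intercept = 0.0, float(y[0])
        return {"r": 0.0, "p": 1.0, "slope": slope, "intercept": intercept,
                "n": int(x.size)}
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return {
        "r": float(r),
        "p": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": int(x.size),
    }


def runs_pmf(r: int, n1: int, n2: int) -> float:
    """Exact probability of ``r`` runs in a random arrangement of n1
    positive and n2 negative signs."""
    def c(a: int, b: int) -> int:
        return comb(a, b) if 0 <= b <= a else 0

    tot = comb(n1 + n2, n1)
    if r % 2 == 0:
        k = r // 2
        return 2 * c(n1 - 1, k - 1) * c(n2 - 1, k - 1) / tot
    k = (r - 1) // 2
    return (c(n1 - 1, k) * c(n2 - 1, k - 1) + c(n1 - 1, k - 1) * c(n2 - 1, k)) / tot


def _runs_exact_tails(r: int, n1: int, n2: int) -> tuple[float, float]:
    low = sum(runs_pmf(i, n1, n2) for i in range(1, r + 1))
    high = sum(runs_pmf(i, n1, n2) for i in range(r, n1 + n2 + 1))
    return min(1.0, low), min(1.0, high)


def _runs_approx_tails(r: int, n1: int, n2: int) -> tuple[float, float]:
    n = n1 + n2
    mu = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1))
    if var <= 0:
        return 1.0, 1.0
    sd = np.sqrt(var)
    low = float(sps.norm.cdf((r - mu + 0.5) / sd))  # continuity-corrected
    high = float(sps.norm.sf((r - mu - 0.5) / sd))
    return min(1.0, low), min(1.0, high)


def _runs_p(low: float, high: float, alternative: str) -> float:
    if alternative == "two_sided":
        return min(1.0, 2.0 * min(low, high))
    if alternative == "too_few":
        return low
    if alternative == "too_many":
        return high
    raise ValidationError(f"unknown alternative {alternative!r}")


def runs_test(
    residuals: np.ndarray,
    x: np.ndarray | None = None,
    method: str = "auto",
    alternative: str = "two_sided",
    exact_threshold: int = 20,
) -> GroupStatResult:
    """Wald-Wolfowitz runs test on the signs of fit residuals.

    Residuals (ordered by ``x`` when given; zeros dropped) are reduced to
    their signs and the number of sign runs is compared with its null
    distribution under random arrangement.  Too few runs indicate the
    clustered residuals of a systematic (non-linear) trend; too many
    indicate alternation.  The default p is two-sided (twice the smaller
    tail, capped at 1); ``alternative="too_few"`` gives the one-tailed
    clustering p used by common curve-fitting software when checking
    linearity.  Exact enumeration is used for n <= ``exact_threshold``;
    above that, a continuity-corrected normal approximation (adequate
    once both signs occur roughly 6+ times).
    """
    res = np.asarray(residuals, dtype=float)
    if x is not None:
        res = res[np.argsort(np.asarray(x), kind="stable")]
    signs = np.sign(res)
    signs = signs[signs != 0]
    if signs.size == 0:
        raise ValidationError("runs test: no nonzero residuals")
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    flags: tuple[str, ...] = ()
    if n1 == 0 or n2 == 0:
        # all residuals one sign: the single-run degenerate case
        return GroupStatResult(
            "runs_test", float(runs), float(n1 + n2), 1.0,
            comparison=f"n+={n1}, n-={n2}", flags=("single_sign",),
        )
    n = n1 + n2
    if method == "auto":
        method = "exact" if n <= exact_threshold else "approx"
    if method == "exact":
        low, high = _runs_exact_tails(runs, n1, n2)
    elif method == "approx":
        low, high = _runs_approx_tails(runs, n1, n2)
    else:
        raise ValidationError(f"unknown runs test method {method!r}")
    p = _runs_p(low, high, alternative)
    if runs == 2 and min(n1, n2) > 1:
        flags = ("extreme_clustering",)
    return GroupStatResult(
        "runs_test", float(runs), float(n), float(p),
        comparison=f"n+={n1}, n-={n2}", flags=flags,
    )


# ---------------------------------------------------------------------------
# Glycemic severity
# ---------------------------------------------------------------------------

def severity_measures(bg_series: np.ndarray) -> dict:
    """Lifetime average blood glucose and number of weeks strictly above
    400 mg/dL for one animal's weekly series."""
    bg = np.asarray(bg_series, dtype=float)
    if bg.size == 0:
        raise ValidationError("severity_measures: empty blood-glucose series")
    return {
        "mean_bg_mg_dl": float(bg.mean()),
        "weeks_above_400": int(np.sum(bg > 400.0)),
    }
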