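"""Statistical layer: median stratification, stratified incidence tables,
group-comparison tests, and logistic models with standardized coefficients.

The central analysis stratifies participants by baseline beta-cell function
(low/high, split at the cohort median) and, within each stratum, by the size
of their 10-year insulin-sensitivity decline (large/small, split at the
within-stratum median of DIS).  Incidence of progression to prediabetes and
diabetes is then compared across the large/small DIS columns with Pearson
2x2 chi-square tests, and the relative strength of DIS versus DBCF is
quantified by the ratio of standardized logistic-regression coefficients.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .glycemic_status import ProgressionGroup

logger = logging.getLogger("glycoprog")

PROGRESSION_ORDER = ("T2D_P", "PREDM_P", "NON_P")  # Table row order: worst first


class BCFStratum(enum.Enum):
    LOW = "LOW"
    HIGH = "HIGH"


class DISStratum(enum.Enum):
    LARGE = "LARGE"
    SMALL = "SMALL"


# ---------------------------------------------------------------------------
# Median split
# ---------------------------------------------------------------------------

def median_split(values, high_label: str = "HIGH", low_label: str = "LOW") -> np.ndarray:
    """Binary labels at the sample median: strictly above -> high side.

    Elements equal to the median go to the low side, so with odd n the median
    element itself is labelled low.  For DIS the "large" decline is the high
    side.  All-identical input yields all-low with a warning.
    """
    arr = np.asarray(values, dtype=float)
    defined = ~np.isnan(arr)
    if defined.sum() < 2:
        raise ValueError("median_split needs at least 2 defined values")
    med = np.median(arr[defined])
    if np.all(arr[defined] == arr[defined][0]):
        warnings.warn("median_split: all values identical; labelling all low")
    out = np.where(arr > med, high_label, low_label).astype(object)
    out[~defined] = None
    return out


# ---------------------------------------------------------------------------
# 2x2 chi-square
# ---------------------------------------------------------------------------

@dataclass
class Chi2Result:
    statistic: float | None
    df: int
    p_value: float | None
    valid: bool
    note: str = ""


def chi_square_2x2(a: float, b: float, c: float, d: float) -> Chi2Result:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]], no continuity
    correction: n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table")
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        return Chi2Result(statistic=None, df=1, p_value=None, valid=False,
                          note="zero margin; statistic undefined")
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return Chi2Result(statistic=float(stat), df=1,
                      p_value=float(stats.chi2.sf(stat, 1)), valid=True)


# ---------------------------------------------------------------------------
# Stratified incidence (Table-2-style)
# ---------------------------------------------------------------------------

@dataclass
class StratifiedTable:
    """Counts/percentages by (BCF stratum x DIS stratum x progression group)
    plus per-BCF-stratum 2x2 chi-square p-values for each outcome row."""

    counts: pd.DataFrame        # index: progression; columns: (bcf, dis)
    percentages: pd.DataFrame   # same shape; column percentages (count/N*100)
    stratum_n: pd.Series        # N per (bcf, dis) column
    p_values: pd.DataFrame      # index: progression; columns: bcf stratum

    @property
    def total_n(self) -> int:
        return int(self.counts.to_numpy().sum())


def stratified_incidence(labels: pd.DataFrame) -> StratifiedTable:
    """Build the stratified incidence table from per-participant labels.

    ``labels`` needs columns ``bcf_stratum`` (LOW/HIGH), ``dis_stratum``
    (LARGE/SMALL) and ``progression`` (NON_P/PREDM_P/T2D_P; enum or string).
    For each BCF stratum and outcome, a 2x2 chi-square compares large vs
    small DIS on outcome-vs-rest.
    """
    df = labels.copy()
    for col in ("bcf_stratum", "dis_stratum", "progression"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
        df[col] = df[col].map(lambda v: v.name if isinstance(v, enum.Enum) else str(v))

    bcf_levels = ("LOW", "HIGH")
    dis_levels = ("LARGE", "SMALL")
    cols = pd.MultiIndex.from_product([bcf_levels, dis_levels], names=["bcf", "dis"])
    counts = pd.DataFrame(0, index=list(PROGRESSION_ORDER), columns=cols)
    for (b, d_), grp in df.groupby(["bcf_stratum", "dis_stratum"]):
        vc = grp["progression"].value_counts()
        for outcome in PROGRESSION_ORDER:
            counts.loc[outcome, (b, d_)] = int(vc.get(outcome, 0))

    stratum_n = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts / stratum_n.replace(0, np.nan) * 100.0

    pvals = pd.DataFrame(index=list(PROGRESSION_ORDER), columns=list(bcf_levels),
                         dtype=float)
    for b in bcf_levels:
        n_large = stratum_n.get((b, "LARGE"), 0)
        n_small = stratum_n.get((b, "SMALL"), 0)
        for outcome in PROGRESSION_ORDER:
            a = counts.loc[outcome, (b, "LARGE")]
            c = counts.loc[outcome, (b, "SMALL")]
            if n_large == 0 or n_small == 0:
                pvals.loc[outcome, b] = np.nan
                continue
            res = chi_square_2x2(a, n_large - a, c, n_small - c)
            pvals.loc[outcome, b] = res.p_value if res.valid else np.nan

    return StratifiedTable(counts=counts, percentages=pct,
                           stratum_n=stratum_n, p_values=pvals)


def assign_strata(deltas: pd.DataFrame) -> pd.DataFrame:
    """Median-split baseline BCF over the cohort, then DIS within each BCF
    stratum (Table-2 column Ns imply the within-stratum DIS split).

    ``deltas`` needs columns id, dis, baseline_bcf (from ``compute_deltas``).
    Rows with undefined values are dropped (with a log line).
    """
    df = deltas.copy()
    n0 = len(df)
    df = df.dropna(subset=["dis", "baseline_bcf"])
    if n0 - len(df):
        logger.info("assign_strata: dropped %d participants with undefined DIS or baseline BCF",
                    n0 - len(df))
    df["bcf_stratum"] = median_split(df["baseline_bcf"], high_label="HIGH", low_label="LOW")
    df["dis_stratum"] = None
    for b in ("LOW", "HIGH"):
        mask = df["bcf_stratum"] == b
        if mask.sum() >= 2:
            df.loc[mask, "dis_stratum"] = median_split(
                df.loc[mask, "dis"], high_label="LARGE", low_label="SMALL")
    return df


# ---------------------------------------------------------------------------
# Group comparisons (t-test / ANOVA / Bonferroni)
# ---------------------------------------------------------------------------

@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupTestReport:
    test: str                      # "t" or "anova"
    statistic: float
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def group_tests(groups: dict[str, np.ndarray]) -> GroupTestReport:
    """Two-sample pooled-variance t-test (2 groups) or one-way ANOVA (>=3),
    with Bonferroni-adjusted pairwise post hoc comparisons."""
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, a in zip(names, arrays):
        if len(a) < 2:
            raise ValueError(f"group {name!r} has n < 2")

    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return GroupTestReport(test="t", statistic=float(t), p_value=float(p))

    f, p = stats.f_oneway(*arrays)
    pairs = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
    k = len(pairs)
    pairwise = []
    for i, j in pairs:
        t, praw = stats.ttest_ind(arrays[i], arrays[j], equal_var=True)
        pairwise.append(PairwiseResult(
            pair=(names[i], names[j]), statistic=float(t),
            p_raw=float(praw), p_adjusted=float(min(1.0, praw * k))))
    return GroupTestReport(test="anova", statistic=float(f), p_value=float(p),
                           pairwise=pairwise)


# ---------------------------------------------------------------------------
# Logistic regression with standardized coefficients
# ---------------------------------------------------------------------------

class SeparationError(RuntimeError):
    """Raised when the logistic MLE does not exist (perfect separation) or
    the fit fails to converge."""


@dataclass
class LogisticFit:
    outcome: str
    model_id: int | None
    params: pd.Series                 # unstandardized coefficients (incl. const)
    conf_int: pd.DataFrame            # Wald 95% CIs, columns [lower, upper]
    odds_ratios: pd.Series
    std_params: pd.Series | None      # standardized coefficients
    std_conf_int: pd.DataFrame | None
    deviance: float
    std_deviance: float | None
    n: int
    dropped_columns: list[str] = field(default_factory=list)
    ratio_standardized: float | None = None   # DIS : DBCF


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy(dtype=float)) < Xc.shape[1]:
        raise ValueError("design matrix is rank-deficient (duplicate or constant column?)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
        except Exception as exc:  # statsmodels raises PerfectSeparationError
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (possible separation)")
    # scale-invariant sanity: a valid MLE has finite coefficients and
    # standard errors (under separation both diverge)
    if not (np.isfinite(res.params.to_numpy()).all()
            and np.isfinite(res.bse.to_numpy()).all()):
        raise SeparationError("non-finite coefficients or standard errors "
                              "(perfect separation?)")
    return res


def _continuous_columns(X: pd.DataFrame) -> list[str]:
    return [c for c in X.columns if X[c].nunique(dropna=True) > 2]


def fit_logistic(outcome, design: pd.DataFrame, standardize: bool = False,
                 outcome_label: str = "", model_id: int | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS/Newton) with Wald 95% CIs.

    With ``standardize=True``, continuous covariates (more than two distinct
    values) are centered and scaled to unit SD before a second fit, so
    coefficients of predictors in different units are comparable; binary
    covariates are left as is.  Standardization is an affine
    reparameterization, so both fits have identical deviance.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is degenerate (single class)")
    X = design.astype(float)
    res = _fit_logit(y, X)
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]

    std_params = std_ci = None
    std_dev = None
    if standardize:
        Xs = X.copy()
        for c in _continuous_columns(X):
            sd = X[c].std(ddof=1)
            if sd > 0:
                Xs[c] = (X[c] - X[c].mean()) / sd
        res_s = _fit_logit(y, Xs)
        std_params = res_s.params
        std_ci = res_s.conf_int(alpha=0.05)
        std_ci.columns = ["lower", "upper"]
        std_dev = float(-2 * res_s.llf)

    return LogisticFit(
        outcome=outcome_label, model_id=model_id,
        params=res.params, conf_int=ci, odds_ratios=np.exp(res.params),
        std_params=std_params, std_conf_int=std_ci,
        deviance=float(-2 * res.llf), std_deviance=std_dev,
        n=len(y))


MODEL_COVARIATES = {
    1: ["dis", "dbcf"],
    2: ["dis", "dbcf", "sex_male", "age", "bmi"],
    3: ["dis", "dbcf", "sex_male", "age", "bmi", "baseline_is_high", "baseline_bcf_high"],
}


def model_suite(data: pd.DataFrame) -> list[LogisticFit]:
    """Fit Models 1-3 for progression to prediabetes and to diabetes.

    ``data`` is per-participant with columns dis, dbcf, sex_male, age, bmi,
    baseline_is_high, baseline_bcf_high and progression.  Each outcome is a
    binary contrast against non-progressors, excluding the third group
    (PreDM-p vs Non-p; T2D-p vs Non-p).  Every fit reports unstandardized
    and standardized coefficients and the DIS:DBCF ratio of standardized
    coefficients.  Degenerate (constant) covariates are dropped with a
    warning.
    """
    df = data.copy()
    df["progression"] = df["progression"].map(
        lambda v: v.name if isinstance(v, enum.Enum) else str(v))
    contrasts = {
        "preDM": ("PREDM_P", ("PREDM_P", "NON_P")),
        "DM": ("T2D_P", ("T2D_P", "NON_P")),
    }
    fits: list[LogisticFit] = []
    for outcome_label, (event, keep_groups) in contrasts.items():
        sub = df[df["progression"].isin(keep_groups)]
        y = (sub["progression"] == event).astype(float)
        for model_id, covars in MODEL_COVARIATES.items():
            missing = [c for c in covars if c not in sub.columns]
            if missing:
                raise ValueError(f"model {model_id}: missing covariates {missing}")
            X = sub[covars].astype(float)
            dropped = [c for c in covars if X[c].nunique(dropna=True) < 2]
            if dropped:
                warnings.warn(f"model {model_id} ({outcome_label}): dropping "
                              f"degenerate covariates {dropped}")
                X = X.drop(columns=dropped)
            rows = X.notna().all(axis=1)
            fit = fit_logistic(y[rows], X[rows], standardize=True,
                               outcome_label=outcome_label, model_id=model_id)
            fit.dropped_columns = dropped
            if fit.std_params is not None and "dis" in fit.std_params and "dbcf" in fit.std_params:
                dbcf_std = fit.std_params["dbcf"]
                fit.ratio_standardized = (float(fit.std_params["dis"] / dbcf_std)
                                          if dbcf_std != 0 else None)
            fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# Longitudinal trajectory summary
# ---------------------------------------------------------------------------

def trajectory_summary(df: pd.DataFrame, value_col: str,
                       group_col: str = "progression",
                       id_col: str = "id",
                       visit_col: str = "visit_index",
                       alpha: float = 0.05) -> pd.DataFrame:
    """Group x visit mean/SD/n with percent decline from the group baseline
    mean and a paired baseline-vs-visit t-test flag at ``alpha``."""
    work = df[[id_col, group_col, visit_col, value_col]].copy()
    work[group_col] = work[group_col].map(
        lambda v: v.name if isinstance(v, enum.Enum) else str(v))
    rows = []
    for g, grp in work.groupby(group_col, sort=True):
        base = grp[grp[visit_col] == 0].set_index(id_col)[value_col]
        base_mean = float(base.mean()) if len(base) else np.nan
        for v, sub in grp.groupby(visit_col, sort=True):
            vals = sub.set_index(id_col)[value_col].dropna()
            mean = float(vals.mean()) if len(vals) else np.nan
            row = {
                group_col: g, visit_col: int(v), "n": int(len(vals)),
                "mean": mean,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "pct_decline_from_baseline": (
                    100.0 * (base_mean - mean) / base_mean
                    if base_mean and base_mean > 0 and len(vals) else np.nan),
                "p_vs_baseline": np.nan, "significant_vs_baseline": False,
            }
            if v != 0 and len(base) and len(vals):
                common = base.dropna().index.intersection(vals.index)
                if len(common) > 1:
                    t, p = stats.ttest_rel(base.loc[common], vals.loc[common])
                    row["p_vs_baseline"] = float(p)
                    row["significant_vs_baseline"] = bool(p < alpha)
            rows.append(row)
    return pd.DataFrame(rows)
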