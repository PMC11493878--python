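"""Cohort-level statistics.

Group comparisons follow the conventions of the study design they serve:
pooled-variance Student t-tests (printed dfs are n1 + n2 − 2 throughout),
a Yates-corrected chi-square for the gender imbalance, Holm–Bonferroni
step-down correction over each sleep-architecture test family, and OLS
regressions (overall F, adjusted R²) of the PLAS-induced
electrophysiological response on memory gains and the plasma Aβ42/40
change, with optional age/gender covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

SLEEP_PARAMETERS = ("N1", "N2", "N3", "REM", "W", "TST", "SL", "SE", "WASO")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    tail: str = "two"
    p_adjusted: float | None = None


@dataclass
class Chi2Result:
    chi2: float
    df: int
    p: float


@dataclass
class RegressionResult:
    formula: str
    coefficients: dict
    F: float
    df: tuple                    # (df_model, df_resid)
    adj_r2: float
    p: float
    n: int
    covariate_model: "RegressionResult | None" = None


def two_sample_t_from_summary(m1, sd1, n1, m2, sd2, n2,
                              tail: str = "two") -> TTestResult:
    """Pooled-variance Student t from summary statistics, df = n1 + n2 − 2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return TTestResult(t=float(t), df=df, p=_t_pvalue(t, df, tail), tail=tail)


def two_sample_t(x, y, tail: str = "two") -> TTestResult:
    """Pooled-variance Student t from raw data; identical to the
    summary-statistic path by construction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need n >= 2")
    return two_sample_t_from_summary(x.mean(), x.std(ddof=1), len(x),
                                     y.mean(), y.std(ddof=1), len(y), tail)


def one_sample_t(x, popmean: float = 0.0, tail: str = "two") -> TTestResult:
    x = np.asarray(x, float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    t, _ = sstats.ttest_1samp(x, popmean)
    df = len(x) - 1
    return TTestResult(t=float(t), df=df, p=_t_pvalue(t, df, tail), tail=tail)


def _t_pvalue(t, df, tail):
    if tail == "two":
        return float(2.0 * sstats.t.sf(abs(t), df))
    if tail == "one":
        return float(sstats.t.sf(abs(t), df))
    raise ValueError("tail must be 'two' or 'one'")


def yates_chi2(table) -> Chi2Result:
    """2×2 chi-square with Yates continuity correction."""
    obs = np.asarray(table, float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    if (obs < 0).any() or not np.allclose(obs, np.rint(obs)):
        raise ValueError("counts must be non-negative integers")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (expected <= 0).any():
        raise ValueError("all expected counts must be positive")
    chi2 = float((((np.abs(obs - expected) - 0.5).clip(min=0)) ** 2
                  / expected).sum())
    return Chi2Result(chi2=chi2, df=1, p=float(sstats.chi2.sf(chi2, 1)))


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment, order-preserving, monotone, never below
    the input p."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# sleep architecture


def sleep_architecture_contrasts(table: pd.DataFrame,
                                 parameters=SLEEP_PARAMETERS) -> dict:
    """Experimental-vs-baseline difference scores with Holm-corrected tests.

    ``table`` is long-format: one row per participant-night with columns
    participant_id, group, night (BL/E1/E2/E3) and one column per sleep
    parameter. Per participant and parameter the difference score collapses
    the experimental nights: mean(E1, E2, E3) − BL. Families corrected
    separately: all between-group tests; all within-group tests per group.
    Participants missing any night are excluded (and reported).
    """
    required = {"participant_id", "group", "night"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    params = [p for p in parameters if p in table.columns]
    if not params:
        raise ValueError("no sleep parameter columns found")

    counts = table.groupby("participant_id")["night"].nunique()
    complete = set(counts[counts == 4].index)
    excluded = sorted(set(table["participant_id"]) - complete)
    tb = table[table["participant_id"].isin(complete)]

    wide = {}
    for pid, sub in tb.groupby("participant_id"):
        sub = sub.set_index("night")
        row = {"group": sub["group"].iloc[0]}
        for p in params:
            row[p] = sub.loc[["E1", "E2", "E3"], p].mean() - sub.loc["BL", p]
        wide[pid] = row
    diffs = pd.DataFrame.from_dict(wide, orient="index")

    groups = sorted(diffs["group"].unique())
    out = {"difference_scores": diffs, "excluded_participants": excluded,
           "between": {}, "within": {g: {} for g in groups}}

    def safe(fn, *args):
        # degenerate (zero-variance) difference scores: no evidence, p = 1
        try:
            res = fn(*args)
        except ValueError:
            return TTestResult(t=0.0, df=0, p=1.0)
        if not np.isfinite(res.t):
            return TTestResult(t=0.0, df=res.df, p=1.0)
        return res

    if len(groups) == 2:
        g1, g2 = groups
        between = {p: safe(two_sample_t, diffs.loc[diffs["group"] == g1, p],
                           diffs.loc[diffs["group"] == g2, p])
                   for p in params}
        adj = holm_bonferroni([between[p].p for p in params])
        for p, a in zip(params, adj):
            between[p].p_adjusted = float(a)
        out["between"] = between

    for g in groups:
        sub = diffs[diffs["group"] == g]
        within = {p: safe(one_sample_t, sub[p], 0.0) for p in params}
        adj = holm_bonferroni([within[p].p for p in params])
        for p, a in zip(params, adj):
            within[p].p_adjusted = float(a)
        out["within"][g] = within
    return out


# ---------------------------------------------------------------------------
# regressions


def ols_fit(y, predictors: dict, formula: str = "") -> RegressionResult:
    """OLS with intercept; overall F, adjusted R², model p."""
    y = np.asarray(y, float)
    names = list(predictors)
    X = np.column_stack([np.asarray(predictors[k], float) for k in names])
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[keep], X[keep]
    n, k = X.shape
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, got {n}")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        culprits = [nm for i, nm in enumerate(names)
                    if np.std(X[:, i]) == 0
                    or np.linalg.matrix_rank(np.delete(Xc, i + 1, axis=1))
                    == np.linalg.matrix_rank(Xc)]
        raise ValueError(f"rank-deficient design; collinear column(s): "
                         f"{culprits or names}")
    fit = sm.OLS(y, Xc).fit()
    coeffs = {"const": float(fit.params[0])}
    coeffs.update({nm: float(v) for nm, v in zip(names, fit.params[1:])})
    return RegressionResult(
        formula=formula or ("y ~ " + " + ".join(names)),
        coefficients=coeffs, F=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        adj_r2=float(fit.rsquared_adj), p=float(fit.f_pvalue), n=n)


def response_regression(table: pd.DataFrame, outcome: str,
                        predictor: str = "response_score_erp",
                        covariates=None, subset: str = "all") -> RegressionResult:
    """Regress an outcome (memory gain at t5/t6/t7 or abeta_diff) on the
    electrophysiological response score, optionally within one group and
    with age/gender covariates. When covariates are requested, the
    no-covariate fit is returned with the covariate fit attached for
    comparison."""
    df = table if subset == "all" else table[table["group"] == subset]
    if outcome not in df.columns or predictor not in df.columns:
        raise ValueError(f"missing column: {outcome!r} or {predictor!r}")
    y = df[outcome].to_numpy(float)
    base = ols_fit(y, {predictor: df[predictor].to_numpy(float)},
                   formula=f"{outcome} ~ {predictor} [{subset}]")
    if covariates:
        preds = {predictor: df[predictor].to_numpy(float)}
        for c in covariates:
            if c == "gender":
                preds["gender"] = (df["gender"] == "F").to_numpy(float)
            else:
                preds[c] = df[c].to_numpy(float)
        base.covariate_model = ols_fit(
            y, preds,
            formula=f"{outcome} ~ {predictor} + {' + '.join(covariates)} [{subset}]")
    return base


def baseline_independence_check(table: pd.DataFrame,
                                predictor: str = "abeta_pre",
                                response: str = "response_score_erp") -> dict:
    """Per group, regress the response score on the pre-intervention
    Aβ42/40 ratio — the check that the response is not driven by baseline
    amyloid status."""
    out = {}
    for group, sub in table.groupby("group"):
        out[group] = ols_fit(sub[response].to_numpy(float),
                             {predictor: sub[predictor].to_numpy(float)},
                             formula=f"{response} ~ {predictor} [{group}]")
    return out
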