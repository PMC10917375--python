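"""Behavioral analysis: repeated-measures ANOVA on accuracy, effect
sizes, and sex comparisons.

The central test is a mixed-design ANOVA with inhibition (Go vs NoGo
accuracy) as the within-subject factor, sex as the between-subject
factor, and age as a covariate.  With a two-level within factor the
within-subject effects are exactly the tests on per-subject difference
scores: the inhibition main effect is the intercept of the regression
of (Go - NoGo) on [1, sex, age], giving F(1, n - k) — F(1, 115) for
118 subjects with sex and age in the model.  Partial eta squared is
reported as eta_p^2 = F df1 / (F df1 + df2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaEffect",
    "rm_anova_inhibition_by_sex",
    "eta_p_squared",
    "cohens_d_pooled",
    "sex_comparison",
]


@dataclass
class AnovaEffect:
    """One tested effect from the mixed ANOVA."""

    name: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float


def eta_p_squared(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic:
    eta_p^2 = F df1 / (F df1 + df2) = SS_effect / (SS_effect + SS_error)."""
    return F * df1 / (F * df1 + df2)


def _effect_from_regression(y: np.ndarray, X: np.ndarray, col: int,
                            name: str) -> AnovaEffect:
    """F test for one regression coefficient, with partial eta squared."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df2 = n - k
    sigma2 = resid @ resid / df2
    XtX_inv = np.linalg.inv(X.T @ X)
    if sigma2 == 0:
        F = 0.0 if beta[col] == 0 else np.inf
    else:
        F = float(beta[col] ** 2 / (sigma2 * XtX_inv[col, col]))
    p = float(stats.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
    return AnovaEffect(name, F, 1, df2, p, eta_p_squared(F, 1, df2))


def rm_anova_inhibition_by_sex(table: pd.DataFrame,
                               include_age: bool = True) -> dict:
    """Mixed ANOVA on accuracy: within inhibition, between sex, age covariate.

    ``table`` needs ``go_accuracy`` and ``nogo_accuracy`` (percent, one
    row per subject) and, if used, ``sex`` ("F"/"M") and ``age``.
    Returns AnovaEffect entries for the inhibition main effect, the
    inhibition-by-sex interaction, and the between-subject sex effect.
    With a single-sex table the sex terms are dropped with a warning.
    """
    go = table["go_accuracy"].to_numpy(dtype=float)
    nogo = table["nogo_accuracy"].to_numpy(dtype=float)
    n = len(table)
    d = go - nogo

    have_sex = "sex" in table and table["sex"].nunique() > 1
    if "sex" in table and not have_sex:
        warnings.warn("single-sex table: between-subject factor dropped")
    cols = [np.ones(n)]
    if have_sex:
        sex = np.where(table["sex"].to_numpy() == "F", 0.5, -0.5)
        cols.append(sex - sex.mean())
    if include_age and "age" in table:
        age = table["age"].to_numpy(dtype=float)
        cols.append(age - age.mean())
    X = np.column_stack(cols)

    out = {"inhibition": _effect_from_regression(d, X, 0, "inhibition")}
    if have_sex:
        out["inhibition_x_sex"] = _effect_from_regression(
            d, X, 1, "inhibition_x_sex")
        subj_mean = (go + nogo) / 2.0
        out["sex"] = _effect_from_regression(subj_mean, X, 1, "sex")
    return out


def cohens_d_pooled(mean1: float, sem1: float, mean2: float, sem2: float,
                    n: int) -> float:
    """Cohen's d from group means and standard errors at group size ``n``.

    d = (mean1 - mean2) / sqrt((s1^2 + s2^2) / 2) with s = sem * sqrt(n)
    (pooled-SD form for equal group sizes).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("standard errors must be positive")
    s1 = sem1 * np.sqrt(n)
    s2 = sem2 * np.sqrt(n)
    pooled = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((mean1 - mean2) / pooled)


def sex_comparison(table: pd.DataFrame,
                   measures: tuple = ("go_accuracy", "nogo_accuracy",
                                      "go_rt_ms"),
                   include_age: bool = True) -> dict:
    """Age-adjusted two-group (sex) comparison per behavioral measure.

    Each measure is regressed on [1, sex, age]; the returned statistics
    are the t and two-sided p for the sex term.
    """
    sexes = table["sex"].unique()
    if len(sexes) != 2:
        raise ValueError("sex comparison needs exactly two groups")
    counts = table["sex"].value_counts()
    if counts.min() < 2:
        raise ValueError("each sex group needs at least two subjects")
    n = len(table)
    sex = np.where(table["sex"].to_numpy() == "F", 0.5, -0.5)
    cols = [np.ones(n), sex - sex.mean()]
    if include_age and "age" in table:
        age = table["age"].to_numpy(dtype=float)
        cols.append(age - age.mean())
    X = np.column_stack(cols)
    XtX_inv = np.linalg.inv(X.T @ X)
    out = {}
    for mname in measures:
        y = table[mname].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = n - X.shape[1]
        sigma2 = resid @ resid / df
        if sigma2 == 0:
            t = 0.0 if beta[1] == 0 else np.inf
            p = 1.0 if beta[1] == 0 else 0.0
        else:
            t = float(beta[1] / np.sqrt(sigma2 * XtX_inv[1, 1]))
            p = float(2.0 * stats.t.sf(abs(t), df))
        out[mname] = {"estimate": float(beta[1]), "t": t, "p": p, "df": df}
    return out
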