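"""Group-comparison and regression statistics for tract measures.

The battery: one-way ANOVA with Tukey HSD post-hoc comparisons, ANCOVA
(group effect by partial F after covariate adjustment), Cohen's d with the
pooled SD, per-tract ordinary least squares of cognitive-domain Z-scores
on tract measures with adjusted R^2, Benjamini-Hochberg FDR applied
separately per affected/unaffected tract family, and mode imputation of
the missing depression indicator.

Cohen's d is oriented control-minus-patient (first group minus second) so
that lower patient FA_T yields positive d.  Two-group continuous
comparisons default to Welch's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "anova_tukey", "ancova", "cohens_d", "tract_regression", "bh_fdr",
    "impute_mode", "two_group_test", "fdr_by_family", "AnovaTukeyResult",
    "RegressionResult",
]


@dataclass
class AnovaTukeyResult:
    f_stat: float
    p_value: float
    tukey: pd.DataFrame      # columns group_a, group_b, mean_diff, p_adj


def _as_groups(groups):
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = [(f"group{i}", g) for i, g in enumerate(groups)]
    return [(str(k), np.asarray(v, dtype=float)) for k, v in items]


def anova_tukey(groups) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise post-hoc comparisons.

    ``groups`` is a mapping name -> values (or a sequence of arrays) with
    at least three groups of >= 2 observations each; two groups should use
    :func:`two_group_test` instead.
    """
    items = _as_groups(groups)
    if len(items) < 3:
        raise ValueError("ANOVA with Tukey post-hoc needs >= 3 groups; "
                         "use two_group_test for two groups")
    for name, vals in items:
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    arrays = [v for _, v in items]
    if all(np.ptp(v) == 0 for v in arrays) and len({v[0] for v in arrays}) == 1:
        # identical constant groups: F = 0/0 -> define F=0, p=1, Tukey p=1
        pairs = [(a, b) for i, (a, _) in enumerate(items)
                 for b, _ in items[i + 1:]]
        tk = pd.DataFrame([{"group_a": a, "group_b": b, "mean_diff": 0.0,
                            "p_adj": 1.0} for a, b in pairs])
        return AnovaTukeyResult(0.0, 1.0, tk)
    f_stat, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[name] * len(v) for name, v in items])
    res = pairwise_tukeyhsd(values, labels)
    uniq = list(res.groupsunique)
    pairs = [(uniq[i], uniq[j]) for i in range(len(uniq))
             for j in range(i + 1, len(uniq))]
    tk = pd.DataFrame({
        "group_a": [a for a, _ in pairs],
        "group_b": [b for _, b in pairs],
        "mean_diff": np.asarray(res.meandiffs, dtype=float),
        "p_adj": np.asarray(res.pvalues, dtype=float),
    })
    return AnovaTukeyResult(float(f_stat), float(p), tk)


def ancova(outcome, group, covariates: pd.DataFrame | dict):
    """Covariate-adjusted group comparison (linear model, partial F).

    Fits ``outcome ~ C(group) + covariates`` by OLS and tests the group
    factor with a partial F-test against the covariate-only model.
    Returns ``(p_value, fitted_model)``.
    """
    y = np.asarray(outcome, dtype=float)
    group = pd.Series(group).astype(str).reset_index(drop=True)
    if group.nunique() < 2:
        raise ValueError("group factor is constant")
    cov = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
    if cov.isna().any().any():
        raise ValueError("covariates contain missing values; impute first "
                         "(see impute_mode)")
    constant = [c for c in cov.columns if cov[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariate(s): {constant}")
        cov = cov.drop(columns=constant)
    dummies = pd.get_dummies(group, prefix="group", drop_first=True).astype(float)
    X_full = sm.add_constant(pd.concat([dummies, cov], axis=1))
    _check_rank(X_full)
    X_red = sm.add_constant(cov)
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_num = full.df_model - red.df_model
    if full.ssr == 0 and red.ssr == 0:
        return 1.0, full
    f = ((red.ssr - full.ssr) / df_num) / (full.ssr / full.df_resid)
    p = float(sps.f.sf(f, df_num, full.df_resid))
    return p, full


def _check_rank(X: pd.DataFrame):
    arr = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        corr = pd.DataFrame(arr, columns=X.columns).corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = np.unravel_index(np.nanargmax(corr.values), corr.shape)
        raise ValueError(
            "rank-deficient design; most collinear columns: "
            f"{corr.index[pair[0]]!r} and {corr.columns[pair[1]]!r}")


def cohens_d(a, b) -> float:
    """Standardized mean difference (a minus b) with the pooled SD.

    Convention: pass the control (or reference) group first, so a measure
    that is *lower* in patients yields positive d.  Zero pooled SD returns
    NaN with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Cohen's d needs >= 2 observations per group")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        warnings.warn("zero pooled SD: Cohen's d undefined")
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


@dataclass
class RegressionResult:
    slope: float
    adjusted_r2: float
    p_value: float
    n: int
    model: object = None


def tract_regression(domain_z, tract_measure,
                     covariates: pd.DataFrame | dict | None = None
                     ) -> RegressionResult:
    """OLS of a domain Z-score on one tract measure, with covariates.

    The reported slope and p-value belong to the tract-measure coefficient;
    adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1) for the full model.  Requires
    n > number of predictors + 1.
    """
    y = np.asarray(domain_z, dtype=float)
    x = pd.DataFrame({"tract_measure": np.asarray(tract_measure, dtype=float)})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
        x = pd.concat([x.reset_index(drop=True), cov], axis=1)
    n, p = len(y), x.shape[1]
    if n <= p + 1:
        raise ValueError(f"insufficient observations: n={n} for {p} predictors")
    X = sm.add_constant(x)
    model = sm.OLS(y, X).fit()
    return RegressionResult(slope=float(model.params["tract_measure"]),
                            adjusted_r2=float(model.rsquared_adj),
                            p_value=float(model.pvalues["tract_measure"]),
                            n=n, model=model)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of p-values.

    q_i = min_{j >= i} m * p_(j) / j, clipped at 1, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fdr_by_family(table: pd.DataFrame, p_col: str = "p",
                  family_cols=("family",), q_col: str = "q") -> pd.DataFrame:
    """Apply BH-FDR separately within each family (e.g. affected vs
    unaffected tract analyses); families never influence each other."""
    out = table.copy()
    out[q_col] = np.nan
    for _, idx in out.groupby(list(family_cols)).groups.items():
        p = out.loc[idx, p_col]
        finite = p.notna()
        if finite.any():
            out.loc[p.index[finite], q_col] = bh_fdr(p[finite].to_numpy())
    return out


def impute_mode(column) -> pd.Series:
    """Replace missing values by the most frequent observed value.

    Ties break toward the lowest code (symptom absent), the conservative
    choice; a tie is reported with a warning.  All-missing input is an
    error.
    """
    s = pd.Series(column).copy()
    observed = s.dropna()
    if observed.empty:
        raise ValueError("cannot impute: all values missing")
    counts = observed.value_counts()
    top = counts[counts == counts.max()].index
    if len(top) > 1:
        warnings.warn(f"mode tie among {sorted(top)}; imputing {min(top)}")
    return s.fillna(min(top))


def two_group_test(a, b, welch: bool = True):
    """Two-sided t-test for two groups (Welch by default)."""
    t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                         equal_var=not welch)
    return float(t), float(p)
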