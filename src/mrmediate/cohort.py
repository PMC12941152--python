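"""Cross-sectional descriptive layer: group summaries, rank-sum and
contingency tests, and propensity-score matching for the matched
sensitivity analysis.

Continuous variables are compared case vs control with the Mann–Whitney U
test, categorical variables with the Pearson chi-square statistic (an
optional seeded Monte-Carlo p-value handles sparse tables; a literal exact
multivariate test is intractable at biobank margins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ParameterError


@dataclass
class GroupSummary:
    """Per-group summary of one continuous variable."""

    variable: str
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    mean_difference: float  # case minus control
    n_case: int
    n_control: int


def summarize_groups(
    table: pd.DataFrame, variable: str, group_col: str = "group"
) -> GroupSummary | pd.DataFrame:
    """Summarise ``variable`` by case/control group.

    Continuous (numeric) variables return a :class:`GroupSummary` with the
    mean difference MD = mean(case) - mean(control); categorical variables
    return a counts + column-percentage table.
    """
    if variable not in table.columns:
        raise ParameterError(f"unknown variable {variable!r}")
    if group_col not in table.columns:
        raise ParameterError(f"missing group column {group_col!r}")
    g = table[group_col]
    case = table.loc[g == "case", variable]
    control = table.loc[g == "control", variable]
    if pd.api.types.is_numeric_dtype(table[variable]):
        return GroupSummary(
            variable=variable,
            case_mean=float(case.mean()),
            case_sd=float(case.std(ddof=1)),
            control_mean=float(control.mean()),
            control_sd=float(control.std(ddof=1)),
            mean_difference=float(case.mean() - control.mean()),
            n_case=len(case),
            n_control=len(control),
        )
    counts = pd.crosstab(table[variable], g)
    pct = 100.0 * counts / counts.sum(axis=0)
    out = pd.concat({"count": counts, "percent": pct}, axis=1)
    return out


def rank_sum_test(x, y) -> tuple[float, float]:
    """Mann–Whitney U test, two-sided.

    Exact enumeration when both samples have fewer than 20 observations
    and no ties span the groups; tie-corrected, continuity-corrected
    normal approximation otherwise.  All values tied across both groups
    returns p = 1 with a degeneracy warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups", stacklevel=2)
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if (x.size < 20 and y.size < 20) else "asymptotic"
    if method == "exact" and len(np.unique(pooled)) < pooled.size:
        method = "asymptotic"  # exact null distribution invalid under ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_test(
    table,
    monte_carlo: bool = False,
    n_resamples: int = 9999,
    seed: int | None = None,
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns ``(statistic, df, p)`` with the asymptotic chi-square p, or a
    seeded Monte-Carlo p (random tables with fixed margins) for sparse
    tables when ``monte_carlo`` is set.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ParameterError("need at least a 2x2 table")
    if np.any(obs < 0):
        raise ParameterError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ParameterError("degenerate margin: a row or column sums to zero")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    if monte_carlo:
        rng = np.random.default_rng(seed)
        rt = stats.random_table(obs.sum(axis=1).astype(int), obs.sum(axis=0).astype(int))
        sims = rt.rvs(n_resamples, method="patefield", random_state=rng)
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
        p = (1 + np.sum(sim_stats >= stat - 1e-12)) / (1 + n_resamples)
    return float(stat), int(df), float(p)


def psm_match(
    table: pd.DataFrame,
    covariates: list[str],
    group_col: str = "group",
    caliper_sd: float = 0.2,
) -> pd.DataFrame:
    """1:1 greedy propensity-score matching without replacement.

    The propensity is a logistic model of case status on ``covariates``;
    matching is nearest-neighbour on the logit, cases visited in
    descending propensity, with a caliper of ``caliper_sd`` standard
    deviations of the logit.  Cases with no control inside the caliper are
    dropped with a warning; the matched table has equal group sizes.
    """
    if group_col not in table.columns:
        raise ParameterError(f"missing group column {group_col!r}")
    for c in covariates:
        if c not in table.columns:
            raise ParameterError(f"unknown covariate {c!r}")
    df = table.reset_index(drop=True)
    y = (df[group_col] == "case").astype(float)
    if y.sum() == 0 or y.sum() == len(df):
        raise ParameterError("both groups must be non-empty")
    X = sm.add_constant(df[covariates].astype(float))
    fit = sm.Logit(y, X).fit(disp=0)
    logit = np.asarray(X @ fit.params, dtype=float)
    caliper = caliper_sd * logit.std(ddof=1)

    case_idx = np.flatnonzero(y.to_numpy() == 1)
    ctrl_idx = np.flatnonzero(y.to_numpy() == 0)
    case_idx = case_idx[np.argsort(-logit[case_idx], kind="mergesort")]
    order = np.argsort(logit[ctrl_idx], kind="mergesort")
    ctrl_sorted = ctrl_idx[order]
    ctrl_logit = logit[ctrl_sorted]
    available = np.ones(len(ctrl_sorted), dtype=bool)

    matched_cases, matched_ctrls, unmatched = [], [], []
    for ci in case_idx:
        lo = logit[ci]
        pos = np.searchsorted(ctrl_logit, lo)
        best, best_d = -1, np.inf
        for step in (-1, 0):
            j = pos + step
            while 0 <= j < len(ctrl_sorted) and not available[j]:
                j += -1 if step == -1 else 1
            if 0 <= j < len(ctrl_sorted):
                d = abs(ctrl_logit[j] - lo)
                if d < best_d:
                    best, best_d = j, d
        if best >= 0 and best_d <= caliper:
            available[best] = False
            matched_cases.append(ci)
            matched_ctrls.append(ctrl_sorted[best])
        else:
            unmatched.append(ci)
    if unmatched:
        warnings.warn(f"{len(unmatched)} cases unmatched within caliper", stacklevel=2)
    keep = np.concatenate([matched_cases, matched_ctrls]).astype(int)
    return df.loc[keep].reset_index(drop=True)


def standardized_mean_difference(
    table: pd.DataFrame, variable: str, group_col: str = "group"
) -> float:
    """Absolute standardized mean difference of ``variable`` between groups
    (balance diagnostic for matching)."""
    g = table[group_col]
    a = table.loc[g == "case", variable].astype(float)
    b = table.loc[g == "control", variable].astype(float)
    pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled_sd == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled_sd)
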