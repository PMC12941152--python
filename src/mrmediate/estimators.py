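"""Two-sample MR estimators and diagnostics on a harmonized set.

All estimators consume per-variant exposure effects beta_Xj (se sigma_Xj)
and outcome effects beta_Yj (se sigma_Yj) aligned to a common effect
allele.  The per-variant Wald ratio is beta_Yj / beta_Xj with first-order
standard error sigma_Yj / |beta_Xj|; the inverse-variance weighted (IVW)
estimate is the precision-weighted mean of those ratios, equivalently a
zero-intercept weighted regression of beta_Y on beta_X.  MR-Egger frees
the intercept, which absorbs (and tests for) directional horizontal
pleiotropy; weighted median and the mode-based estimators trade efficiency
for robustness to invalid instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import MethodError, ParameterError
from .harmonization import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    """One estimator's causal estimate with diagnostics."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None


def _result(method, beta, se, pval, n_snp, **kw) -> MRResult:
    return MRResult(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(pval),
        n_snp=int(n_snp),
        **kw,
    )


def _ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios and their first-order variances."""
    if np.any(h.beta_exp == 0):
        raise MethodError("zero exposure beta gives an undefined Wald ratio")
    r = h.beta_out / h.beta_exp
    var = (h.se_out / h.beta_exp) ** 2
    return r, var


def wald_ratio(h: HarmonizedSet) -> MRResult:
    """Single-variant causal estimate beta_Y / beta_X."""
    if h.n_snp != 1:
        raise MethodError("wald_ratio requires exactly one variant")
    bx = float(h.beta_exp[0])
    if bx == 0:
        raise MethodError("undefined Wald ratio: exposure beta is zero")
    beta = float(h.beta_out[0]) / bx
    se = float(h.se_out[0]) / abs(bx)
    p = 2 * stats.norm.sf(abs(beta / se))
    return _result("wald_ratio", beta, se, p, 1)


def ivw(h: HarmonizedSet, mode: str = "multiplicative_random") -> MRResult:
    """Inverse-variance weighted estimate.

    With weights ``w_j = beta_Xj**2 / sigma_Yj**2``:

        beta = sum(w_j * ratio_j) / sum(w_j)
        fixed SE = sum(w_j) ** -0.5
        multiplicative-random SE = fixed SE * max(1, sqrt(Q / (J - 1)))

    The multiplicative random-effects flavour (default) inflates the SE
    under heterogeneity but never deflates it below fixed-effects.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ParameterError(f"unknown IVW mode {mode!r}")
    if h.n_snp < 2:
        raise MethodError("IVW needs at least 2 variants; use wald_ratio for one")
    w = h.beta_exp**2 / h.se_out**2
    beta = float(np.sum(h.beta_exp * h.beta_out / h.se_out**2) / np.sum(w))
    se_fixed = float(np.sum(w)) ** -0.5
    ratios = h.beta_out / h.beta_exp
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = h.n_snp - 1
    se = se_fixed
    if mode == "multiplicative_random":
        se = se_fixed * max(1.0, math.sqrt(q / df))
    p = 2 * stats.norm.sf(abs(beta / se))
    method = "ivw_fe" if mode == "fixed" else "ivw_mre"
    return _result(
        method, beta, se, p, h.n_snp, q_stat=q, q_df=df, q_pval=float(stats.chi2.sf(q, df))
    )


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic of the per-variant ratios around
    the IVW estimate; chi-square upper-tail p on J-1 df."""
    res = ivw(h, mode="fixed")
    return res.q_stat, res.q_df, res.q_pval


def mr_egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger: weighted regression of beta_Y on beta_X with a free
    intercept, all variants pre-oriented so beta_X >= 0 (negating both
    members of a pair leaves the ratio unchanged but is required for the
    intercept to be identified).  Weights 1/sigma_Y**2; slope and intercept
    tested on t with J-2 df; SEs floored at the fixed-effect level via
    max(1, residual scale)."""
    if h.n_snp < 3:
        raise MethodError("MR-Egger needs at least 3 variants")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    bx = h.beta_exp * sign
    by = h.beta_out * sign
    w = 1.0 / h.se_out**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx_inv = np.linalg.inv(X.T @ WX)
    coef = xtwx_inv @ (WX.T @ by)
    resid = by - X @ coef
    df = h.n_snp - 2
    q_egger = float(np.sum(w * resid**2))
    scale = math.sqrt(q_egger / df)
    se_unit = np.sqrt(np.diag(xtwx_inv))
    se = se_unit * max(1.0, scale)
    slope, intercept = coef[1], coef[0]
    p_slope = 2 * stats.t.sf(abs(slope / se[1]), df)
    p_int = 2 * stats.t.sf(abs(intercept / se[0]), df)
    return _result(
        "egger",
        slope,
        se[1],
        p_slope,
        h.n_snp,
        q_stat=q_egger,
        q_df=df,
        q_pval=float(stats.chi2.sf(q_egger, df)),
        egger_intercept=float(intercept),
        egger_intercept_se=float(se[0]),
        egger_intercept_pval=float(p_int),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w)
    p = s - w / 2.0
    return float(np.interp(0.5, p, r))


def _bootstrap_se(h: HarmonizedSet, point_fn, reps: int, seed: int) -> float:
    """Parametric bootstrap: redraw beta_X, beta_Y from their sampling
    normals and recompute the point estimate."""
    rng = np.random.default_rng(seed)
    J = h.n_snp
    est = np.empty(reps)
    for i in range(reps):
        bx = h.beta_exp + h.se_exp * rng.standard_normal(J)
        by = h.beta_out + h.se_out * rng.standard_normal(J)
        bx = np.where(bx == 0, 1e-300, bx)
        est[i] = point_fn(by / bx, (h.se_out / bx) ** 2)
    return float(est.std(ddof=1))


def weighted_median(h: HarmonizedSet, reps: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median estimator: the 50%-weight point of the ordered
    per-variant ratios (consistent when valid instruments carry a majority
    of the weight).  SE from a seeded parametric bootstrap."""
    if h.n_snp < 3:
        raise MethodError("weighted median needs at least 3 variants")
    if reps < 100:
        import warnings

        warnings.warn("fewer than 100 bootstrap reps gives an unstable SE", stacklevel=2)
    ratios, var = _ratios(h)
    weights = 1.0 / var
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(h, lambda r, v: _weighted_median_point(r, 1.0 / v), reps, seed)
    p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta != 0 else 1.0)
    return _result("weighted_median", beta, se, p, h.n_snp)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    w = weights / weights.sum()
    sd = ratios.std(ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(sd, mad if mad > 0 else sd) * len(ratios) ** (-1 / 5)
    if s <= 0 or not np.isfinite(s):
        # all ratios (essentially) identical
        return float(ratios[0])
    hbw = bandwidth_factor * s
    grid = np.linspace(ratios.min() - 3 * hbw, ratios.max() + 3 * hbw, 512)
    dens = (w[None, :] * stats.norm.pdf((grid[:, None] - ratios[None, :]) / hbw)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    reps: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Mode-based estimate: the peak of a Gaussian kernel density over the
    per-variant ratios (Silverman-style bandwidth scaled by
    ``bandwidth_factor``), weighting the kernel by inverse ratio variance
    for the weighted variant.  Consistent when the largest cluster of
    instruments is valid.  SE from a seeded parametric bootstrap."""
    if bandwidth_factor <= 0:
        raise ParameterError("bandwidth_factor must be positive")
    if h.n_snp < 3:
        raise MethodError("mode estimators need at least 3 variants")
    ratios, var = _ratios(h)

    def point(r, v):
        w = 1.0 / v if weighted else np.ones_like(r)
        return _kde_mode(r, w, bandwidth_factor)

    beta = point(ratios, var)
    se = _bootstrap_se(h, point, reps, seed)
    p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta != 0 else 1.0)
    return _result("weighted_mode" if weighted else "simple_mode", beta, se, p, h.n_snp)


def all_methods(h: HarmonizedSet, reps: int = 1000, seed: int = 0) -> dict[str, MRResult]:
    """The five-method suite: IVW (multiplicative random effects),
    MR-Egger, weighted median, simple mode and weighted mode."""
    return {
        "ivw": ivw(h),
        "egger": mr_egger(h),
        "weighted_median": weighted_median(h, reps=reps, seed=seed),
        "simple_mode": mode_estimate(h, weighted=False, reps=reps, seed=seed),
        "weighted_mode": mode_estimate(h, weighted=True, reps=reps, seed=seed),
    }
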