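"""Multivariable MR and the two-step mediation calculus.

The mediation decomposition on the exposure -> mediator -> outcome triangle:

    total      = univariable MR of outcome on exposure (IVW, or MR-Egger
                 when the Egger intercept signals pleiotropy)
    direct     = exposure coefficient from multivariable MR with the
                 mediator as second exposure
    indirect   = step1 * step2   (product / two-step method, default)
               = total - direct  (difference method, reported alongside)

where step1 is the univariable exposure->mediator MR estimate and step2
the mediator->outcome estimate.  Confidence intervals for the indirect
effect use the first-order delta method with zero covariance between
steps — exact for independent GWAS samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CollinearExposuresError, MethodError, ParameterError
from .estimators import Z95, MRResult, ivw, mr_egger
from .gwas_io import PipelineConfig, SummaryStats
from .harmonization import HarmonizedSet, harmonize
from .instruments import select_instruments


@dataclass
class MVMRResult:
    """Direct effects of two exposures from multivariable IVW."""

    beta1: float
    se1: float
    pval1: float
    beta2: float
    se2: float
    pval2: float
    n_snp: int
    #: second exposure dropped as an all-zero column (reduces to univariable)
    exp2_dropped: bool = False


@dataclass
class MediationResult:
    """Full decomposition of an exposure->outcome effect through one mediator."""

    total_effect: float
    total_se: float
    total_method: str
    direct_effect: float
    direct_se: float
    step1_effect: float
    step1_se: float
    step2_effect: float
    step2_se: float
    indirect_effect: float
    indirect_se: float
    ci_low: float
    ci_high: float
    proportion_mediated: float | None
    indirect_difference: float | None = None
    indirect_difference_se: float | None = None
    inconsistent_mediation: bool = False


def mvmr_ivw(h: HarmonizedSet) -> MVMRResult:
    """Multivariable IVW: weighted least squares of beta_Y on
    (beta_X1, beta_X2) without intercept, weights 1/sigma_Y**2.  The
    coefficient on each exposure is its direct effect conditional on the
    other.  SEs floored at the fixed-effect level via max(1, residual
    scale); p-values from normal z.

    A second-exposure column that is identically zero is dropped (the fit
    reduces exactly to univariable IVW); near-collinear columns
    (|correlation| > 0.999) raise :class:`CollinearExposuresError`.
    """
    if h.beta_exp2 is None:
        raise MethodError("mvmr_ivw needs a harmonized second exposure")
    if h.n_snp < 3:
        raise MethodError("MVMR needs at least 3 variants")
    x1, x2, y = h.beta_exp, h.beta_exp2, h.beta_out
    w = 1.0 / h.se_out**2

    exp2_dropped = bool(np.all(x2 == 0))
    if not exp2_dropped:
        if np.std(x1) > 0 and np.std(x2) > 0:
            corr = abs(np.corrcoef(x1, x2)[0, 1])
            if corr > 0.999:
                raise CollinearExposuresError(
                    f"exposure effect columns nearly collinear (|r| = {corr:.5f})"
                )
        X = np.column_stack([x1, x2])
    else:
        X = x1[:, None]

    WX = X * w[:, None]
    xtwx = X.T @ WX
    try:
        xtwx_inv = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise CollinearExposuresError("singular design in MVMR") from exc
    coef = xtwx_inv @ (WX.T @ y)
    resid = y - X @ coef
    df = h.n_snp - X.shape[1]
    scale = math.sqrt(float(np.sum(w * resid**2)) / df) if df > 0 else 1.0
    se = np.sqrt(np.diag(xtwx_inv)) * max(1.0, scale)

    if exp2_dropped:
        b1, s1 = float(coef[0]), float(se[0])
        b2, s2, p2 = 0.0, float("nan"), float("nan")
    else:
        b1, s1 = float(coef[0]), float(se[0])
        b2, s2 = float(coef[1]), float(se[1])
        p2 = 2 * stats.norm.sf(abs(b2 / s2))
    p1 = 2 * stats.norm.sf(abs(b1 / s1))
    return MVMRResult(b1, s1, float(p1), b2, s2, float(p2), h.n_snp, exp2_dropped)


def indirect_product(
    step1: float, step1_se: float, step2: float, step2_se: float
) -> tuple[float, float]:
    """Product-method indirect effect with first-order delta SE:
    ``sqrt(b1**2 * s2**2 + b2**2 * s1**2)`` (independent steps)."""
    ind = step1 * step2
    se = math.sqrt(step1**2 * step2_se**2 + step2**2 * step1_se**2)
    return ind, se


def indirect_difference(
    total: float, total_se: float, direct: float, direct_se: float
) -> tuple[float, float]:
    """Difference-method indirect effect, ``total - direct``, with the
    zero-covariance SE ``sqrt(s_total**2 + s_direct**2)``."""
    return total - direct, math.sqrt(total_se**2 + direct_se**2)


def select_total_effect(
    ivw_result: MRResult, egger_result: MRResult, alpha: float = 0.05
) -> tuple[float, float, str]:
    """Pick the total-effect estimate: IVW when the Egger intercept shows
    no directional pleiotropy (p > alpha); otherwise MR-Egger, but only if
    its slope is itself significant; else flag ``no-valid-total``."""
    if egger_result.egger_intercept_pval is None:
        raise ParameterError("egger_result lacks an intercept test")
    if egger_result.egger_intercept_pval > alpha:
        return ivw_result.beta, ivw_result.se, "ivw"
    if egger_result.pval < alpha:
        return egger_result.beta, egger_result.se, "egger"
    return ivw_result.beta, ivw_result.se, "no-valid-total"


def proportion_mediated(indirect: float, total: float) -> float:
    """Mediated percentage, 100 * indirect / total.  Values outside
    [0, 100] (inconsistent mediation: opposing direct and indirect paths)
    are returned as-is with a warning."""
    if total == 0:
        raise ParameterError("proportion mediated undefined for zero total effect")
    pct = 100.0 * indirect / total
    if not 0 <= pct <= 100:
        warnings.warn(
            f"proportion mediated {pct:.2f}% outside [0, 100]: inconsistent mediation",
            stacklevel=2,
        )
    return pct


def two_step_mediation(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    config: PipelineConfig | None = None,
) -> MediationResult:
    """Run the full mediation pipeline on three summary-statistics tables.

    Steps: select exposure instruments (primary p threshold) and mediator
    instruments (the more lenient threshold); univariable IVW for
    exposure->mediator (step 1), mediator->outcome (step 2) and
    exposure->outcome (total, with the IVW->Egger fallback); MVMR over the
    union of instruments for the direct effect; indirect effect by the
    product method (difference method reported alongside) with a 95%
    delta-method interval.
    """
    cfg = config or PipelineConfig()
    exp_iv = select_instruments(
        exposure, cfg.p_instrument_primary, r2_max=cfg.clump_r2, window_kb=cfg.clump_window_kb
    )
    med_iv = select_instruments(
        mediator, cfg.p_instrument_microbiome, r2_max=cfg.clump_r2, window_kb=cfg.clump_window_kb
    )
    if len(exp_iv) < 2 or len(med_iv) < 2:
        raise MethodError("too few instruments for mediation analysis")
    w = cfg.palindrome_eaf_window

    h_step1 = harmonize(exp_iv, mediator, eaf_window=w)
    step1 = ivw(h_step1)
    h_step2 = harmonize(med_iv, outcome, eaf_window=w)
    step2 = ivw(h_step2)

    h_total = harmonize(exp_iv, outcome, eaf_window=w)
    total_ivw = ivw(h_total)
    total_egger = mr_egger(h_total)
    total, total_se, total_method = select_total_effect(
        total_ivw, total_egger, alpha=0.05
    )

    union_ids = sorted(set(exp_iv.table["variant_id"]) | set(med_iv.table["variant_id"]))
    exp_union = exposure.subset(union_ids)
    h_mvmr = harmonize(exp_union, outcome, eaf_window=w, second_exposure=mediator)
    direct = mvmr_ivw(h_mvmr)

    ind, ind_se = indirect_product(step1.beta, step1.se, step2.beta, step2.se)
    ind_diff, ind_diff_se = indirect_difference(total, total_se, direct.beta1, direct.se1)
    prop = None
    inconsistent = False
    if total_method != "no-valid-total" and total != 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prop = proportion_mediated(ind, total)
        inconsistent = not 0 <= prop <= 100

    return MediationResult(
        total_effect=total,
        total_se=total_se,
        total_method=total_method,
        direct_effect=direct.beta1,
        direct_se=direct.se1,
        step1_effect=step1.beta,
        step1_se=step1.se,
        step2_effect=step2.beta,
        step2_se=step2.se,
        indirect_effect=ind,
        indirect_se=ind_se,
        ci_low=ind - Z95 * ind_se,
        ci_high=ind + Z95 * ind_se,
        proportion_mediated=prop,
        indirect_difference=ind_diff,
        indirect_difference_se=ind_diff_se,
        inconsistent_mediation=inconsistent,
    )
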