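"""Discovery screening: forward MR over many candidate outcomes, BH-FDR
correction, reverse-direction MR to flag reverse causation, and the
hand-off list of mediation candidates.

FDR families are defined per screen direction (one Benjamini–Hochberg
family across the forward IVW p-values, another across the reverse ones),
matching per-analysis correction of a taxon-wide scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import EmptyIntersectionError, MethodError, ParameterError
from .estimators import ivw, mr_egger
from .gwas_io import PipelineConfig, SummaryStats
from .harmonization import harmonize
from .instruments import select_instruments


def bh_fdr(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values: ``q_(i) = min_{j >= i}
    (m * p_(j) / j)`` capped at 1, returned in the input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenReport:
    """Outcome of one bidirectional screen."""

    results: pd.DataFrame
    survivors: list[str]
    mediation_candidates: list[str]
    skipped: list[str] = field(default_factory=list)
    audit: dict = field(default_factory=dict)


def _mr_row(exposure_iv: SummaryStats, outcome: SummaryStats, cfg: PipelineConfig):
    h = harmonize(exposure_iv, outcome, eaf_window=cfg.palindrome_eaf_window)
    if h.n_snp < 2:
        raise MethodError("fewer than 2 harmonizable variants")
    res = ivw(h)
    row = {
        "n_snp": res.n_snp,
        "beta": res.beta,
        "se": res.se,
        "pval": res.pval,
        "q_stat": res.q_stat,
        "q_pval": res.q_pval,
        "egger_intercept": np.nan,
        "egger_intercept_pval": np.nan,
    }
    if h.n_snp >= 3:
        eg = mr_egger(h)
        row["egger_intercept"] = eg.egger_intercept
        row["egger_intercept_pval"] = eg.egger_intercept_pval
    return row


def run_screen(
    exposure: SummaryStats,
    candidate_outcomes: Iterable[SummaryStats],
    config: PipelineConfig | None = None,
    bidirectional: bool = True,
) -> ScreenReport:
    """Screen ``exposure`` against every candidate outcome.

    Forward: IVW (plus heterogeneity and Egger-intercept diagnostics) of
    each outcome on the exposure's instruments, then one BH-FDR family over
    the forward IVW p-values; survivors are outcomes with q < fdr_alpha.
    Reverse (``bidirectional``): roles swapped for each survivor, using
    the lenient microbiome instrument threshold for the candidate-side
    exposure; survivors whose reverse q < fdr_alpha are flagged
    reverse-causal and removed from the mediation candidates.

    Pairs with fewer than 2 harmonizable variants are skipped and logged;
    the run continues.
    """
    cfg = config or PipelineConfig()
    outcomes = list(candidate_outcomes)
    exp_iv = select_instruments(
        exposure, cfg.p_instrument_primary, r2_max=cfg.clump_r2, window_kb=cfg.clump_window_kb
    )
    if len(exp_iv) == 0:
        raise MethodError(f"no instruments for {exposure.trait_id}")

    rows = []
    skipped: list[str] = []
    for out in outcomes:
        try:
            row = _mr_row(exp_iv, out, cfg)
        except (MethodError, EmptyIntersectionError) as exc:
            skipped.append(out.trait_id)
            warnings.warn(f"skipping {out.trait_id}: {exc}", stacklevel=2)
            continue
        row.update(exposure=exposure.trait_id, outcome=out.trait_id, direction="forward")
        rows.append(row)

    results = pd.DataFrame(rows)
    survivors: list[str] = []
    if not results.empty:
        results["q_value"] = bh_fdr(results["pval"])
        survivors = list(results.loc[results["q_value"] < cfg.fdr_alpha, "outcome"])

    reverse_flagged: list[str] = []
    if bidirectional and survivors:
        by_id = {o.trait_id: o for o in outcomes}
        rev_rows = []
        for tid in survivors:
            out = by_id[tid]
            try:
                rev_iv = select_instruments(
                    out,
                    cfg.p_instrument_microbiome,
                    r2_max=cfg.clump_r2,
                    window_kb=cfg.clump_window_kb,
                )
                if len(rev_iv) == 0:
                    raise MethodError("no reverse instruments")
                row = _mr_row(rev_iv, exposure, cfg)
            except (MethodError, EmptyIntersectionError) as exc:
                skipped.append(f"reverse:{tid}")
                warnings.warn(f"skipping reverse MR for {tid}: {exc}", stacklevel=2)
                continue
            row.update(exposure=tid, outcome=exposure.trait_id, direction="reverse")
            rev_rows.append(row)
        if rev_rows:
            rev = pd.DataFrame(rev_rows)
            rev["q_value"] = bh_fdr(rev["pval"])
            reverse_flagged = list(rev.loc[rev["q_value"] < cfg.fdr_alpha, "exposure"])
            results = pd.concat([results, rev], ignore_index=True)

    front = ["exposure", "outcome", "direction"]
    if not results.empty:
        results = results[front + [c for c in results.columns if c not in front]]
    mediation_candidates = [t for t in survivors if t not in set(reverse_flagged)]
    audit = {
        "exposure": exposure.trait_id,
        "n_outcomes": len(outcomes),
        "n_instruments": len(exp_iv),
        "p_instrument_primary": cfg.p_instrument_primary,
        "p_instrument_microbiome": cfg.p_instrument_microbiome,
        "fdr_alpha": cfg.fdr_alpha,
        "palindrome_eaf_window": cfg.palindrome_eaf_window,
        "bidirectional": bidirectional,
        "seed": cfg.seed,
        "reverse_flagged": reverse_flagged,
    }
    return ScreenReport(
        results=results,
        survivors=survivors,
        mediation_candidates=mediation_candidates,
        skipped=skipped,
        audit=audit,
    )
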