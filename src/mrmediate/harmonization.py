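"""Allele harmonization of exposure and outcome summary statistics.

All retained variants are expressed on the exposure's effect-allele
orientation.  An outcome record listing the same allele pair passes
through; one listing the swapped pair has its beta negated and EAF
reflected; a strand-complement pair (e.g. C/T reported as G/A) is resolved
before either rule.  Palindromic variants (A/T or G/C), whose strand
cannot be resolved from alleles, are kept only when both effect-allele
frequencies are informative — available and strictly outside the ambiguity
window around 0.5 — and are oriented by frequency agreement; otherwise
they are excluded.  Any allele pair matching none of these patterns is
incompatible (e.g. a different variant at the same id) and excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyIntersectionError
from .gwas_io import SummaryStats

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: exclusion reason codes
PALINDROMIC_AMBIGUOUS = "palindromic-ambiguous"
INCOMPATIBLE_ALLELES = "incompatible-alleles"
MISSING_IN_OUTCOME = "missing-in-outcome"


@dataclass
class HarmonizedSet:
    """Exposure/outcome (and optional second-exposure) effects aligned to a
    common effect allele, ready for the MR estimators."""

    variant_ids: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_exp: np.ndarray | None = None
    beta_exp2: np.ndarray | None = None
    se_exp2: np.ndarray | None = None
    exclusion_log: dict[str, str] = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    def __len__(self) -> int:
        return len(self.variant_ids)

    def subset(self, index) -> "HarmonizedSet":
        index = np.asarray(index)
        return HarmonizedSet(
            variant_ids=self.variant_ids[index],
            beta_exp=self.beta_exp[index],
            se_exp=self.se_exp[index],
            beta_out=self.beta_out[index],
            se_out=self.se_out[index],
            eaf_exp=None if self.eaf_exp is None else self.eaf_exp[index],
            beta_exp2=None if self.beta_exp2 is None else self.beta_exp2[index],
            se_exp2=None if self.se_exp2 is None else self.se_exp2[index],
            exclusion_log=dict(self.exclusion_log),
        )

    def to_frame(self) -> pd.DataFrame:
        d = {
            "variant_id": self.variant_ids,
            "beta_exp": self.beta_exp,
            "se_exp": self.se_exp,
            "beta_out": self.beta_out,
            "se_out": self.se_out,
        }
        if self.beta_exp2 is not None:
            d["beta_exp2"] = self.beta_exp2
            d["se_exp2"] = self.se_exp2
        return pd.DataFrame(d)


def _align_to_exposure(
    exp: pd.DataFrame,
    other: pd.DataFrame,
    eaf_window: float,
    drop_palindromic: bool,
):
    """Align ``other`` onto ``exp``'s allele orientation.

    Returns (aligned beta, aligned se, keep mask, reasons array) over the
    rows of the merged frame (exp and other already joined on variant_id).
    """
    ea_x = exp["effect_allele"].to_numpy()
    oa_x = exp["other_allele"].to_numpy()
    ea_o = other["effect_allele"].to_numpy()
    oa_o = other["other_allele"].to_numpy()
    eaf_x = exp["eaf"].to_numpy(dtype=float)
    eaf_o = other["eaf"].to_numpy(dtype=float)
    beta = other["beta"].to_numpy(dtype=float).copy()
    se = other["se"].to_numpy(dtype=float)

    comp = np.vectorize(_COMPLEMENT.get)
    palindromic = ea_x == comp(oa_x)

    same = (ea_o == ea_x) & (oa_o == oa_x)
    swapped = (ea_o == oa_x) & (oa_o == ea_x)
    comp_same = (comp(ea_o) == ea_x) & (comp(oa_o) == oa_x)
    comp_swapped = (comp(ea_o) == oa_x) & (comp(oa_o) == ea_x)

    keep = np.ones(len(beta), dtype=bool)
    reasons = np.full(len(beta), "", dtype=object)
    flip = np.zeros(len(beta), dtype=bool)

    # non-palindromic: allele patterns identify the orientation
    np_mask = ~palindromic
    flip[np_mask & (swapped | comp_swapped)] = True
    bad = np_mask & ~(same | swapped | comp_same | comp_swapped)
    keep[bad] = False
    reasons[bad] = INCOMPATIBLE_ALLELES

    # palindromic: both allele codings look identical up to strand; the pair
    # of alleles must still match (A/T vs A/T or T/A), else incompatible
    pal_pair_ok = palindromic & (same | swapped)
    bad = palindromic & ~pal_pair_ok
    keep[bad] = False
    reasons[bad] = INCOMPATIBLE_ALLELES

    if drop_palindromic:
        drop = pal_pair_ok
        keep[drop] = False
        reasons[drop] = PALINDROMIC_AMBIGUOUS
    else:
        with np.errstate(invalid="ignore"):
            informative = (
                np.isfinite(eaf_x)
                & np.isfinite(eaf_o)
                & (np.abs(eaf_x - 0.5) > eaf_window)
                & (np.abs(eaf_o - 0.5) > eaf_window)
            )
        ambiguous = pal_pair_ok & ~informative
        keep[ambiguous] = False
        reasons[ambiguous] = PALINDROMIC_AMBIGUOUS
        # orientations agree when the frequencies sit on the same side of 0.5
        resolved = pal_pair_ok & informative
        disagree = resolved & ((eaf_x < 0.5) != (eaf_o < 0.5))
        flip[disagree] = True

    beta[flip] = -beta[flip]
    return beta, se, keep, reasons


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    eaf_window: float = 0.08,
    second_exposure: SummaryStats | None = None,
    drop_palindromic: bool = False,
) -> HarmonizedSet:
    """Harmonize outcome (and optionally a second exposure) to the exposure
    instruments' effect alleles.

    Parameters
    ----------
    eaf_window
        Half-width of the palindrome ambiguity window around EAF 0.5.
    drop_palindromic
        Exclude all palindromic variants regardless of frequency.

    Raises :class:`EmptyIntersectionError` when no variant id is shared at
    all; when variants intersect but every one is excluded a warning is
    emitted and an empty set (with the full exclusion log) returned.
    """
    exp = exposure.table
    merged = exp.merge(
        outcome.table, on="variant_id", how="left", suffixes=("", "_out"), sort=False
    )
    exclusion: dict[str, str] = {}

    present = merged["beta_out"].notna().to_numpy()
    if not present.any():
        raise EmptyIntersectionError(
            f"no shared variants between {exposure.trait_id} and {outcome.trait_id}"
        )
    for vid in merged.loc[~present, "variant_id"]:
        exclusion[vid] = MISSING_IN_OUTCOME

    both = merged[present].reset_index(drop=True)
    out_view = both[
        ["effect_allele_out", "other_allele_out", "eaf_out", "beta_out", "se_out"]
    ].rename(columns=lambda c: c[:-4])
    beta_o, se_o, keep, reasons = _align_to_exposure(
        both, out_view, eaf_window, drop_palindromic
    )

    beta_x2 = se_x2 = None
    if second_exposure is not None:
        m2 = both.merge(
            second_exposure.table, on="variant_id", how="left", suffixes=("", "_e2")
        )
        present2 = m2["beta_e2"].notna().to_numpy()
        e2_view = m2[
            ["effect_allele_e2", "other_allele_e2", "eaf_e2", "beta_e2", "se_e2"]
        ].rename(columns=lambda c: c[:-3])
        beta_x2, se_x2, keep2, reasons2 = _align_to_exposure(
            m2, e2_view, eaf_window, drop_palindromic
        )
        keep2 &= present2
        reasons2[~present2] = MISSING_IN_OUTCOME
        newly_bad = keep & ~keep2
        reasons[newly_bad] = reasons2[newly_bad]
        keep &= keep2

    for vid, r in zip(both["variant_id"], reasons):
        if r:
            exclusion[vid] = r

    hs = HarmonizedSet(
        variant_ids=both["variant_id"].to_numpy()[keep],
        beta_exp=both["beta"].to_numpy(dtype=float)[keep],
        se_exp=both["se"].to_numpy(dtype=float)[keep],
        beta_out=beta_o[keep],
        se_out=se_o[keep],
        eaf_exp=both["eaf"].to_numpy(dtype=float)[keep],
        beta_exp2=None if beta_x2 is None else beta_x2[keep],
        se_exp2=None if se_x2 is None else se_x2[keep],
        exclusion_log=exclusion,
    )
    if hs.n_snp == 0:
        warnings.warn(
            f"all {len(both)} shared variants excluded during harmonization "
            f"({exposure.trait_id} vs {outcome.trait_id})",
            stacklevel=2,
        )
    return hs
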