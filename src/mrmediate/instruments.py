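"""Instrument selection: p-value thresholding, greedy LD clumping and
instrument-strength (F-statistic) checks.

LD is supplied as a user-provided pairwise r-squared lookup (e.g. exported
from an external clumping service); no reference panel is bundled.  When no
lookup is given, pairs within the window are treated as independent unless
``distance_only=True`` demands distance-based pruning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParameterError
from .gwas_io import SummaryStats


@dataclass(frozen=True)
class InstrumentStrength:
    """Strength summary of an instrument set.

    ``f_stat = (r2_total / k) * (n - k - 1) / (1 - r2_total)`` — the
    standard k-instrument F approximation from the variance explained.
    """

    r2_total: float
    n: int
    k: int
    f_stat: float


def f_statistic(r2_total: float, n: int, k: int) -> InstrumentStrength:
    """F-statistic for k instruments jointly explaining ``r2_total`` of the
    exposure variance in a GWAS of n samples.  F > 10 is the conventional
    weak-instrument cut."""
    if not 0 <= r2_total < 1:
        raise ParameterError("r2_total must lie in [0, 1)")
    if k < 1:
        raise ParameterError("k must be at least 1")
    if n <= k + 1:
        raise ParameterError("need n > k + 1")
    f = (r2_total / k) * (n - k - 1) / (1.0 - r2_total)
    return InstrumentStrength(r2_total=r2_total, n=n, k=k, f_stat=f)


def variance_explained(ss: SummaryStats) -> float:
    """Proportion of exposure variance explained by the instruments,
    ``sum_j 2 * eaf_j * (1 - eaf_j) * beta_j**2`` (variance-standardised
    trait).  Records missing EAF are skipped with a warning."""
    t = ss.table
    have = t["eaf"].notna()
    if not have.any():
        raise EmptyInputError("cannot compute variance explained: all EAFs missing")
    if (~have).any():
        warnings.warn(
            f"{int((~have).sum())} records missing EAF skipped in variance_explained",
            stacklevel=2,
        )
    eaf = t.loc[have, "eaf"].to_numpy()
    beta = t.loc[have, "beta"].to_numpy()
    return float(np.sum(2.0 * eaf * (1.0 - eaf) * beta**2))


def read_ld_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a pairwise LD file with columns variant_a, variant_b, r2."""
    df = pd.read_csv(path, sep=None, engine="python")
    return {
        (str(a), str(b)): float(r)
        for a, b, r in zip(df["variant_a"], df["variant_b"], df["r2"])
    }


def _pair_r2(ld: Mapping[tuple[str, str], float], a: str, b: str) -> float | None:
    if (a, b) in ld:
        return ld[(a, b)]
    if (b, a) in ld:
        return ld[(b, a)]
    return None


def select_instruments(
    ss: SummaryStats,
    p_threshold: float = 1e-6,
    ld: Mapping[tuple[str, str], float] | None = None,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
    distance_only: bool = False,
) -> SummaryStats:
    """Threshold on p then greedily clump.

    Candidates with ``pval < p_threshold`` are visited in ascending p
    (ties broken by variant_id); a candidate is dropped when it lies within
    ``window_kb`` of an already-kept variant on the same chromosome and
    their pairwise r² (from ``ld``) is at least ``r2_max``.  Pairs absent
    from ``ld`` count as independent, unless ``distance_only`` makes any
    within-window pair count as linked.

    An empty result (nothing passes the threshold) returns an empty
    SummaryStats with a warning rather than raising.
    """
    if len(ss) == 0:
        raise EmptyInputError("empty summary statistics")
    t = ss.table
    cand = t[t["pval"] < p_threshold].copy()
    if cand.empty:
        warnings.warn(
            f"no variant passes p < {p_threshold:g} for {ss.trait_id}", stacklevel=2
        )
        return SummaryStats(ss.trait_id, t.iloc[0:0].copy(), ss.trait_label)

    cand = cand.sort_values(["pval", "variant_id"], kind="mergesort")
    window_bp = int(window_kb) * 1000
    kept_rows: list[int] = []
    kept_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for idx, row in cand.iterrows():
        clumped = False
        for kpos, kid in kept_by_chrom.get(row["chrom"], ()):
            if abs(int(row["pos"]) - kpos) <= window_bp:
                if distance_only:
                    clumped = True
                    break
                r2 = None if ld is None else _pair_r2(ld, row["variant_id"], kid)
                if r2 is not None and r2 >= r2_max:
                    clumped = True
                    break
        if not clumped:
            kept_rows.append(idx)
            kept_by_chrom.setdefault(row["chrom"], []).append(
                (int(row["pos"]), row["variant_id"])
            )
    kept = t.loc[sorted(kept_rows)].copy()
    return SummaryStats(ss.trait_id, kept, ss.trait_label)
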