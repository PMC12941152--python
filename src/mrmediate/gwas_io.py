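"""Reading, writing and validation of GWAS summary-statistics tables.

The canonical on-disk format is a tab-separated table with header

    variant_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

one row per biallelic SNP.  ``eaf`` (effect-allele frequency) may be missing,
written as ``NA``; ``NA``, ``""`` and ``"."`` are accepted on read.  Positions
are 1-based.  Only single-nucleotide A/C/G/T alleles are accepted — indel
rows are rejected, since every downstream step (harmonization in particular)
assumes biallelic SNPs.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, EmptyInputError, ParameterError

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: columns that must be present (possibly via a column map); eaf is optional
MANDATORY_COLUMNS = [c for c in CANONICAL_COLUMNS if c != "eaf"]

_NA_TOKENS = {"NA", "", ".", "nan", "NaN"}
_VALID_ALLELES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise ParameterError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ParameterError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ParameterError("effect and other allele must differ")
        if not self.se > 0:
            raise ParameterError("se must be positive")
        if not 0 < self.pval <= 1:
            raise ParameterError("pval must lie in (0, 1]")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ParameterError("eaf must lie strictly inside (0, 1)")
        if self.n <= 0:
            raise ParameterError("sample size must be positive")


@dataclass
class SummaryStats:
    """A set of per-variant summary associations for a single trait.

    Backed by a :class:`pandas.DataFrame` with the canonical columns; row
    order is preserved through round-trips and ``variant_id`` is unique.
    """

    trait_id: str
    table: pd.DataFrame
    trait_label: str = ""
    #: per-row rejection report populated by :func:`read_summary_stats`
    rejected: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"summary table missing columns: {missing}")
        if self.table["variant_id"].duplicated().any():
            dupes = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"]
            raise ConfigurationError(f"duplicate variant ids: {sorted(set(dupes))[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> list[VariantAssociation]:
        out = []
        for row in self.table.itertuples(index=False):
            eaf = None if pd.isna(row.eaf) else float(row.eaf)
            out.append(
                VariantAssociation(
                    variant_id=str(row.variant_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    effect_allele=str(row.effect_allele),
                    other_allele=str(row.other_allele),
                    beta=float(row.beta),
                    se=float(row.se),
                    pval=float(row.pval),
                    n=int(row.n),
                    eaf=eaf,
                )
            )
        return out

    @classmethod
    def from_records(
        cls, trait_id: str, records: list[VariantAssociation], trait_label: str = ""
    ) -> "SummaryStats":
        rows = []
        for r in records:
            d = dataclasses.asdict(r)
            d["eaf"] = math.nan if d["eaf"] is None else d["eaf"]
            rows.append(d)
        table = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        return cls(trait_id=trait_id, table=table, trait_label=trait_label)

    def subset(self, variant_ids) -> "SummaryStats":
        keep = self.table[self.table["variant_id"].isin(set(variant_ids))]
        return SummaryStats(self.trait_id, keep.copy(), self.trait_label)


@dataclass
class PipelineConfig:
    """Thresholds and seeds steering instrument selection, harmonization,
    FDR screening and bootstrap-based estimators.

    ``p_instrument_primary`` is the instrument p-value cut for the primary
    exposure; ``p_instrument_microbiome`` the more lenient cut used for
    microbial-abundance exposures whose GWAS rarely reach genome-wide
    significance.
    """

    p_instrument_primary: float = 1e-6
    p_instrument_microbiome: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    palindrome_eaf_window: float = 0.08
    fdr_alpha: float = 0.05
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_instrument_primary",
            "p_instrument_microbiome",
            "clump_r2",
            "clump_window_kb",
            "f_min",
            "fdr_alpha",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 <= self.palindrome_eaf_window < 0.5:
            raise ParameterError("palindrome_eaf_window must lie in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return path


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_label: str = "",
) -> SummaryStats:
    """Read a summary-statistics table, validating every row.

    Parameters
    ----------
    path
        Tab- or comma-separated file with a header row.
    column_map
        Optional mapping from canonical names to the file's column names,
        e.g. ``{"variant_id": "SNP", "pval": "P"}``.  The ``eaf`` column may
        be mapped to ``None`` to declare it absent.

    Rows violating the per-variant invariants (non-ACGT or identical
    alleles, non-positive SE, p outside (0,1], EAF outside (0,1), duplicate
    id) are dropped; a per-row report is attached as ``result.rejected``
    with columns ``row`` (0-based data row) and ``reason``.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    eaf_declared_absent = "eaf" in column_map and column_map["eaf"] is None

    raw = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)

    rename = {}
    for canon in CANONICAL_COLUMNS:
        source = column_map.get(canon, canon)
        if source is None:
            continue
        if source in raw.columns:
            rename[source] = canon
        elif canon in MANDATORY_COLUMNS:
            raise ConfigurationError(
                f"missing mandatory column {canon!r} (looked for {source!r}) in {path}"
            )
    df = raw.rename(columns=rename)
    if "eaf" not in df.columns or eaf_declared_absent:
        df["eaf"] = "NA"
    df = df[CANONICAL_COLUMNS].copy()

    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.strip().str.upper()
    df["variant_id"] = df["variant_id"].str.strip()
    df["chrom"] = df["chrom"].str.strip()

    def to_num(col: str) -> pd.Series:
        s = df[col].str.strip()
        s = s.where(~s.isin(_NA_TOKENS), other=np.nan)
        return pd.to_numeric(s, errors="coerce")

    pos = to_num("pos")
    eaf = to_num("eaf")
    beta = to_num("beta")
    se = to_num("se")
    pval = to_num("pval")
    n = to_num("n")
    eaf_token_missing = df["eaf"].str.strip().isin(_NA_TOKENS)

    flag(df["variant_id"] == "", "empty variant_id")
    flag(~df["effect_allele"].isin(_VALID_ALLELES), "effect_allele not a single A/C/G/T base")
    flag(~df["other_allele"].isin(_VALID_ALLELES), "other_allele not a single A/C/G/T base")
    flag(df["effect_allele"] == df["other_allele"], "effect and other allele identical")
    flag(pos.isna() | (pos < 1) | (pos != pos.round()), "invalid position")
    flag(beta.isna() | ~np.isfinite(beta), "invalid beta")
    flag(se.isna() | ~(se > 0), "se not positive")
    flag(pval.isna() | ~((pval > 0) & (pval <= 1)), "pval outside (0, 1]")
    flag(n.isna() | ~(n > 0) | (n != n.round()), "invalid sample size")
    flag(eaf.notna() & ~((eaf > 0) & (eaf < 1)), "eaf outside (0, 1)")
    flag(~eaf_token_missing & eaf.isna(), "unparseable eaf")
    flag(df["variant_id"].duplicated(), "duplicate variant_id")

    bad = reasons != ""
    rejected = pd.DataFrame({"row": df.index[bad], "reason": reasons[bad]}).reset_index(
        drop=True
    )
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} of {len(df)} rows rejected while reading {path.name}",
            stacklevel=2,
        )

    clean = pd.DataFrame(
        {
            "variant_id": df["variant_id"],
            "chrom": df["chrom"],
            "pos": pos,
            "effect_allele": df["effect_allele"],
            "other_allele": df["other_allele"],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )[~bad]
    if clean.empty:
        raise EmptyInputError(f"no valid summary-statistic rows in {path}")
    clean["pos"] = clean["pos"].astype(np.int64)
    clean["n"] = clean["n"].astype(np.int64)

    ss = SummaryStats(
        trait_id=trait_id if trait_id is not None else path.stem,
        table=clean.reset_index(drop=True),
        trait_label=trait_label,
    )
    ss.rejected = rejected
    return ss


def write_summary_stats(ss: SummaryStats, path: str | Path) -> Path:
    """Write ``ss`` as a canonical TSV; floats at 10 significant digits,
    missing EAF as ``NA``.  Round-trips through :func:`read_summary_stats`."""
    if len(ss) == 0:
        raise EmptyInputError("refusing to write an empty summary-statistics table")
    path = Path(path)
    out = ss.table.copy()
    for col in ("eaf", "beta", "se", "pval"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else format(v, ".10g"))
    out.to_csv(path, sep="\t", index=False, columns=CANONICAL_COLUMNS)
    return path
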