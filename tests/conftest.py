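import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedSet, SummaryStats
from mrmediate.gwas_io import CANONICAL_COLUMNS

_ALLELE_PAIRS = [("A", "G"), ("T", "C"), ("C", "A"), ("G", "T")]


def make_harmonized(beta_exp, se_out, beta_out=None, se_exp=None, beta_exp2=None, se_exp2=None):
    """Build a HarmonizedSet directly from effect vectors (default exposure
    SE is tiny, so ratio-based oracles are exact)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    if beta_out is None:
        beta_out = np.zeros_like(beta_exp)
    beta_out = np.asarray(beta_out, dtype=float)
    se_exp = np.full_like(beta_exp, 1e-6) if se_exp is None else np.asarray(se_exp, float)
    return HarmonizedSet(
        variant_ids=np.array([f"rs{i}" for i in range(len(beta_exp))]),
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        beta_exp2=None if beta_exp2 is None else np.asarray(beta_exp2, float),
        se_exp2=None if se_exp2 is None else np.asarray(se_exp2, float),
    )


def make_sumstats(rows, trait_id="trait"):
    """SummaryStats from a list of dicts; unspecified fields get benign
    defaults (distinct ids/positions, A/G alleles, eaf 0.3, n 10000)."""
    full = []
    for i, row in enumerate(rows):
        ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        base = {
            "variant_id": f"rs{i + 1}",
            "chrom": "1",
            "pos": 1_000_000 + i * 20_000_000,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": 0.3,
            "beta": 0.1,
            "se": 0.01,
            "pval": 1e-8,
            "n": 10_000,
        }
        base.update(row)
        full.append(base)
    return SummaryStats(trait_id, pd.DataFrame(full, columns=CANONICAL_COLUMNS))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_harmonized(rng, n=10):
    """A random but well-conditioned harmonized set for oracle checks."""
    bx = rng.uniform(0.05, 0.2, n) * rng.choice([-1, 1], n)
    sy = rng.uniform(0.005, 0.02, n)
    by = rng.normal(0.0, 0.05, n)
    sx = rng.uniform(0.002, 0.01, n)
    return make_harmonized(bx, sy, by, se_exp=sx)
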