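"""Synthetic GWAS summary statistics from a known causal triangle.

The generator emulates the two-sample setting: three independent GWAS —
exposure X, mediator M, outcome Y — measured on non-overlapping samples,
coupled through the structural model

    X  <-  G_j  (per-SNP instrument effects gamma_j,  j = 1..J)
    M  =  alpha * X  (+ its own instruments delta_k,  k = 1..K)
    Y  =  c' * X  +  b * M  (+ per-SNP pleiotropy e_j on the X-instruments)

so the total X->Y effect is ``c' + alpha*b`` and the mediated share is
``alpha*b / (c' + alpha*b)``.  Everything is generated directly at the
summary level: the estimated per-SNP effect is the true marginal effect
plus Gaussian sampling noise with standard error
``1 / sqrt(2 * maf * (1 - maf) * n)``, the usual approximation for a
variance-standardised trait.  No individual-level genotypes are simulated.

Mediator-specific instruments (the ``delta`` block) are included because
with instruments acting only through X the exposure and mediator effect
vectors are exactly proportional, leaving multivariable MR and the
mediator->outcome step unidentified; real microbiome GWAS instruments are
likewise not instruments of the upstream disorder.

Requested fractions of palindromic (A/T, G/C) variants and of variants
whose outcome allele coding is swapped are planted so harmonization has
real work to do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .gwas_io import CANONICAL_COLUMNS, SummaryStats

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class TriangleTruth:
    """Ground-truth parameters of one simulated exposure->mediator->outcome
    triangle.

    Parameters
    ----------
    n_snps
        J, number of exposure instruments (default 50).
    gamma
        Per-SNP instrument effects on the exposure.  May be an array of
        length ``n_snps`` or a ``(low, high)`` pair from which effects are
        drawn uniformly at simulation time (default ``(0.05, 0.15)``).
    alpha, b, c_prime
        Structural effects: exposure->mediator, mediator->outcome, and the
        direct exposure->outcome path.
    pleio_mean, pleio_sd
        Mean and SD of per-SNP pleiotropic effects added to the outcome
        betas of the exposure instruments; ``pleio_mean != 0`` gives
        directional pleiotropy, ``pleio_mean == 0, pleio_sd > 0`` balanced.
    pleio_gamma_corr
        Correlation between the pleiotropy draws and ``gamma`` — nonzero
        values violate the InSIDE assumption.
    n_snps_med, delta
        Number and effect sizes of mediator-specific instruments (same
        conventions as ``gamma``).
    n_exp, n_med, n_out
        GWAS sample sizes of the three (non-overlapping) studies.
    overlap_corr
        Optional correlation between exposure- and outcome-GWAS sampling
        noise, modelling participant overlap; 0 for the two-sample design.
    maf_range
        Minor-allele-frequency interval; effect-allele frequency is drawn
        uniformly within it.
    frac_palindromic, frac_flipped
        Fractions of variants given A/T-or-G/C allele pairs, and of
        variants whose outcome (and mediator) allele coding is swapped.
    """

    n_snps: int = 50
    gamma: object = (0.05, 0.15)
    alpha: float = -0.2
    b: float = -0.3
    c_prime: float = 0.1
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    pleio_gamma_corr: float = 0.0
    n_snps_med: int = 50
    delta: object = (0.05, 0.15)
    n_exp: int = 50_000
    n_med: int = 50_000
    n_out: int = 50_000
    overlap_corr: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.45)
    frac_palindromic: float = 0.2
    frac_flipped: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 3:
            raise ParameterError("need at least 3 exposure instruments")
        if self.n_snps_med < 0:
            raise ParameterError("n_snps_med must be non-negative")
        for nm in ("n_exp", "n_med", "n_out"):
            if getattr(self, nm) < 100:
                raise ParameterError(f"{nm} must be at least 100")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ParameterError("maf_range must satisfy 0 < low < high <= 0.5")
        if not 0 <= self.frac_palindromic <= 1 or not 0 <= self.frac_flipped <= 1:
            raise ParameterError("fractions must lie in [0, 1]")
        if not -1 <= self.pleio_gamma_corr <= 1 or not -1 <= self.overlap_corr <= 1:
            raise ParameterError("correlations must lie in [-1, 1]")

    @property
    def total_effect(self) -> float:
        """True total exposure->outcome effect, c' + alpha*b."""
        return self.c_prime + self.alpha * self.b

    @property
    def proportion_mediated(self) -> float:
        """True mediated percentage, 100 * alpha*b / (c' + alpha*b)."""
        return 100.0 * self.alpha * self.b / self.total_effect

    def resolve_effects(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Materialise gamma and delta as arrays (drawing ranges if needed)."""

        def materialise(spec, count):
            arr = np.asarray(spec, dtype=float)
            if arr.shape == (2,) and count != 2:
                return rng.uniform(arr[0], arr[1], size=count)
            if arr.shape == (count,):
                return arr.copy()
            if arr.shape == (2,):  # count == 2 and a pair: treat as explicit effects
                return arr.copy()
            raise ParameterError(
                f"effect spec must be a (low, high) pair or an array of length {count}"
            )

        return materialise(self.gamma, self.n_snps), materialise(self.delta, self.n_snps_med)


def _variant_layout(n_total: int, truth: TriangleTruth, rng: np.random.Generator):
    """Ids, positions and allele pairs; successive SNPs on one chromosome sit
    20 Mb apart so distance-only clumping never collides."""
    ids = np.array([f"rs{i + 1:06d}" for i in range(n_total)])
    chrom = np.array([str(i % 22 + 1) for i in range(n_total)])
    pos = np.array([1_000_000 + (i // 22) * 20_000_000 for i in range(n_total)], dtype=np.int64)

    n_pal = int(round(truth.frac_palindromic * n_total))
    pal_mask = np.zeros(n_total, dtype=bool)
    pal_mask[rng.permutation(n_total)[:n_pal]] = True
    ea = np.empty(n_total, dtype="U1")
    oa = np.empty(n_total, dtype="U1")
    for i in range(n_total):
        pool = _PALINDROMIC_PAIRS if pal_mask[i] else _NONPALINDROMIC_PAIRS
        a, b_ = pool[rng.integers(len(pool))]
        ea[i], oa[i] = a, b_
    return ids, chrom, pos, ea, oa, pal_mask


def _assemble(trait_id, label, ids, chrom, pos, ea, oa, eaf, beta, se, n) -> SummaryStats:
    z = np.abs(beta / se)
    pval = np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0)
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": np.full(len(ids), n, dtype=np.int64),
        },
        columns=CANONICAL_COLUMNS,
    )
    return SummaryStats(trait_id=trait_id, table=table, trait_label=label)


def simulate_triangle(
    truth: TriangleTruth,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, TriangleTruth]:
    """Generate exposure, mediator and outcome summary statistics from
    ``truth``.  Identical seeds give bit-identical tables.

    Returns ``(exposure, mediator, outcome, truth)``.  All three tables list
    every SNP (J exposure instruments followed by K mediator instruments,
    then shuffled into the layout); instrument selection downstream is by
    p-value, exactly as with real summary files.
    """
    rng = np.random.default_rng(truth.seed)
    gamma, delta = truth.resolve_effects(rng)
    J, K = truth.n_snps, truth.n_snps_med
    n_total = J + K

    ids, chrom, pos, ea, oa, _ = _variant_layout(n_total, truth, rng)
    maf = rng.uniform(*truth.maf_range, size=n_total)

    g_full = np.concatenate([gamma, np.zeros(K)])
    d_full = np.concatenate([np.zeros(J), delta])

    # pleiotropy acts on the outcome betas of the exposure instruments
    z_pleio = rng.standard_normal(J)
    if truth.pleio_gamma_corr != 0.0:
        g_std = (gamma - gamma.mean()) / (gamma.std() if gamma.std() > 0 else 1.0)
        rho = truth.pleio_gamma_corr
        z_pleio = rho * g_std + np.sqrt(1 - rho**2) * z_pleio
    e = np.concatenate([truth.pleio_mean + truth.pleio_sd * z_pleio, np.zeros(K)])

    true_bx = g_full
    true_bm = g_full * truth.alpha + d_full
    true_by = g_full * truth.total_effect + d_full * truth.b + e

    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * truth.n_exp)
    se_m = 1.0 / np.sqrt(2 * maf * (1 - maf) * truth.n_med)
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * truth.n_out)

    zx = rng.standard_normal(n_total)
    zm = rng.standard_normal(n_total)
    zy = rng.standard_normal(n_total)
    if truth.overlap_corr != 0.0:
        zy = truth.overlap_corr * zx + np.sqrt(1 - truth.overlap_corr**2) * zy

    bx = true_bx + se_x * zx
    bm = true_bm + se_m * zm
    by = true_by + se_y * zy

    exposure = _assemble("sim_exposure", "simulated exposure", ids, chrom, pos, ea, oa, maf, bx, se_x, truth.n_exp)

    # mediator and outcome share the flip pattern: a study that coded the
    # variant the other way swaps alleles, negates beta and reports 1-eaf
    n_flip = int(round(truth.frac_flipped * n_total))
    flip = np.zeros(n_total, dtype=bool)
    flip[rng.permutation(n_total)[:n_flip]] = True

    def flipped(ea_, oa_, eaf_, beta_):
        ea2 = np.where(flip, oa_, ea_)
        oa2 = np.where(flip, ea_, oa_)
        eaf2 = np.where(flip, 1.0 - eaf_, eaf_)
        beta2 = np.where(flip, -beta_, beta_)
        return ea2, oa2, eaf2, beta2

    ea_m, oa_m, eaf_m, bm_f = flipped(ea, oa, maf, bm)
    mediator = _assemble("sim_mediator", "simulated mediator", ids, chrom, pos, ea_m, oa_m, eaf_m, bm_f, se_m, truth.n_med)
    ea_y, oa_y, eaf_y, by_f = flipped(ea, oa, maf, by)
    outcome = _assemble("sim_outcome", "simulated outcome", ids, chrom, pos, ea_y, oa_y, eaf_y, by_f, se_y, truth.n_out)

    return exposure, mediator, outcome, truth


def simulate_screen(
    truth: TriangleTruth,
    n_outcomes: int,
    effects: dict[int, float] | None = None,
    seed: int | None = None,
) -> tuple[SummaryStats, list[SummaryStats]]:
    """One exposure GWAS plus ``n_outcomes`` outcome GWAS sharing its
    instruments — the screening scenario.

    ``effects`` maps outcome index -> true causal effect of the exposure on
    that outcome; unlisted outcomes are null.  Outcome sampling noise is
    independent across outcomes.  Flips/palindromes follow ``truth``.
    """
    if n_outcomes < 1:
        raise ParameterError("need at least one outcome")
    effects = dict(effects or {})
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    gamma, _ = truth.resolve_effects(rng)
    J = truth.n_snps
    ids, chrom, pos, ea, oa, _ = _variant_layout(J, truth, rng)
    maf = rng.uniform(*truth.maf_range, size=J)
    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * truth.n_exp)
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * truth.n_out)

    bx = gamma + se_x * rng.standard_normal(J)
    exposure = _assemble("sim_exposure", "simulated exposure", ids, chrom, pos, ea, oa, maf, bx, se_x, truth.n_exp)

    outcomes = []
    for i in range(n_outcomes):
        theta = effects.get(i, 0.0)
        by = gamma * theta + se_y * rng.standard_normal(J)
        n_flip = int(round(truth.frac_flipped * J))
        flip = np.zeros(J, dtype=bool)
        flip[rng.permutation(J)[:n_flip]] = True
        ea2 = np.where(flip, oa, ea)
        oa2 = np.where(flip, ea, oa)
        eaf2 = np.where(flip, 1.0 - maf, maf)
        by2 = np.where(flip, -by, by)
        outcomes.append(
            _assemble(f"sim_outcome_{i:03d}", f"simulated outcome {i}", ids, chrom, pos, ea2, oa2, eaf2, by2, se_y, truth.n_out)
        )
    return exposure, outcomes


@dataclass
class CohortSpec:
    """Marginal specification of a simulated case/control cohort.

    ``continuous`` maps variable name to per-group ``(mean, sd)`` pairs;
    ``categorical`` maps variable name to ``{level: (p_control, p_case)}``
    with each group's probabilities summing to 1.
    """

    n_case: int
    n_control: int
    continuous: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    categorical: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ParameterError("group sizes must be at least 1")
        for var, levels in self.categorical.items():
            probs = np.array(list(levels.values()), dtype=float)
            if probs.ndim != 2 or probs.shape[1] != 2:
                raise ParameterError(f"{var}: each level needs (p_control, p_case)")
            if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-8):
                raise ParameterError(f"{var}: probabilities must sum to 1 in each group")
        for var, groups in self.continuous.items():
            for g, (mu, sd) in groups.items():
                if sd < 0:
                    raise ParameterError(f"{var}/{g}: sd must be non-negative")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a subject-level table matching ``spec``'s marginals.

    Continuous variables are Gaussian per group; categorical variables are
    drawn from the per-group level probabilities.  Column-wise sample
    means/frequencies converge to the specified values as n grows.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_control + spec.n_case
    group = np.array(["control"] * spec.n_control + ["case"] * spec.n_case)
    out = {"group": group}
    for var, groups in spec.continuous.items():
        mu_c, sd_c = groups["control"]
        mu_a, sd_a = groups["case"]
        vals = np.empty(n)
        vals[: spec.n_control] = rng.normal(mu_c, sd_c, spec.n_control)
        vals[spec.n_control :] = rng.normal(mu_a, sd_a, spec.n_case)
        out[var] = vals
    for var, levels in spec.categorical.items():
        names = list(levels.keys())
        p = np.array([levels[k] for k in names], dtype=float)  # (levels, 2)
        vals = np.empty(n, dtype=object)
        vals[: spec.n_control] = rng.choice(names, size=spec.n_control, p=p[:, 0])
        vals[spec.n_control :] = rng.choice(names, size=spec.n_case, p=p[:, 1])
        out[var] = vals
    return pd.DataFrame(out)


def biobank_cohort_spec(n_case: int = 232, n_control: int = 210_642, seed: int = 0) -> CohortSpec:
    """A :class:`CohortSpec` with marginals shaped like a large population
    biobank contrasting a small neurodevelopmental-disorder case group
    against population controls: cases eat more cheese and oily fish, less
    fiber, calcium and fruit, skew male and more deprived."""
    return CohortSpec(
        n_case=n_case,
        n_control=n_control,
        continuous={
            "age": {"control": (56.08, 7.95), "case": (55.22, 8.63)},
            "bmi": {"control": (26.96, 4.65), "case": (28.52, 5.70)},
            "fiber": {"control": (7.16, 4.86), "case": (5.87, 4.77)},
            "calcium": {"control": (427.46, 274.62), "case": (374.48, 276.56)},
            "cheese": {"control": (0.37, 0.26), "case": (0.67, 0.23)},
        },
        categorical={
            "sex": {"male": (0.4489, 0.6379), "female": (0.5511, 0.3621)},
            "oily_fish": {
                "<1/week": (0.4326, 0.4483),
                "1-2/week": (0.3869, 0.3233),
                ">=2/week": (0.1805, 0.2284),
            },
        },
        seed=seed,
    )
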