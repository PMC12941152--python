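# mrmediate

Two-sample Mendelian randomization (MR), multivariable MR and two-step
mediation analysis on GWAS summary statistics — with a synthetic
summary-statistics generator so the whole pipeline can be exercised, end
to end, against known ground truth without downloading any GWAS data.

The package is aimed at epidemiologists and biostatisticians dissecting
exposure → mediator → outcome questions from published GWAS — for
example, whether gut-microbial taxa mediate the effect of a
neuropsychiatric condition on dietary preferences. It covers:

- **I/O** — validated reading/writing of summary-statistics tables
  (variant, alleles, EAF, β, SE, p, n) with per-row rejection reports.
- **Instruments** — p-value thresholding, greedy LD clumping from a
  user-supplied r² table, F-statistic and variance-explained checks.
- **Harmonization** — allele alignment with strand-complement resolution
  and frequency-based handling of palindromic SNPs.
- **Estimators** — IVW (fixed and multiplicative-random-effects),
  MR-Egger with its pleiotropy intercept test, weighted median, simple and
  weighted mode, Wald ratio, and Cochran's Q heterogeneity.
- **MVMR & mediation** — multivariable IVW direct effects, product- and
  difference-method indirect effects with delta-method 95% CIs, the
  IVW→Egger total-effect fallback, and the proportion mediated.
- **Screening** — bidirectional MR over many candidate outcomes with
  Benjamini–Hochberg FDR and reverse-causation flagging.
- **Cohort layer** — case/control descriptive summaries, Mann–Whitney and
  chi-square tests, and 1:1 propensity-score matching.
- **Simulation** — coupled exposure/mediator/outcome summary statistics
  from a known causal triangle (γ, α, b, c′, pleiotropy, palindromes,
  allele flips), plus subject-level cohort tables from marginal specs.

## The model in brief

With instruments j = 1..J and harmonized effects (β̂_Xj, β̂_Yj, σ_Yj), the
inverse-variance weighted estimate of the causal effect of X on Y is

    β̂_IVW = Σ_j w_j (β̂_Yj/β̂_Xj) / Σ_j w_j ,   w_j = β̂²_Xj/σ²_Yj ,

MR-Egger adds a free intercept capturing directional pleiotropy, and on a
triangle X → M → Y the mediated effect is α·b with delta-method SE
√(α²σ²_b + b²σ²_α); the proportion mediated is 100·α·b/(c′ + α·b).
See `docs/methods.md` for the full account.

## Worked example

```python
from mrmediate import (TriangleTruth, simulate_triangle, select_instruments,
                       harmonize, all_methods, two_step_mediation)

truth = TriangleTruth(alpha=-0.2, b=-0.3, c_prime=0.1, seed=1)
print(truth.total_effect, truth.proportion_mediated)   # 0.16 37.5

exposure, mediator, outcome, _ = simulate_triangle(truth)
iv = select_instruments(exposure, p_threshold=1e-6)
h = harmonize(iv, outcome)
for name, res in all_methods(h, seed=1).items():
    print(f"{name:16s} beta={res.beta:+.4f} se={res.se:.4f}")

med = two_step_mediation(exposure, mediator, outcome)
print(f"total={med.total_effect:.4f} ({med.total_method}) "
      f"direct={med.direct_effect:.4f} indirect={med.indirect_effect:.4f} "
      f"mediated={med.proportion_mediated:.1f}%")
```

prints (seed 1):

```
0.16 37.5
ivw              beta=+0.1456 se=0.0127
egger            beta=+0.1500 se=0.0513
weighted_median  beta=+0.1520 se=0.0154
simple_mode      beta=+0.1355 se=0.0314
weighted_mode    beta=+0.1508 se=0.0272
total=0.1456 (ivw) direct=0.0911 indirect=0.0533 mediated=36.6%
```

All five estimators agree with the true total effect 0.16 within sampling
error; the multivariable-MR direct effect recovers c′ = 0.1 and the
product-method proportion mediated lands near the true 37.5%.

A thin CLI mirrors the library: `mrmediate simulate triangle`,
`instruments`, `harmonize`, `mr`, `mediate`, `screen`, `cohort` — run
`mrmediate --help`.

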