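# qtpower

Statistical power, sample-size, and detectable-effect calculations for
genome-wide association studies (GWAS) of **quantitative traits**, where the
effect size is given as **heritability** rather than group means and
variances.

## Who this is for

Study designers planning a cohort GWAS with a quantitative phenotype (e.g.
HIV set-point viral load, lipid levels, height) usually know the fraction of
phenotypic variance a variant might explain — its heritability H — but not
the per-genotype means and error variance that classical power formulas
demand for the noncentrality parameter

    λ = Σᵢ rᵢ τᵢ² / σ².

`qtpower` removes that obstacle for the one-degree-of-freedom genetic models
(dominant, recessive, additive) that dominate GWAS practice.

## The statistic

For unrelated subjects, H equals the coefficient of determination R² of the
one-df genetic model.  On the relative scale where the total sum of squares
is 1, the ANOVA decomposition gives SSM = H, SSE = 1 − H,
MSE = (1 − H)/(N − 2), hence

    F = H (N − 2) / (1 − H),

a function of H and the sample size N alone.  Since X ~ t(d) implies
X² ~ F(1, d) (centrally and noncentrally), power is the two-sided
noncentral-t tail

    P = Pr(|T| > t(N − 2, α/2)),    T ~ t(N − 2; δ),  δ = √(H(N−2)/(1−H)),

with Bonferroni per-test α = (family-wise α)/M for M SNPs.  Covariates
(c of them, explaining a fraction C of variance) change the error df to
N − 2 − c and the denominator to 1 − H − C; linkage disequilibrium r²
between marker and causal variant replaces N by the effective sample size
r²N, so detecting through a marker needs 1/r² times the subjects.

Two numerical methods are available: `method="exact"` (the exact
noncentral-t distribution, the default) and `method="normal"` (the
asymptotic approximation P = Φ(δ − z_{α/2}) + Φ(−δ − z_{α/2}), which
reproduces the original Windows GUI calculator's published numbers to three
decimals — see `docs/methods.md`).

A Monte-Carlo oracle (`simulate_genotypes`, `simulate_phenotype`,
`association_test`, `empirical_power`) draws Hardy–Weinberg genotypes and
Gaussian phenotypes at an exactly controlled noncentrality and verifies the
analytic engine empirically.

## Worked example

The two-stage HIV set-point viral load study: stage 1 genotyped 486
subjects, stage 2 extended the cohort to 2554.  The significance threshold
implied by the study's published power table is first recovered by
calibration, then reused:

```python
from qtpower import DesignSpec, calibrate_per_test_alpha, power, \
    solve_detectable_heritability

# per-test alpha making the (H=7%, N=486) design attain power 0.792
alpha = calibrate_per_test_alpha(0.07, 486, 0.792, method="normal")
print(f"{alpha:.4g}")                       # 1.767e-07  (~283k SNPs at 0.05)

spec = DesignSpec(heritability=0.01, n_subjects=2554, per_test_alpha=alpha)
print(f"{power(spec, method='normal').power:.3f}")   # 0.442

h = solve_detectable_heritability(2554, 0.78, method="normal",
                                  per_test_alpha=alpha)
print(f"{h:.4f}")                           # 0.0139
```

So at stage 1, a variant explaining 7% of the variance is detected with
power 0.79; after stage 2 the smallest heritability detectable with ~80%
power is about 1.4%.

The same numbers from the shell, plus a curve table and plot:

```sh
qtpower --h2 7% --n 486 --alpha 1.7666e-7 --per-test --method normal
qtpower --h2 0.05 --n 1000 --n-snps 500000 --curves curves.tsv --plot curves.svg
```

The report prints the power together with every intermediate (per-test
alpha, error df, noncentrality δ, critical value, √MSE and the smallest
significant relative mean difference Δm).  `--solve n --target-power 0.8`
inverts for sample size, `--solve h2` for detectable heritability,
`--simulate 5000` appends a Monte-Carlo check.

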