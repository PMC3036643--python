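# Methods

## Model

A quantitative trait y is tested against a single biallelic variant under a
one-degree-of-freedom genetic coding x: dominant (carrier indicator,
aa vs Aa∪AA), recessive (minor-homozygote indicator), or additive (0/1/2
dosage).  The analysis model is the one-way ANOVA (two-group codings) or
simple linear regression (dosage); both produce an F(1, N−2) statistic, and
X ~ t(d) ⟺ X² ~ F(1, d) holds centrally and noncentrally, so everything
reduces to a two-sided t test.

The effect size is heritability H = V(g)/V(t), which for unrelated subjects
is the model R².  Sums of squares are only needed *relative* to the total:
with SST ≡ 1, SSM = H, SSE = 1 − H, MSE = (1−H)/(N−2), giving

    F = H (N − 2) / (1 − H)          (independent of the absolute scale)
    δ = √F                            (noncentrality of the t statistic)
    power = Pr(|T| > t(N−2, α/2)),    T ~ noncentral t(N − 2, δ).

Assumptions: Gaussian residuals, unrelated subjects, a single tested
variant per test (Bonferroni across M SNPs), no population stratification,
and no gene–gene or gene–environment interaction.  Binary traits and
variance-component designs are out of scope.

## Adjustments

* **Multiple testing** — per-test two-sided α = family-wise α / M
  (Bonferroni only; it is conservative, but no alternative is offered).
* **Covariates** — c covariates explaining a fraction C of variance reduce
  the error df to N − 2 − c and the residual variance to 1 − H − C, so
  δ² = H(N−2−c)/(1−H−C).  With the default C = 0 this is exactly a df-only
  adjustment; the C term follows from the ANOVA decomposition when the
  covariates absorb C·SST.
* **Linkage disequilibrium** — a marker at squared correlation r² from the
  causal variant is handled by the effective sample size N_eff = r²N in
  both δ² and the df.  Consequently the required sample size through the
  marker is ⌈1/r²⌉ times the causal-variant requirement (up to integer
  rounding), which is the classical LD sample-size inflation rule; the
  solver test asserts exactly this identity.  Whether the original
  calculator also discounted the df is unknowable from its description;
  discounting it is the conservative reading and changes power only at
  O(1/N).

## Numerical methods

Two evaluation methods are exposed, and the difference between them turned
out to be scientifically meaningful:

* `method="exact"` — the exact noncentral-t two-sided tail, evaluated as
  `nct.sf(t_crit, df, δ) + nct.sf(t_crit, df, −δ)`.  (The symmetric form is
  used because the direct lower-tail evaluation `nct.cdf(−t_crit, df, δ)`
  is numerically unstable in scipy for large δ.)  This is the defensible
  default and the quantity the Monte-Carlo oracle estimates.
* `method="normal"` — the asymptotic approximation
  P = Φ(δ − z_{α/2}) + Φ(−δ − z_{α/2}).

The original GUI calculator for this model never documented its numerical
method.  Calibrating the per-test alpha on its published (H=7%, N=486) =
0.792 cell and predicting the other 21 published cells discriminates
sharply between the two: the normal approximation matches every cell to
≤ 0.0005, while the exact noncentral t deviates by up to 0.028 (at H = 1%,
N = 2554).  The published table was therefore produced with the normal
approximation, and the table-reproduction tests and the acceptance script
use `method="normal"`; the calibrated per-test alpha is 1.767 × 10⁻⁷
(≈ 283k SNPs under a family-wise alpha of 0.05).  For study design the two
methods differ by at most a few percent in power at genome-wide alphas; the
exact method is never anti-conservative relative to the approximation in
the regimes tested.

Other numerical choices:

* Critical values and tail probabilities come from scipy.stats (`t`, `nct`,
  `norm`, `f`, `ncf`).  The t² ↔ F(1, d) identity is asserted at the
  power level to 1e−10; at the quantile level only to 1e−9, the root
  tolerance of scipy's iterative inverse CDFs.
* `solve_sample_size`: bracket doubling from the smallest feasible N
  followed by integer bisection (power is strictly increasing in N).
* `solve_detectable_heritability`: Brent root-finding in H on
  (10⁻¹⁰, 1 − C − 10⁻¹⁰) to an absolute tolerance below 10⁻⁶ (power is
  continuous and strictly increasing in H).
* `calibrate_per_test_alpha`: Brent root-finding in log₁₀ α — the inverse
  problem of recovering a significance threshold from a published power.
* Degenerate inputs are rejected with named invariants: H = 0 or 1,
  non-integer N, effective df ≤ 0 ("sample size too small for requested
  adjustments"), α outside (0,1), r² outside (0,1].
* Table output caps powers ≥ 0.9995 at the printed value "0.999" (the
  convention of the published table); the unrounded value is always
  available in `PowerResult.power`.
* `PowerResult.relative_delta_m` reports √MSE × t_crit, i.e. the smallest
  relative group-mean difference that reaches significance — the "Δm =
  std·t" quantity read at the critical point, which is the useful design
  reading of an otherwise ambiguous definition.

## The simulation oracle

`simulate_genotypes` draws genotype codes from Hardy–Weinberg proportions
((1−p)², 2p(1−p), p²) at minor-allele frequency p; `simulate_phenotype`
builds y = βx + ε with iid standard-normal ε.

Two generation modes:

* **exact mode** (default for validation): β is chosen from the *realized*
  genotype sum of squares S_xx so that the conditional noncentrality
  β√S_xx equals the target δ = √(H(N−2)/(1−H)) exactly.  Conditional on
  the genotype draw, the test statistic is then exactly noncentral
  t(N−2, δ) — the very quantity the analytic engine integrates — so the
  Monte-Carlo estimate must agree with the analytic power up to binomial
  noise, and a 3-standard-error acceptance band is fair at 5000
  replicates.  (Forcing the *fitted* in-sample R² to equal H instead would
  make F deterministic and the power estimate a 0/1 indicator, which is
  why that seemingly natural construction is not used.)  Equivalently, the
  noncentrality-scale heritability β²S_xx/(β²S_xx + (N−2)) equals H to
  machine precision.
* **population mode**: β = √(H/((1−H)·Var_HWE(x))) on unit error variance,
  so heritability holds in expectation over genotype draws; used for the
  null-calibration tests and realism studies.

The minor-allele frequency does not appear in the power formula; the
empirical-power grid confirms the MAF-invariance of power at fixed
noncentrality across MAF 0.3 and 0.5 and all three codings.  Replicates
whose coding collapses to one group (small N, rare allele under the
recessive coding) are redrawn from fresh seed substreams, counted, and
reported; each replicate consumes an independent child of the master
`SeedSequence`, so runs are reproducible.

What the simulations do **not** emulate: real LD structure (the LD
adjustment is validated analytically through the N_eff identity),
genotyping error, non-Gaussian traits, relatedness, stratification, or
multi-SNP genomes.  Passing the oracle shows the analytic tail integration
and the test statistic's distribution agree under the stated model — not
that the model describes any particular cohort.

## Problem sizes

The validation grid uses the two study-stage scales directly (N = 486) and
the second stage scaled to one fifth (N = 2554/5 = 511) with the per-test
alpha relaxed to 10⁻³, at 5000 replicates per combination: genome-wide
alphas of order 10⁻⁷ are not resolvable by desk-scale simulation, and the
distributional claim being validated is alpha-uniform.  24 combinations
(2 H × 2 N × 3 models × 2 MAFs) run in a few minutes.

## Known limitations

* Bonferroni only; no FDR or permutation thresholds.
* Quantitative traits only; no case-control power.
* The covariate option's variance term C is a modeling decision (the
  original tool documented only the df change; with C = 0 both coincide).
* Power at H values within ~10⁻¹² of 0 is reported as the per-test alpha
  by construction of the limit, but H = 0 itself is rejected as input.
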