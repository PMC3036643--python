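"""Statistical power for GWAS of quantitative traits, parameterized by heritability.

Classical power calculations for a quantitative outcome need the group means
and the error variance to form the noncentrality parameter of the F test,

    lambda = sum_i r_i * tau_i**2 / sigma**2,

quantities a study designer rarely has.  In genetics the effect size of a
variant is instead quoted as *heritability* H = V(g)/V(t), the fraction of
phenotypic variance attributable to the variant, which for unrelated subjects
is the coefficient of determination R^2 of the one-degree-of-freedom genetic
model (dominant, recessive, or additive coding).  On the relative scale where
the total sum of squares is 1, the ANOVA decomposition gives SSM = H,
SSE = 1 - H, MSE = (1-H)/(N-2), and therefore

    F = H (N - 2) / (1 - H),

a function of H and the sample size N alone.  Because every one-df model
yields an F(1, d) statistic, and X ~ t(d) implies X^2 ~ F(1, d) (centrally and
noncentrally), power reduces to a two-sided noncentral-t tail probability with
noncentrality delta = sqrt(H (N-2) / (1-H)) — no means or variances required.

The module provides the analytic engine (with Bonferroni, covariate, and
linkage-disequilibrium adjustments and inverse solvers for sample size and
detectable heritability), a Monte-Carlo simulation oracle that generates
Hardy-Weinberg genotypes and Gaussian phenotypes at an exactly specified
noncentrality to validate the analytic numbers, and a command-line front end
that prints reports, power-curve tables, and curve-family plots.

Two numerical methods are exposed.  ``method="exact"`` evaluates the exact
noncentral-t distribution.  ``method="normal"`` applies the asymptotic normal
approximation P = Phi(delta - z_{a/2}) + Phi(-delta - z_{a/2}); this is the
computation the original Windows power calculator for this model evidently
used — it reproduces that program's published power table to three decimals,
while the exact noncentral t differs by up to ~0.03 at small H and large N.
"""

from __future__ import annotations

import argparse
import dataclasses
import logging
import math
import sys
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DesignSpec",
    "PowerResult",
    "PowerCurveTable",
    "GenotypeSample",
    "PhenotypeSample",
    "AssociationTest",
    "EmpiricalPower",
    "per_test_alpha",
    "noncentrality",
    "power",
    "calibrate_per_test_alpha",
    "solve_sample_size",
    "solve_detectable_heritability",
    "power_curve_table",
    "simulate_genotypes",
    "simulate_phenotype",
    "association_test",
    "empirical_power",
    "write_curve_table",
    "plot_curve_family",
    "format_report",
    "main",
]

# --------------------------------------------------------------------------
# Configuration / constants
# --------------------------------------------------------------------------

logger = logging.getLogger("qtpower")

GeneticModel = Literal["dominant", "recessive", "additive"]
PowerMethod = Literal["exact", "normal"]

GENETIC_MODELS = ("dominant", "recessive", "additive")

#: family-wise type-1 error rate used when none is given
DEFAULT_FAMILY_ALPHA = 0.05
#: default heritability grid for curve families: 1% .. 10% in 1% steps
DEFAULT_H_GRID = tuple(h / 100.0 for h in range(1, 11))
#: powers at or above this are printed as "0.999" in table output
POWER_PRINT_CAP = 0.9995
#: absolute tolerance of the detectable-heritability bisection
H_SOLVER_TOL = 1e-6


# --------------------------------------------------------------------------
# Design and result types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Complete description of a single-SNP quantitative-trait study design.

    Parameters
    ----------
    heritability:
        Fraction of phenotypic variance explained by the tested variant,
        H in (0, 1).  Equals the model R^2 for unrelated subjects.
    n_subjects:
        Total sample size N (integer, > 2 + n_covariates).
    n_snps:
        Number of SNPs tested genome-wide; drives the default Bonferroni
        per-test alpha.
    family_alpha:
        Family-wise type-1 error rate, in (0, 1).
    per_test_alpha:
        Optional override of the two-sided per-test alpha.  When ``None``
        the Bonferroni value ``family_alpha / n_snps`` is used.
    n_covariates:
        Number of non-genetic covariates c; each costs one error df.
    covariate_variance:
        Fraction C of phenotypic variance the covariates explain, removed
        from the error term (the default C = 0 leaves only the df cost).
    ld_r2:
        Squared LD correlation r^2 between genotyped marker and causal
        variant.  Power is computed at the effective sample size r^2 * N,
        so the sample size needed through a marker is 1/r^2 times larger.
    genetic_model:
        "dominant", "recessive", or "additive".  All three share the same
        one-df power formula; the label selects the simulation coding.
    """

    heritability: float
    n_subjects: int
    n_snps: int = 1
    family_alpha: float = DEFAULT_FAMILY_ALPHA
    per_test_alpha: Optional[float] = None
    n_covariates: int = 0
    covariate_variance: float = 0.0
    ld_r2: float = 1.0
    genetic_model: GeneticModel = "additive"

    def __post_init__(self) -> None:
        H, C = self.heritability, self.covariate_variance
        if not 0.0 < H < 1.0:
            raise ValueError(f"heritability must lie in (0, 1), got {H}")
        if not 0.0 <= C < 1.0:
            raise ValueError(f"covariate_variance must lie in [0, 1), got {C}")
        if H + C >= 1.0:
            raise ValueError(
                f"heritability + covariate_variance must be < 1, got {H + C}")
        n = self.n_subjects
        if isinstance(n, bool) or not (
                isinstance(n, (int, np.integer))
                or (isinstance(n, float) and n.is_integer())):
            raise ValueError(f"n_subjects must be an integer, got {n!r}")
        object.__setattr__(self, "n_subjects", int(n))
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")
        if not 0.0 < self.family_alpha < 1.0:
            raise ValueError(
                f"family_alpha must lie in (0, 1), got {self.family_alpha}")
        if self.per_test_alpha is not None and not 0.0 < self.per_test_alpha < 1.0:
            raise ValueError(
                f"per_test_alpha must lie in (0, 1), got {self.per_test_alpha}")
        if self.n_covariates < 0:
            raise ValueError(
                f"n_covariates must be >= 0, got {self.n_covariates}")
        if not 0.0 < self.ld_r2 <= 1.0:
            raise ValueError(f"ld_r2 must lie in (0, 1], got {self.ld_r2}")
        if self.genetic_model not in GENETIC_MODELS:
            raise ValueError(
                f"genetic_model must be one of {GENETIC_MODELS}, "
                f"got {self.genetic_model!r}")
        if self.df_error <= 0:
            raise ValueError(
                "sample size too small for requested adjustments: effective "
                f"sample size {self.ld_r2 * self.n_subjects:g} must exceed "
                f"2 + {self.n_covariates} covariates")

    @property
    def resolved_alpha(self) -> float:
        """The two-sided per-test alpha actually in force."""
        if self.per_test_alpha is not None:
            return self.per_test_alpha
        return per_test_alpha(self.family_alpha, self.n_snps)

    @property
    def df_error(self) -> float:
        """Error degrees of freedom r^2 * N - 2 - c of the t test."""
        return self.ld_r2 * self.n_subjects - 2.0 - self.n_covariates

    def replace(self, **changes) -> "DesignSpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PowerResult:
    """Power together with every intermediate of the calculation."""

    power: float
    per_test_alpha: float
    df_error: float
    noncentrality: float
    critical_t: float
    relative_sd: float       # sqrt(MSE) on the SST = 1 scale
    relative_delta_m: float  # smallest significant relative mean difference
    method: str = "exact"


@dataclass
class PowerCurveTable:
    """Grid of power over (heritability, sample size), as in a curve family.

    ``power_matrix[i, j]`` is the power at ``h_values[i]``, ``n_values[j]``;
    infeasible grid points are NaN.  ``annotation`` optionally carries the
    user's own design point ``(n_subjects, power)`` for highlighting.
    """

    h_values: np.ndarray
    n_values: np.ndarray
    power_matrix: np.ndarray
    annotation: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.h_values = np.asarray(self.h_values, dtype=float)
        self.n_values = np.asarray(self.n_values, dtype=int)
        self.power_matrix = np.asarray(self.power_matrix, dtype=float)
        if self.power_matrix.shape != (len(self.h_values), len(self.n_values)):
            raise ValueError("power_matrix shape must be (len(h), len(n))")
        ok = np.isnan(self.power_matrix) | (
            (self.power_matrix >= 0.0) & (self.power_matrix <= 1.0))
        if not ok.all():
            raise ValueError("power values must lie in [0, 1] or be NaN")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.power_matrix,
            index=pd.Index(self.h_values, name="heritability"),
            columns=pd.Index(self.n_values, name="n_subjects"),
        )


# --------------------------------------------------------------------------
# Analytic power engine
# --------------------------------------------------------------------------

def per_test_alpha(family_alpha: float, n_snps: int) -> float:
    """Bonferroni per-test two-sided alpha: ``family_alpha / n_snps``."""
    if not 0.0 < family_alpha < 1.0:
        raise ValueError(f"family_alpha must lie in (0, 1), got {family_alpha}")
    if n_snps < 1:
        raise ValueError(f"n_snps must be >= 1, got {n_snps}")
    return family_alpha / n_snps


def noncentrality(
    heritability: float,
    n_subjects: int,
    n_covariates: int = 0,
    covariate_variance: float = 0.0,
    ld_r2: float = 1.0,
) -> float:
    """Noncentrality delta of the one-df t statistic.

    delta = sqrt( H * (r^2 N - 2 - c) / (1 - H - C) ); with no covariates and
    full LD this is sqrt(H (N-2) / (1-H)), i.e. delta^2 equals the expected F
    statistic H (N-2)/(1-H) of the relative-scale ANOVA decomposition.
    """
    spec = DesignSpec(
        heritability=heritability,
        n_subjects=n_subjects,
        n_covariates=n_covariates,
        covariate_variance=covariate_variance,
        ld_r2=ld_r2,
    )
    df = spec.df_error
    return math.sqrt(
        heritability * df / (1.0 - heritability - covariate_variance))


def _two_sided_power(delta: float, alpha: float, df: float,
                     method: str) -> tuple[float, float]:
    """Return (power, critical value) of the two-sided one-df test."""
    if method == "exact":
        crit = stats.t.isf(alpha / 2.0, df)
        # lower tail via symmetry nct.cdf(-t|delta) = nct.sf(t|-delta);
        # the direct lower-tail evaluation is numerically unstable here
        p = stats.nct.sf(crit, df, delta) + stats.nct.sf(crit, df, -delta)
    elif method == "normal":
        crit = stats.norm.isf(alpha / 2.0)
        p = stats.norm.sf(crit - delta) + stats.norm.cdf(-crit - delta)
    else:
        raise ValueError(f"method must be 'exact' or 'normal', got {method!r}")
    return float(min(1.0, max(0.0, p))), float(crit)


def power(spec: DesignSpec, method: PowerMethod = "exact") -> PowerResult:
    """Two-sided power of the one-df genetic association test.

    Computes P(|T| > t_crit) where T is noncentral-t with
    df = r^2 N - 2 - c and noncentrality delta = sqrt(H df / (1 - H - C)),
    and t_crit is the central two-sided critical value at the per-test alpha.

    ``method="exact"`` uses the noncentral-t distribution itself;
    ``method="normal"`` uses the asymptotic normal approximation that
    reproduces the original GUI calculator's output (see module docstring).
    """
    alpha = spec.resolved_alpha
    df = spec.df_error
    delta = noncentrality(
        spec.heritability, spec.n_subjects, spec.n_covariates,
        spec.covariate_variance, spec.ld_r2)
    p, crit = _two_sided_power(delta, alpha, df, method)
    rel_sd = math.sqrt(
        (1.0 - spec.heritability - spec.covariate_variance) / df)
    return PowerResult(
        power=p,
        per_test_alpha=alpha,
        df_error=df,
        noncentrality=delta,
        critical_t=crit,
        relative_sd=rel_sd,
        relative_delta_m=rel_sd * crit,
        method=method,
    )


def calibrate_per_test_alpha(
    heritability: float,
    n_subjects: int,
    target_power: float,
    method: PowerMethod = "exact",
    **spec_kwargs,
) -> float:
    """Per-test alpha at which the design attains ``target_power``.

    Power is strictly increasing in alpha, so the root is unique; it is
    found by Brent's method on log10(alpha).  Useful for recovering the
    significance threshold implied by a published power figure.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target_power must lie in (0, 1), got {target_power}")

    def gap(log_alpha: float) -> float:
        spec = DesignSpec(heritability=heritability, n_subjects=n_subjects,
                          per_test_alpha=10.0 ** log_alpha, **spec_kwargs)
        return power(spec, method=method).power - target_power

    lo, hi = -300.0, math.log10(1.0 - 1e-12)
    if gap(hi) < 0.0:
        raise ValueError("target power unreachable at any alpha < 1")
    if gap(lo) > 0.0:
        raise ValueError("target power below the attainable floor")
    root = optimize.brentq(gap, lo, hi, xtol=1e-13)
    return 10.0 ** root


# --------------------------------------------------------------------------
# Inverse solvers
# --------------------------------------------------------------------------

def _min_feasible_n(n_covariates: int, ld_r2: float) -> int:
    """Smallest integer N with positive error df after adjustments."""
    n = math.floor((2 + n_covariates) / ld_r2) + 1
    while ld_r2 * n - 2 - n_covariates <= 0:
        n += 1
    return max(n, 4)


def solve_sample_size(
    heritability: float,
    target_power: float,
    method: PowerMethod = "exact",
    **spec_kwargs,
) -> int:
    """Smallest integer sample size N reaching ``target_power``.

    Power is strictly increasing in N, so the answer is unique; it is found
    by doubling the bracket from the smallest feasible N and integer
    bisection inside it.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target_power must lie in (0, 1), got {target_power}")

    def p_at(n: int) -> float:
        spec = DesignSpec(heritability=heritability, n_subjects=n,
                          **spec_kwargs)
        return power(spec, method=method).power

    probe = DesignSpec(heritability=heritability, n_subjects=10 ** 9,
                       **spec_kwargs)
    if target_power <= probe.resolved_alpha:
        raise ValueError(
            "target_power must exceed the per-test alpha "
            f"({probe.resolved_alpha:g})")

    lo = _min_feasible_n(probe.n_covariates, probe.ld_r2)
    if p_at(lo) >= target_power:
        return lo
    hi = lo
    while p_at(hi) < target_power:
        hi *= 2
        if hi > 10 ** 9:
            raise ValueError("required sample size exceeds 1e9; "
                             "target power effectively unreachable")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if p_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def solve_detectable_heritability(
    n_subjects: int,
    target_power: float,
    method: PowerMethod = "exact",
    **spec_kwargs,
) -> float:
    """Smallest heritability detectable with ``target_power`` at fixed N.

    Power is continuous and strictly increasing in H, so bisection (Brent)
    between H -> 0 and H -> 1 - C finds the unique boundary heritability.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target_power must lie in (0, 1), got {target_power}")

    def p_at(h: float) -> float:
        spec = DesignSpec(heritability=h, n_subjects=n_subjects, **spec_kwargs)
        return power(spec, method=method).power

    C = spec_kwargs.get("covariate_variance", 0.0)
    lo, hi = 1e-10, 1.0 - C - 1e-10
    if p_at(hi) < target_power:
        raise ValueError(
            f"target power {target_power} unreachable at any heritability "
            f"with N={n_subjects}")
    if p_at(lo) >= target_power:
        return lo
    root = optimize.brentq(lambda h: p_at(h) - target_power, lo, hi,
                           xtol=H_SOLVER_TOL / 10.0)
    return float(root)


def power_curve_table(
    n_grid: Sequence[int],
    h_grid: Optional[Sequence[float]] = None,
    method: PowerMethod = "exact",
    annotate: Optional[DesignSpec] = None,
    **spec_kwargs,
) -> PowerCurveTable:
    """Power at every (heritability, sample size) grid point.

    The default heritability grid is 1% .. 10% in 1% steps.  Grid points
    that violate the design invariants (e.g. N too small for the requested
    covariates) are recorded as NaN with a warning rather than raising.
    """
    if h_grid is None:
        h_grid = DEFAULT_H_GRID
    h_values = np.asarray(list(h_grid), dtype=float)
    n_values = np.asarray(list(n_grid), dtype=int)
    if h_values.size == 0 or n_values.size == 0:
        raise ValueError("h_grid and n_grid must be non-empty")
    matrix = np.full((h_values.size, n_values.size), np.nan)
    for i, h in enumerate(h_values):
        for j, n in enumerate(n_values):
            try:
                spec = DesignSpec(heritability=float(h), n_subjects=int(n),
                                  **spec_kwargs)
                matrix[i, j] = power(spec, method=method).power
            except ValueError as exc:
                warnings.warn(
                    f"grid point (H={h:g}, N={n}) infeasible: {exc}",
                    stacklevel=2)
    annotation = None
    if annotate is not None:
        annotation = (annotate.n_subjects, power(annotate, method=method).power)
    return PowerCurveTable(h_values, n_values, matrix, annotation)


# --------------------------------------------------------------------------
# Monte-Carlo simulation oracle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSample:
    """Simulated genotypes for N subjects at one biallelic SNP.

    ``codes`` counts copies of the minor allele (0/1/2) drawn from
    Hardy-Weinberg proportions ((1-p)^2, 2p(1-p), p^2) at minor-allele
    frequency ``maf``; ``model_coding`` is the one-df collapse —
    dominant: carrier indicator (>= 1 copy), recessive: homozygote
    indicator (2 copies), additive: the dosage itself.
    """

    codes: np.ndarray
    maf: float
    model: GeneticModel

    @property
    def model_coding(self) -> np.ndarray:
        if self.model == "dominant":
            return (self.codes >= 1).astype(float)
        if self.model == "recessive":
            return (self.codes == 2).astype(float)
        return self.codes.astype(float)

    @property
    def degenerate(self) -> bool:
        """True when the coding has no variation (test undefined)."""
        coding = self.model_coding
        return bool(np.all(coding == coding[0]))


@dataclass(frozen=True)
class PhenotypeSample:
    """Simulated quantitative trait paired with a genotype draw.

    ``realized_h2`` is the fitted in-sample R^2 of the trait on the model
    coding; ``target_noncentrality`` is the delta the generator aimed for
    (exact mode attains it to machine precision given the genotype draw).
    """

    values: np.ndarray
    realized_h2: float
    group_means: dict
    error_variance: float
    target_noncentrality: float
    effect_size: float


def _hwe_probs(maf: float) -> np.ndarray:
    q = 1.0 - maf
    return np.array([q * q, 2.0 * maf * q, maf * maf])


def simulate_genotypes(
    n_subjects: int,
    maf: float,
    model: GeneticModel = "additive",
    seed=None,
) -> GenotypeSample:
    """Draw genotype codes from Hardy-Weinberg proportions.

    ``seed`` may be an int, SeedSequence, or Generator; the draw is
    reproducible given the same seed.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    if n_subjects < 4:
        raise ValueError(f"n_subjects must be >= 4, got {n_subjects}")
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    rng = np.random.default_rng(seed)
    codes = rng.choice(3, size=n_subjects, p=_hwe_probs(maf))
    return GenotypeSample(codes=codes, maf=maf, model=model)


def simulate_phenotype(
    genotypes: GenotypeSample,
    heritability: float,
    exact: bool = True,
    seed=None,
) -> PhenotypeSample:
    """Simulate a quantitative trait with the requested heritability.

    The trait is ``beta * coding + eps`` with iid standard-normal noise.

    exact mode (default)
        ``beta`` is set from the realized genotype sum of squares so that
        the conditional noncentrality of the t statistic equals
        sqrt(H (N-2) / (1-H)) *exactly* for this genotype draw.  The test
        statistic is then exactly noncentral-t(N-2, delta), the same
        quantity the analytic engine evaluates, which makes Monte-Carlo
        comparisons against it sharp.  Equivalently, the noncentrality-scale
        heritability beta^2 Sxx / (beta^2 Sxx + (N-2)) equals H exactly.

    population mode
        ``beta = sqrt(H / ((1-H) var_HWE(coding)))`` on unit error variance,
        so heritability holds in expectation over genotype draws.
    """
    if not 0.0 < heritability < 1.0:
        raise ValueError(f"heritability must lie in (0, 1), got {heritability}")
    coding = genotypes.model_coding
    n = coding.size
    sxx = float(np.sum((coding - coding.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("degenerate genotype draw: model coding has no "
                         "variation")
    rng = np.random.default_rng(seed)
    delta = math.sqrt(heritability * (n - 2) / (1.0 - heritability))
    if exact:
        beta = delta / math.sqrt(sxx)
    else:
        p = genotypes.maf
        probs = _hwe_probs(p)
        support = {"dominant": np.array([0.0, 1.0, 1.0]),
                   "recessive": np.array([0.0, 0.0, 1.0]),
                   "additive": np.array([0.0, 1.0, 2.0])}[genotypes.model]
        mean = float(probs @ support)
        var = float(probs @ (support - mean) ** 2)
        beta = math.sqrt(heritability / ((1.0 - heritability) * var))
    eps = rng.standard_normal(n)
    values = beta * coding + eps
    r = float(np.corrcoef(coding, values)[0, 1])
    groups = {int(g): float(values[genotypes.codes == g].mean())
              for g in np.unique(genotypes.codes)}
    return PhenotypeSample(
        values=values,
        realized_h2=r * r,
        group_means=groups,
        error_variance=1.0,
        target_noncentrality=delta,
        effect_size=beta,
    )


@dataclass(frozen=True)
class AssociationTest:
    """One-df association test result: F statistic, p-value, fitted R^2."""

    statistic: float
    p_value: float
    r_squared: float


def association_test(
    phenotype: PhenotypeSample,
    genotypes: GenotypeSample,
) -> AssociationTest:
    """Two-sided one-df test of the model-coded genotype predictor.

    Dominant and recessive codings are tested by one-way ANOVA of the two
    genotype groups; the additive coding by simple linear regression.  Both
    yield the identical F(1, N-2) statistic F = R^2 (N-2) / (1 - R^2).
    """
    coding = genotypes.model_coding
    y = phenotype.values
    if np.all(coding == coding[0]):
        raise ValueError("degenerate coding: association test undefined")
    if genotypes.model in ("dominant", "recessive"):
        f_stat, p = stats.f_oneway(y[coding == 0.0], y[coding == 1.0])
    else:
        fit = stats.linregress(coding, y)
        f_stat, p = fit.slope ** 2 / fit.stderr ** 2, fit.pvalue
    r = float(np.corrcoef(coding, y)[0, 1])
    return AssociationTest(statistic=float(f_stat), p_value=float(p),
                           r_squared=r * r)


@dataclass(frozen=True)
class EmpiricalPower:
    """Monte-Carlo power estimate with its binomial standard error."""

    estimate: float
    std_error: float
    n_reject: int
    n_replicates: int
    n_redraws: int


def empirical_power(
    spec: DesignSpec,
    maf: float,
    n_replicates: int,
    seed: int,
    exact: bool = True,
    audit_path=None,
) -> EmpiricalPower:
    """Estimate power by simulation: fraction of replicates with p < alpha.

    Each replicate draws genotypes and a phenotype from an independent
    substream spawned off the master seed, runs the one-df association
    test, and compares the p-value with the per-test alpha of ``spec``.
    Replicates whose coding collapses to a single group (possible at small
    N or extreme MAF under the recessive coding) are redrawn from fresh
    substreams; the redraw count is reported and a warning is emitted if it
    exceeds 1% of the replicates.  ``audit_path`` optionally writes a
    replicate-level TSV (replicate, realized_h2, F, p, reject).
    """
    if n_replicates < 100:
        raise ValueError(f"n_replicates must be >= 100, got {n_replicates}")
    if spec.ld_r2 != 1.0:
        raise ValueError("the simulation oracle models full LD only; "
                         "validate the LD adjustment analytically")
    alpha = spec.resolved_alpha
    root = np.random.SeedSequence(seed)  # spawn() is stateful: lazy substreams
    rows = []
    n_reject = 0
    n_redraws = 0
    for rep in range(n_replicates):
        while True:
            child_g, child_p = root.spawn(1)[0].spawn(2)
            geno = simulate_genotypes(spec.n_subjects, maf,
                                      spec.genetic_model, seed=child_g)
            if not geno.degenerate:
                break
            n_redraws += 1
            if n_redraws > 50 * n_replicates:
                raise ValueError(
                    "nearly all genotype draws are degenerate under this "
                    "design; increase n_subjects or the MAF")
        pheno = simulate_phenotype(geno, spec.heritability, exact=exact,
                                   seed=child_p)
        test = association_test(pheno, geno)
        reject = test.p_value < alpha
        n_reject += reject
        if audit_path is not None:
            rows.append((rep, pheno.realized_h2, test.statistic,
                         test.p_value, int(reject)))
    if n_redraws > 0.01 * n_replicates:
        warnings.warn(
            f"{n_redraws} degenerate genotype draws redrawn "
            f"(> 1% of {n_replicates} replicates)", stacklevel=2)
    if audit_path is not None:
        import pandas as pd

        pd.DataFrame(
            rows, columns=["replicate", "realized_h2", "F", "p", "reject"],
        ).to_csv(audit_path, sep="\t", index=False)
    est = n_reject / n_replicates
    se = math.sqrt(est * (1.0 - est) / n_replicates)
    return EmpiricalPower(estimate=est, std_error=se, n_reject=n_reject,
                          n_replicates=n_replicates, n_redraws=n_redraws)


# --------------------------------------------------------------------------
# Tabular and graphical output
# --------------------------------------------------------------------------

def _format_power_cell(p: float) -> str:
    if np.isnan(p):
        return "NA"
    if p >= POWER_PRINT_CAP:
        return "0.999"
    return f"{p:.3f}"


def _format_percent(h: float) -> str:
    pct = h * 100.0
    return f"{pct:.1f}%" if abs(pct - round(pct)) > 1e-9 else f"{pct:.0f}%"


def write_curve_table(table: PowerCurveTable, destination) -> None:
    """Write the power grid as TSV: heritability rows, one column per N.

    Heritabilities are printed as percentages with at most one decimal,
    powers to three decimals, and values >= 0.9995 capped to "0.999".
    """
    header = "Heritability\t" + "\t".join(
        f"{n} Subjects" for n in table.n_values)
    lines = [header]
    for i, h in enumerate(table.h_values):
        cells = [_format_power_cell(p) for p in table.power_matrix[i]]
        lines.append("\t".join([_format_percent(h)] + cells))
    try:
        with open(destination, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write curve table to {destination}: {exc}")


def read_curve_table(source) -> PowerCurveTable:
    """Parse a TSV written by :func:`write_curve_table` back into a table."""
    with open(source) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    n_values = [int(col.split()[0]) for col in header[1:]]
    h_values, rows = [], []
    for ln in lines[1:]:
        cells = ln.split("\t")
        h_values.append(float(cells[0].rstrip("%")) / 100.0)
        rows.append([float("nan") if c == "NA" else float(c)
                     for c in cells[1:]])
    matrix = (np.array(rows, dtype=float) if rows
              else np.empty((0, len(n_values))))
    return PowerCurveTable(np.array(h_values), np.array(n_values), matrix)


def plot_curve_family(table: PowerCurveTable, destination) -> None:
    """Plot power against sample size, one curve per heritability.

    The user's design point, when present in ``table.annotation``, is
    drawn as a marker with its coordinates labelled.  Output format
    follows the file extension (SVG, PNG, PDF, ...).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for i, h in enumerate(table.h_values):
        row = table.power_matrix[i]
        style = "o-" if len(table.n_values) > 1 else "o"
        ax.plot(table.n_values, row, style, ms=3,
                label=f"H = {_format_percent(h)}")
    if table.annotation is not None:
        n0, p0 = table.annotation
        ax.plot([n0], [p0], "k*", ms=14, zorder=5)
        ax.annotate(f"design point (N={n0}, power={p0:.3f})",
                    xy=(n0, p0), xytext=(5, -12),
                    textcoords="offset points", fontsize=8)
    ax.set_xlabel("Sample size (N)")
    ax.set_ylabel("Power")
    ax.set_ylim(0.0, 1.02)
    ax.legend(fontsize=8, ncol=2)
    ax.set_title("Power curves by heritability")
    try:
        fig.savefig(destination, bbox_inches="tight")
    except OSError as exc:
        raise OSError(f"cannot write plot to {destination}: {exc}")
    finally:
        plt.close(fig)


def format_report(spec: DesignSpec, result: PowerResult) -> str:
    """Human-readable power report for a single design."""
    lines = [
        "Quantitative-trait association power",
        "------------------------------------",
        f"heritability (H)        : {spec.heritability:g}"
        f"  ({spec.heritability * 100:g}%)",
        f"sample size (N)         : {spec.n_subjects}",
        f"genetic model           : {spec.genetic_model} (one df)",
        f"SNPs tested (M)         : {spec.n_snps}",
        f"family-wise alpha       : {spec.family_alpha:g}",
        f"per-test alpha (2-sided): {result.per_test_alpha:.6g}",
    ]
    if spec.n_covariates:
        lines.append(
            f"covariates              : {spec.n_covariates} "
            f"(explaining {spec.covariate_variance * 100:g}% of variance)")
    if spec.ld_r2 < 1.0:
        lines.append(
            f"LD r^2 to causal variant: {spec.ld_r2:g} "
            f"(effective N = {spec.ld_r2 * spec.n_subjects:g})")
    lines += [
        f"error df                : {result.df_error:g}",
        f"noncentrality delta     : {result.noncentrality:.4f}"
        f"  (delta^2 = {result.noncentrality ** 2:.4f})",
        f"critical value          : {result.critical_t:.4f}"
        f"  [{result.method} method]",
        f"relative sd sqrt(MSE)   : {result.relative_sd:.6f}",
        f"detectable rel. diff    : {result.relative_delta_m:.6f}",
        "",
        f"POWER                   : {result.power:.4f}",
    ]
    return "\n".join(lines)


# --------------------------------------------------------------------------
# Command-line interface
# --------------------------------------------------------------------------

def parse_heritability(text: str) -> float:
    """Accept a fraction ("0.07") or a percent string ("7%")."""
    text = text.strip()
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    return float(text)


def read_config(path) -> dict:
    """Read a flat ``key = value`` config file (``#`` starts a comment)."""
    out = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw.rstrip()!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            out[key.replace("_", "-")] = value
    return out


def build_parser() -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(
        prog="qtpower",
        description="Power, sample size, and detectable heritability for "
                    "GWAS of quantitative traits, from heritability alone.",
    )
    ap.add_argument("--h2", type=str, default=None,
                    help="heritability, as a fraction (0.07) or percent (7%%)")
    ap.add_argument("--n", type=int, default=None, help="total sample size")
    ap.add_argument("--n-snps", type=int, default=None,
                    help="number of SNPs tested (Bonferroni denominator)")
    ap.add_argument("--alpha", type=float, default=None,
                    help="family-wise alpha (or per-test with --per-test)")
    ap.add_argument("--per-test", action="store_true",
                    help="treat --alpha as the per-test two-sided alpha")
    ap.add_argument("--covariates", type=int, default=None,
                    help="number of non-genetic covariates")
    ap.add_argument("--covariate-var", type=float, default=None,
                    help="fraction of variance the covariates explain")
    ap.add_argument("--ld-r2", type=float, default=None,
                    help="LD r^2 between marker and causal variant")
    ap.add_argument("--model", choices=GENETIC_MODELS, default=None,
                    help="genetic model (default additive)")
    ap.add_argument("--method", choices=("exact", "normal"), default=None,
                    help="exact noncentral t (default) or the normal "
                         "approximation used by the original GUI calculator")
    ap.add_argument("--target-power", type=float, default=None,
                    help="power target for --solve")
    ap.add_argument("--solve", choices=("n", "h2"), default=None,
                    help="solve for sample size (n) or detectable "
                         "heritability (h2) at --target-power")
    ap.add_argument("--curves", metavar="TSV", default=None,
                    help="write a power-curve table to this path")
    ap.add_argument("--plot", metavar="IMG", default=None,
                    help="write a curve-family plot to this path")
    ap.add_argument("--config", metavar="PATH", default=None,
                    help="flat key=value config file (flags override)")
    ap.add_argument("--seed", type=int, default=0,
                    help="master seed for --simulate")
    ap.add_argument("--simulate", type=int, metavar="REPS", default=None,
                    help="validate the analytic power by Monte-Carlo with "
                         "this many replicates")
    ap.add_argument("--maf", type=float, default=0.3,
                    help="minor-allele frequency for --simulate")
    ap.add_argument("--sim-audit", metavar="TSV", default=None,
                    help="write replicate-level simulation results")
    return ap


_CONFIG_KEYS = {
    "h2": str, "n": int, "n-snps": int, "alpha": float, "per-test": bool,
    "covariates": int, "covariate-var": float, "ld-r2": float,
    "model": str, "method": str, "target-power": float, "solve": str,
    "seed": int, "simulate": int, "maf": float,
}


# flag defaults that stand in when neither config nor flag sets a key
_FLAG_DEFAULTS = {"per-test": False, "maf": 0.3, "seed": 0}


def _resolve(args: argparse.Namespace) -> dict:
    """Merge config-file values under explicit flags (flags win)."""
    merged = {}
    if args.config:
        for key, value in read_config(args.config).items():
            if key not in _CONFIG_KEYS:
                raise ValueError(f"unknown config key {key!r}")
            caster = _CONFIG_KEYS[key]
            merged[key] = (value.lower() in ("1", "true", "yes")
                           if caster is bool else caster(value))
    for key in _CONFIG_KEYS:
        value = getattr(args, key.replace("-", "_"))
        default = _FLAG_DEFAULTS.get(key)
        if value is not None and value != default:
            merged[key] = value  # flag explicitly set (or differs from default)
        elif key in _FLAG_DEFAULTS:
            merged.setdefault(key, default)
    return merged


def _spec_from(merged: dict) -> DesignSpec:
    if "h2" not in merged:
        raise ValueError("heritability is required (--h2)")
    if "n" not in merged:
        raise ValueError("sample size is required (--n)")
    kwargs = dict(
        heritability=parse_heritability(str(merged["h2"])),
        n_subjects=merged["n"],
        n_snps=merged.get("n-snps", 1),
        n_covariates=merged.get("covariates", 0),
        covariate_variance=merged.get("covariate-var", 0.0),
        ld_r2=merged.get("ld-r2", 1.0),
        genetic_model=merged.get("model", "additive"),
    )
    alpha = merged.get("alpha")
    if merged.get("per-test"):
        if alpha is None:
            raise ValueError("--per-test requires --alpha")
        kwargs["per_test_alpha"] = alpha
    elif alpha is not None:
        kwargs["family_alpha"] = alpha
    return DesignSpec(**kwargs)


def _default_n_grid(spec: DesignSpec) -> np.ndarray:
    lo = _min_feasible_n(spec.n_covariates, spec.ld_r2)
    hi = max(4 * spec.n_subjects, lo + 1)
    grid = np.unique(np.geomspace(lo, hi, 10).round().astype(int))
    return np.unique(np.append(grid, spec.n_subjects))


def main(argv: Optional[Sequence[str]] = None) -> int:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s: %(message)s")
    args = build_parser().parse_args(argv)
    try:
        merged = _resolve(args)
        method = merged.get("method", "exact")
        solve = merged.get("solve")
        if solve is not None:
            target = merged.get("target-power")
            if target is None:
                raise ValueError("--solve requires --target-power")
            rest = dict(
                n_snps=merged.get("n-snps", 1),
                family_alpha=merged.get("alpha", DEFAULT_FAMILY_ALPHA)
                if not merged.get("per-test") else DEFAULT_FAMILY_ALPHA,
                per_test_alpha=merged.get("alpha")
                if merged.get("per-test") else None,
                n_covariates=merged.get("covariates", 0),
                covariate_variance=merged.get("covariate-var", 0.0),
                ld_r2=merged.get("ld-r2", 1.0),
                genetic_model=merged.get("model", "additive"),
            )
            if solve == "n":
                if "h2" not in merged:
                    raise ValueError("--solve n requires --h2")
                h = parse_heritability(str(merged["h2"]))
                n_req = solve_sample_size(h, target, method=method, **rest)
                spec = DesignSpec(heritability=h, n_subjects=n_req, **rest)
                logger.info("resolved design: %s", spec)
                print(f"Required sample size for power {target:g} at "
                      f"H={h:g}: N = {n_req}")
                print(format_report(spec, power(spec, method=method)))
            else:
                if "n" not in merged:
                    raise ValueError("--solve h2 requires --n")
                n = merged["n"]
                h_min = solve_detectable_heritability(
                    n, target, method=method, **rest)
                spec = DesignSpec(heritability=h_min, n_subjects=n, **rest)
                logger.info("resolved design: %s", spec)
                print(f"Smallest detectable heritability at N={n} for "
                      f"power {target:g}: H = {h_min:.6f} "
                      f"({h_min * 100:.2f}%)")
                print(format_report(spec, power(spec, method=method)))
            return 0

        spec = _spec_from(merged)
        logger.info("resolved design: %s (per-test alpha %.6g)",
                    spec, spec.resolved_alpha)
        result = power(spec, method=method)
        print(format_report(spec, result))

        if merged.get("simulate"):
            emp = empirical_power(
                spec, maf=merged.get("maf", 0.3),
                n_replicates=merged["simulate"],
                seed=merged.get("seed", 0),
                audit_path=args.sim_audit)
            print(f"\nMonte-Carlo power ({emp.n_replicates} replicates, "
                  f"MAF={merged.get('maf', 0.3):g}): "
                  f"{emp.estimate:.4f} +/- {emp.std_error:.4f} (SE)"
                  f"  [redraws: {emp.n_redraws}]")

        if args.curves or args.plot:
            table = power_curve_table(
                _default_n_grid(spec), method=method, annotate=spec,
                n_snps=spec.n_snps, family_alpha=spec.family_alpha,
                per_test_alpha=spec.per_test_alpha,
                n_covariates=spec.n_covariates,
                covariate_variance=spec.covariate_variance,
                ld_r2=spec.ld_r2, genetic_model=spec.genetic_model)
            if args.curves:
                write_curve_table(table, args.curves)
                print(f"\ncurve table written to {args.curves}")
            if args.plot:
                plot_curve_family(table, args.plot)
                print(f"curve plot written to {args.plot}")
        return 0
    except (ValueError, OSError) as exc:
        print(f"qtpower: error: {exc}", file=sys.stderr)
        return 2


if __name__ == "__main__":
    sys.exit(main())
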