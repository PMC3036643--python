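"""Analytic power engine: noncentrality algebra, distributions, invariants."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from qtpower import (
    DesignSpec,
    noncentrality,
    per_test_alpha,
    power,
)


class TestPerTestAlpha:
    @pytest.mark.parametrize(
        "family,m,expected",
        [(0.05, 1, 0.05), (0.05, 500_000, 1e-7), (0.05, 263_000, 0.05 / 263_000)],
    )
    def test_bonferroni_division(self, family, m, expected):
        assert per_test_alpha(family, m) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("family,m", [(0.0, 10), (1.0, 10), (-0.1, 10),
                                          (0.05, 0), (0.05, -3)])
    def test_domain_errors(self, family, m):
        with pytest.raises(ValueError):
            per_test_alpha(family, m)


class TestNoncentrality:
    # delta = sqrt(H * (r2*N - 2 - c) / (1 - H - C)); frozen from direct
    # arithmetic on the formula
    @pytest.mark.parametrize(
        "h,n,c,cv,r2,expected",
        [
            (0.07, 486, 0, 0.0, 1.0, math.sqrt(0.07 * 484 / 0.93)),   # 6.0357
            (0.5, 4, 0, 0.0, 1.0, math.sqrt(2.0)),                    # 1.4142
            (0.01, 2554, 0, 0.0, 1.0, math.sqrt(0.01 * 2552 / 0.99)), # 5.0774
            (0.07, 486, 2, 0.10, 1.0, math.sqrt(0.07 * 482 / 0.83)),  # 6.3757
        ],
    )
    def test_frozen_values(self, h, n, c, cv, r2, expected):
        assert noncentrality(h, n, c, cv, r2) == pytest.approx(expected,
                                                               rel=1e-10)

    def test_literal_magnitudes(self):
        # the two HIV-study design points, to 4 decimals
        assert noncentrality(0.07, 486) == pytest.approx(6.0357, abs=5e-5)
        assert noncentrality(0.01, 2554) == pytest.approx(5.0772, abs=5e-5)

    def test_insufficient_sample_size_raises(self):
        with pytest.raises(ValueError, match="sample size too small"):
            noncentrality(0.1, 6, n_covariates=5)
        with pytest.raises(ValueError, match="sample size too small"):
            noncentrality(0.1, 10, ld_r2=0.2)  # effective N = 2


class TestDesignSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(heritability=0.0, n_subjects=100),
            dict(heritability=1.0, n_subjects=100),
            dict(heritability=0.6, n_subjects=100, covariate_variance=0.5),
            dict(heritability=0.1, n_subjects=100.5),
            dict(heritability=0.1, n_subjects=2),
            dict(heritability=0.1, n_subjects=100, n_snps=0),
            dict(heritability=0.1, n_subjects=100, family_alpha=1.0),
            dict(heritability=0.1, n_subjects=100, per_test_alpha=0.0),
            dict(heritability=0.1, n_subjects=100, ld_r2=0.0),
            dict(heritability=0.1, n_subjects=100, ld_r2=1.5),
            dict(heritability=0.1, n_subjects=100, n_covariates=-1),
            dict(heritability=0.1, n_subjects=100, genetic_model="codominant"),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DesignSpec(**kwargs)

    def test_integral_float_n_accepted(self):
        assert DesignSpec(heritability=0.1, n_subjects=100.0).n_subjects == 100

    def test_default_alpha_is_bonferroni(self):
        spec = DesignSpec(heritability=0.1, n_subjects=100, n_snps=500_000)
        assert spec.resolved_alpha == pytest.approx(1e-7, rel=1e-12)
        override = spec.replace(per_test_alpha=1e-3)
        assert override.resolved_alpha == 1e-3


class TestPower:
    def test_null_limit_equals_alpha(self):
        # as H -> 0 the test is central and rejects at exactly its level
        spec = DesignSpec(heritability=1e-12, n_subjects=486,
                          per_test_alpha=0.05)
        for method in ("exact", "normal"):
            assert power(spec, method=method).power == pytest.approx(
                0.05, abs=1e-6)

    def test_alpha_near_one_gives_power_near_one(self):
        spec = DesignSpec(heritability=0.03, n_subjects=50,
                          per_test_alpha=1 - 1e-9)
        assert power(spec).power == pytest.approx(1.0, abs=1e-6)

    def test_intermediate_fields_populated(self):
        spec = DesignSpec(heritability=0.07, n_subjects=486, n_snps=100)
        res = power(spec)
        assert res.df_error == 484
        assert res.per_test_alpha == pytest.approx(0.05 / 100)
        assert res.noncentrality == pytest.approx(
            math.sqrt(0.07 * 484 / 0.93), rel=1e-12)
        assert res.critical_t == pytest.approx(
            stats.t.isf(res.per_test_alpha / 2, 484), rel=1e-12)
        # on the SST = 1 scale: std = sqrt(MSE) = sqrt((1-H)/(N-2))
        assert res.relative_sd == pytest.approx(
            math.sqrt(0.93 / 484), rel=1e-12)
        assert res.relative_delta_m == pytest.approx(
            res.relative_sd * res.critical_t, rel=1e-12)

    def test_power_bounded_by_alpha_and_one(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            spec = DesignSpec(
                heritability=float(rng.uniform(0.001, 0.5)),
                n_subjects=int(rng.integers(10, 5000)),
                per_test_alpha=float(10.0 ** rng.uniform(-8, -1)),
            )
            p = power(spec).power
            assert spec.resolved_alpha <= p + 1e-12
            assert p <= 1.0

    def test_identity_adjustments_bit_identical(self):
        base = DesignSpec(heritability=0.05, n_subjects=300, n_snps=1000)
        adjusted = DesignSpec(heritability=0.05, n_subjects=300, n_snps=1000,
                              n_covariates=0, covariate_variance=0.0,
                              ld_r2=1.0)
        assert power(base) == power(adjusted)

    def test_covariates_reduce_df_and_power(self):
        base = DesignSpec(heritability=0.05, n_subjects=100,
                          per_test_alpha=1e-4)
        adj = base.replace(n_covariates=10)
        assert power(adj).df_error == 88
        assert power(adj).power < power(base).power


class TestTSquaredFEquivalence:
    """X ~ t(d) implies X^2 ~ F(1, d), centrally and noncentrally."""

    @pytest.mark.parametrize("df", [5, 50, 484, 2552])
    @pytest.mark.parametrize("alpha", [0.05, 1e-7])
    def test_central_quantile_identity(self, df, alpha):
        # quantiles come from iterative inverse-CDF solvers, so compare at
        # their root tolerance; the distribution-function identity below is
        # checked far tighter
        t_crit = stats.t.isf(alpha / 2, df)
        f_crit = stats.f.isf(alpha, 1, df)
        assert t_crit ** 2 == pytest.approx(f_crit, rel=1e-9)
        # 2 P(T > x) = P(F > x^2) exactly, evaluated at the critical point
        assert 2 * stats.t.sf(t_crit, df) == pytest.approx(
            stats.f.sf(t_crit ** 2, 1, df), rel=1e-12)

    @pytest.mark.parametrize("df", [5, 50, 484, 2552])
    @pytest.mark.parametrize("alpha", [0.05, 1e-7])
    @pytest.mark.parametrize("h", [0.01, 0.07, 0.3])
    def test_noncentral_power_identity(self, df, alpha, h):
        n = df + 2
        spec = DesignSpec(heritability=h, n_subjects=n, per_test_alpha=alpha)
        res = power(spec)
        f_crit = stats.f.isf(alpha, 1, df)
        p_via_f = stats.ncf.sf(f_crit, 1, df, res.noncentrality ** 2)
        assert res.power == pytest.approx(p_via_f, abs=1e-10)


class TestMonotonicity:
    """Power strictly increases in H, N, r2, alpha; decreases in M and c."""

    def _p(self, **kw):
        defaults = dict(heritability=0.03, n_subjects=400, n_snps=1000,
                        family_alpha=0.05, n_covariates=0, ld_r2=1.0)
        defaults.update(kw)
        return power(DesignSpec(**defaults)).power

    def test_lattice(self):
        h_grid = [0.01, 0.03, 0.06, 0.10, 0.20]
        n_grid = [50, 200, 800, 3000]
        m_grid = [1, 100, 10_000, 1_000_000]
        checked = 0
        for h in h_grid:
            for n in n_grid:
                for m in m_grid:
                    base = self._p(heritability=h, n_subjects=n, n_snps=m)
                    if base > 1 - 1e-9:
                        continue  # saturated in float; strictness undefined
                    checked += 1
                    assert self._p(heritability=h * 1.2, n_subjects=n,
                                   n_snps=m) > base
                    assert self._p(heritability=h, n_subjects=2 * n,
                                   n_snps=m) > base
                    assert self._p(heritability=h, n_subjects=n,
                                   n_snps=10 * m) < base
                    assert self._p(heritability=h, n_subjects=n, n_snps=m,
                                   ld_r2=0.5) < base
                    assert self._p(heritability=h, n_subjects=n, n_snps=m,
                                   n_covariates=5) < base
        assert checked * 5 >= 100  # >= 100 ordered parameter comparisons

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        h=st.floats(min_value=0.005, max_value=0.4),
        n=st.integers(min_value=20, max_value=5000),
        log_alpha=st.floats(min_value=-8, max_value=-1.1),
    )
    def test_power_in_bounds_everywhere(self, h, n, log_alpha):
        spec = DesignSpec(heritability=h, n_subjects=n,
                          per_test_alpha=10.0 ** log_alpha)
        p = power(spec).power
        assert spec.resolved_alpha - 1e-12 <= p <= 1.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        h=st.floats(min_value=0.005, max_value=0.3),
        n=st.integers(min_value=20, max_value=3000),
    )
    def test_strictly_increasing_in_heritability(self, h, n):
        spec = DesignSpec(heritability=h, n_subjects=n, per_test_alpha=1e-4)
        bigger = spec.replace(heritability=min(h * 1.5, 0.9))
        p_lo, p_hi = power(spec).power, power(bigger).power
        assume(p_hi < 1 - 1e-9)  # strictness is lost once float saturates
        assert p_hi > p_lo
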