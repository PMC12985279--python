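"""Analytic SEs, Fieller intervals, delta-method INB CIs and the paired bootstrap."""

import math

import numpy as np
import pytest

from triagecea import (
    bootstrap_pairwise,
    combine_arm_ses,
    fieller_ci,
    inb_ci,
    se_cost,
    se_delta_effect,
)


class TestEffectSe:
    def test_closed_form_at_cohort_prevalence(self):
        assert se_delta_effect(0.2, 130) == pytest.approx(math.sqrt(41.6))  # ~6.45

    def test_simulation_oracle(self):
        """SD of differences of two independent Binomial(n, p) counts."""
        rng = np.random.default_rng(42)
        draws = rng.binomial(130, 0.2, 100_000) - rng.binomial(130, 0.2, 100_000)
        assert draws.std() == pytest.approx(se_delta_effect(0.2, 130), rel=0.02)

    def test_maximal_at_half(self):
        assert se_delta_effect(0.5, 100) > se_delta_effect(0.2, 100)
        assert se_delta_effect(0.5, 100) > se_delta_effect(0.8, 100)

    def test_degenerate_prevalence_rejected(self):
        for p in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                se_delta_effect(p, 130)


class TestCostSe:
    def test_cv_model(self):
        assert se_cost(67357, 0.175) == pytest.approx(11787.475)
        assert se_cost(12345, 0.0) == 0.0

    def test_quadrature_combination(self):
        assert combine_arm_ses(10, 10) == pytest.approx(10 * math.sqrt(2))

    def test_covariance_reduces_difference_se(self):
        assert combine_arm_ses(10, 10, cov=50) < combine_arm_ses(10, 10)
        with pytest.raises(ValueError, match="cov"):
            combine_arm_ses(1, 1, cov=10)


class TestFieller:
    def test_zero_uncertainty_collapses_to_point(self):
        est = fieller_ci(14634, 5, 0, 0)
        assert est.lower == est.point == est.upper == pytest.approx(2926.8)

    def test_effect_se_spanning_zero_gives_infinite_upper(self):
        """ΔE=1 with the binomial effect SE: the effect is indistinguishable
        from zero, so the confidence set is unbounded above."""
        est = fieller_ci(77065, 1, se_c=11787.0, se_e=se_delta_effect(0.2, 130))
        assert est.upper == math.inf
        assert math.isfinite(est.lower)

    def test_bounded_interval_contains_point(self):
        est = fieller_ci(10, 5, se_c=1, se_e=0.1)
        assert est.lower <= est.point <= est.upper
        assert est.point == pytest.approx(2.0)

    def test_converges_to_point_as_z_shrinks(self):
        wide = fieller_ci(10, 5, 1, 0.1, z=1.96)
        narrow = fieller_ci(10, 5, 1, 0.1, z=1e-6)
        assert narrow.upper - narrow.lower < 1e-5 < wide.upper - wide.lower
        assert narrow.point == pytest.approx(wide.point)

    def test_monte_carlo_oracle_small(self):
        """Percentiles of ratio draws of a bivariate normal match Fieller
        endpoints when the denominator is bounded away from zero."""
        rng = np.random.default_rng(7)
        mu_c, mu_e, se_c, se_e, cov = 40.0, 8.0, 6.0, 1.0, 2.4
        cov_m = [[se_c**2, cov], [cov, se_e**2]]
        draws = rng.multivariate_normal([mu_c, mu_e], cov_m, size=400_000)
        ratios = draws[:, 0] / draws[:, 1]
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        est = fieller_ci(mu_c, mu_e, se_c, se_e, cov, z=None)
        width = est.upper - est.lower
        assert est.lower == pytest.approx(lo, abs=0.02 * width)
        assert est.upper == pytest.approx(hi, abs=0.02 * width)

    def test_zero_delta_e_has_no_point_ratio(self):
        with pytest.raises(ZeroDivisionError):
            fieller_ci(100, 0, 1, 1)


class TestInbCi:
    def test_zero_uncertainty_collapses_to_point(self):
        est = inb_ci(14634, 5, 5000, 130, se_c=0, se_e=0)
        assert est.lower == est.point == est.upper == pytest.approx(10366 / 130)

    def test_width_nondecreasing_in_cost_cv(self):
        widths = []
        for cv in (0.10, 0.15, 0.175, 0.20):
            est = inb_ci(14634, 5, 5000, 130, se_c=cv * 80000, se_e=6.45)
            widths.append(est.upper - est.lower)
        assert widths == sorted(widths)

    def test_negative_radicand_names_cov(self):
        with pytest.raises(ValueError, match="cov"):
            inb_ci(100, 1, 5000, 130, se_c=1, se_e=0.001, cov=-1e6, cov_sign=+1)

    def test_cov_sign_conventions_differ(self):
        plus = inb_ci(100, 1, 5000, 130, se_c=100, se_e=1, cov=20, cov_sign=+1)
        minus = inb_ci(100, 1, 5000, 130, se_c=100, se_e=1, cov=20, cov_sign=-1)
        assert plus.upper - plus.lower > minus.upper - minus.lower


class TestBootstrap:
    def test_identity_resample_reproduces_point_estimates(
        self, cohort130, strategies, unit_costs
    ):
        idx = np.arange(cohort130.n)[None, :]
        res = bootstrap_pairwise(
            cohort130, strategies["mpmri_or_pet"], strategies["mpmri"], unit_costs,
            indices=idx,
        )
        assert res.B == 1
        assert res.delta_e_draws[0] == 5
        assert res.delta_c_draws[0] == pytest.approx(14633.6)  # exact-cent delta

    def test_seed_replay_is_bit_identical(self, cohort130, strategies, unit_costs):
        kw = dict(B=200, seed=123)
        a = bootstrap_pairwise(
            cohort130, strategies["pet"], strategies["mpmri"], unit_costs, **kw
        )
        b = bootstrap_pairwise(
            cohort130, strategies["pet"], strategies["mpmri"], unit_costs, **kw
        )
        assert np.array_equal(a.delta_e_draws, b.delta_e_draws)
        assert np.array_equal(a.delta_c_draws, b.delta_c_draws)
        assert a.ceac == b.ceac and a.inb_ci == b.inb_ci

    def test_identical_strategies_all_draws_zero(self, cohort130, strategies, unit_costs):
        res = bootstrap_pairwise(
            cohort130, strategies["mpmri"], strategies["mpmri"], unit_costs,
            B=100, seed=5,
        )
        assert np.all(res.delta_e_draws == 0) and np.all(res.delta_c_draws == 0)
        assert all(v == 0.0 for v in res.ceac.values())  # INB > 0 never
        assert res.prop_zero_delta_e == 1.0
        assert res.icer_draws.size == 0

    def test_zero_effect_replicates_tracked(self, cohort130, strategies, unit_costs):
        res = bootstrap_pairwise(
            cohort130, strategies["pet"], strategies["mpmri"], unit_costs,
            B=400, seed=9,
        )
        assert 0 <= res.prop_zero_delta_e < 1
        assert res.icer_draws.size == round((1 - res.prop_zero_delta_e) * 400)

    def test_invalid_B(self, cohort130, strategies, unit_costs):
        with pytest.raises(ValueError):
            bootstrap_pairwise(
                cohort130, strategies["pet"], strategies["mpmri"], unit_costs, B=0
            )
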