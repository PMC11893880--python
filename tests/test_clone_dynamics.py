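"""Fixation-slope posterior, C_part estimate and the bias ratio."""

import numpy as np
import pytest
from scipy.stats import beta

import cryptdrift as cd


def _census(pid, age, n, clones, ppc=0):
    return cd.CloneCensus(pid, age, n, clones, ppc, [1] * clones)


class TestFixationSlope:
    def test_mle_closed_form(self):
        censuses = [_census("a", 50.0, 10**6, 50), _census("b", 100.0, 10**6, 100)]
        assert cd.fixation_slope_mle(censuses) == pytest.approx(1.0e-6)

    def test_posterior_concentrates_on_mle(self):
        censuses = [
            _census("a", 40.0, 10**7, 4000),
            _census("b", 60.0, 10**7, 6000),
            _census("c", 80.0, 10**7, 8000),
        ]
        cfg = cd.InferenceConfig(seed=2, n_draws=800, n_warmup=800)
        post = cd.fit_fixation_slope(censuses, cfg)
        mle = cd.fixation_slope_mle(censuses)  # 1e-5, large counts
        assert post.mean == pytest.approx(mle, rel=0.02)
        assert post.ci95[0] <= mle <= post.ci95[1]
        assert post.rhat < 1.01

    def test_no_events_posterior_piles_near_zero(self):
        censuses = [_census(f"p{i}", 40.0 + 10 * i, 10**6, 0) for i in range(4)]
        cfg = cd.InferenceConfig(seed=3, n_draws=800, n_warmup=800)
        post = cd.fit_fixation_slope(censuses, cfg)
        exposure = sum(c.n_crypts * c.age for c in censuses)
        assert post.mean < 3.0 / exposure

    def test_recovers_truth_from_synthetic_cohort(self, small_cohort, fast_config):
        post = cd.fit_fixation_slope(small_cohort, fast_config)
        assert post.ci95[0] <= 1.6e-6 <= post.ci95[1]

    def test_order_and_split_invariance(self):
        censuses = [
            _census("a", 40.0, 10**7, 4000),
            _census("b", 60.0, 10**7, 6000),
            _census("c", 80.0, 10**7, 8000),
        ]
        cfg = cd.InferenceConfig(seed=5, n_draws=600, n_warmup=600)
        base = cd.fit_fixation_slope(censuses, cfg).mean
        rev = cd.fit_fixation_slope(censuses[::-1], cfg).mean
        split = cd.fit_fixation_slope(
            censuses[:2]
            + [_census("c1", 80.0, 5 * 10**6, 4000), _census("c2", 80.0, 5 * 10**6, 4000)],
            cfg,
        ).mean
        mc_tol = 0.02 * base
        assert abs(rev - base) < mc_tol and abs(split - base) < mc_tol

    def test_age_rescaling_rescales_slope(self):
        censuses = [
            _census("a", 40.0, 10**7, 4000),
            _census("b", 60.0, 10**7, 6000),
            _census("c", 80.0, 10**7, 8000),
        ]
        doubled = [
            _census(c.patient_id, 2 * c.age, c.n_crypts, c.wpc_count) for c in censuses
        ]
        assert cd.fixation_slope_mle(doubled) == pytest.approx(
            cd.fixation_slope_mle(censuses) / 2
        )

    def test_requires_three_distinct_ages(self):
        censuses = [_census("a", 50.0, 1000, 1), _census("b", 50.0, 1000, 2)]
        with pytest.raises(ValueError, match="distinct ages"):
            cd.fit_fixation_slope(censuses)

    def test_saturated_data_rejected(self):
        censuses = [
            _census("a", 40.0, 100, 90),
            _census("b", 60.0, 100, 95),
            _census("c", 80.0, 100, 99),
        ]
        with pytest.raises(ValueError, match="probability >= 1"):
            cd.fit_fixation_slope(censuses)


class TestCpart:
    def test_zero_ppc(self):
        est = cd.estimate_cpart([_census("a", 50.0, 10**6, 0, ppc=0)])
        assert est.pooled_frequency == 0.0
        assert est.ci95[0] == 0.0

    def test_clopper_pearson_bounds(self):
        est = cd.estimate_cpart([_census("a", 50.0, 10**6, 0, ppc=30)])
        assert est.pooled_frequency == pytest.approx(3.0e-5)
        # independent exact-binomial computation
        lo = beta.ppf(0.025, 30, 10**6 - 30 + 1)
        hi = beta.ppf(0.975, 30 + 1, 10**6 - 30)
        assert est.ci95 == (pytest.approx(lo), pytest.approx(hi))

    def test_simulated_coverage(self):
        hits = 0
        for rep in range(60):
            cohort = cd.simulate_cohort(
                cd.CohortSimParams(n_patients=40, cpart_true=5e-5, seed=1000 + rep)
            )
            est = cd.estimate_cpart(cohort)
            hits += est.ci95[0] <= 5e-5 <= est.ci95[1]
        assert hits >= 52  # ~95% nominal; 4 SD slack at n=60

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cd.estimate_cpart([])


class TestBiasRatio:
    def test_constant_draws_exact_ratio(self):
        post = cd.SlopePosterior(
            draws=np.full(100, 2e-6), mean=2e-6, ci95=(2e-6, 2e-6), rhat=1.0, seed=0
        )
        cpart = cd.CpartEstimate(5e-5, (4e-5, 6e-5), 50, 10**6)
        mean, (lo, hi) = cd.fixation_bias_ratio(post, cpart)
        assert mean == pytest.approx(0.04)
        assert lo == pytest.approx(0.04) and hi == pytest.approx(0.04)

    def test_doubling_events_doubles_ratio(self):
        censuses = [
            _census("a", 40.0, 10**7, 2000, ppc=300),
            _census("b", 60.0, 10**7, 3000, ppc=300),
            _census("c", 80.0, 10**7, 4000, ppc=300),
        ]
        doubled = [
            _census(c.patient_id, c.age, c.n_crypts, 2 * c.wpc_count, ppc=c.ppc_count)
            for c in censuses
        ]
        cfg = cd.InferenceConfig(seed=8, n_draws=600, n_warmup=600)
        r1, _ = cd.fixation_bias_ratio(
            cd.fit_fixation_slope(censuses, cfg), cd.estimate_cpart(censuses)
        )
        r2, _ = cd.fixation_bias_ratio(
            cd.fit_fixation_slope(doubled, cfg), cd.estimate_cpart(doubled)
        )
        assert r2 / r1 == pytest.approx(2.0, rel=0.03)

    def test_zero_cpart_raises_with_guidance(self):
        post = cd.SlopePosterior(np.full(10, 1e-6), 1e-6, (1e-6, 1e-6), 1.0, 0)
        cpart = cd.CpartEstimate(0.0, (0.0, 3e-6), 0, 10**6)
        with pytest.raises(ZeroDivisionError, match="score more crypts"):
            cd.fixation_bias_ratio(post, cpart)

    def test_biased_simulation_separates_by_factor_two(self):
        cfg = cd.InferenceConfig(seed=9, n_draws=600, n_warmup=600)
        ratios = []
        for slope in (1.6e-6, 3.2e-6):
            cohort = cd.simulate_cohort(
                cd.CohortSimParams(n_patients=120, delta_cfix_true=slope, seed=77)
            )
            ratios.append(
                cd.fixation_bias_ratio(
                    cd.fit_fixation_slope(cohort, cfg), cd.estimate_cpart(cohort)
                )[0]
            )
        assert ratios[1] / ratios[0] == pytest.approx(2.0, rel=0.25)

    def test_ols_crosscheck_near_mle_for_balanced_design(self):
        censuses = [
            _census("a", 40.0, 10**7, 4000),
            _census("b", 60.0, 10**7, 6000),
            _census("c", 80.0, 10**7, 8000),
        ]
        assert cd.ols_slope_crosscheck(censuses) == pytest.approx(
            cd.fixation_slope_mle(censuses), rel=1e-9
        )
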