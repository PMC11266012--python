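import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.estimators import (
    classify_effect,
    ivw,
    mode_estimator,
    mr_egger,
    run_all_methods,
    wald_ratio,
    weighted_median,
)
from mrkit.harmonize import HarmonizedRecord, harmonized_set_from_arrays
from mrkit.simulate import SimulationConfig, simulate_two_sample


def hrec(beta_exp=0.1, beta_out=0.05, se_out=0.01, se_exp=0.01, snp_id="rs1"):
    return HarmonizedRecord(snp_id=snp_id, beta_exp=beta_exp, se_exp=se_exp,
                            beta_out=beta_out, se_out=se_out, status="aligned")


def sim_hset(seed, k=30, true_beta=0.3, **kw):
    from mrkit.harmonize import harmonize
    from mrkit.instruments import InstrumentSet

    cfg = SimulationConfig(k=k, true_beta=true_beta, seed=seed, **kw)
    exp, out, _ = simulate_two_sample(cfg)
    inst = InstrumentSet("exp", list(exp.records), 5e-8)
    return harmonize(inst, out)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        res = wald_ratio(hrec(0.1, 0.05, 0.01))
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_null_outcome_gives_p_one(self):
        res = wald_ratio(hrec(0.1, 0.0, 0.01))
        assert res.beta == 0.0 and res.pval == pytest.approx(1.0)

    def test_zero_exposure_beta_is_hard_error(self):
        with pytest.raises(ValueError):
            wald_ratio(hrec(0.0, 0.05, 0.01))

    def test_matches_independent_recomputation(self, rng):
        for _ in range(10):
            be, bo, so = rng.normal(0.2, 0.05), rng.normal(0, 0.05), rng.uniform(0.01, 0.05)
            res = wald_ratio(hrec(be, bo, so))
            assert res.beta == pytest.approx(bo / be, abs=0)
            assert res.se == pytest.approx(so / abs(be), abs=0)


class TestIVW:
    def test_k1_disallowed_and_k2_equals_common_wald(self):
        with pytest.raises(ValueError):
            ivw(harmonized_set_from_arrays([0.1], [0.01], [0.05], [0.01]))
        h = harmonized_set_from_arrays([0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.01, 0.01])
        assert ivw(h).beta == pytest.approx(0.5)

    def test_noiseless_limit(self, proportional_hset):
        res = ivw(proportional_hset)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.extra["Q"] == pytest.approx(0.0, abs=1e-12)
        assert res.se == pytest.approx(res.extra["se_fixed"])

    def test_matches_wls_through_origin_oracle(self, noisy_hset):
        """Fixed-effects IVW vs generic weighted least squares with no intercept."""
        be, _, bo, so = noisy_hset.arrays()
        fit = sm.WLS(bo, be[:, None], weights=1 / so**2).fit()
        mine = ivw(noisy_hset, effects_model="fixed")
        assert mine.beta == pytest.approx(float(fit.params[0]), abs=1e-10)
        # WLS bse includes the estimated scale; the fixed-effects SE does not.
        unscaled = float(fit.bse[0]) / np.sqrt(fit.mse_resid)
        assert mine.se == pytest.approx(unscaled, abs=1e-10)

    def test_random_effects_se_never_below_fixed(self):
        for seed in range(5):
            h = sim_hset(seed, k=40, true_beta=0.1, pleiotropy=("balanced", 0.05))
            assert ivw(h).se >= ivw(h, effects_model="fixed").se - 1e-15


class TestEgger:
    def test_no_pleiotropy_limit(self):
        h = sim_hset(1, k=100, true_beta=0.3)
        res = mr_egger(h)
        assert abs(res.extra["intercept"]) < 0.005
        assert res.beta == pytest.approx(ivw(h).beta, abs=0.05)

    def test_intercept_translation_property(self, noisy_hset):
        """Adding +c to every outcome beta shifts the intercept by about +c."""
        c = 0.1
        res0 = mr_egger(noisy_hset)
        be, se, bo, so = noisy_hset.arrays()
        shifted = harmonized_set_from_arrays(be, se, bo + c, so)
        res1 = mr_egger(shifted)
        # Exact when all exposure betas are already positive (no re-orientation).
        assert (be > 0).all()
        assert res1.extra["intercept"] - res0.extra["intercept"] == pytest.approx(c, abs=1e-10)
        assert res1.beta == pytest.approx(res0.beta, abs=1e-10)

    def test_detects_directional_pleiotropy(self):
        hits = 0
        n_rep = 200
        for seed in range(1, n_rep + 1):
            h = sim_hset(seed, k=200, true_beta=0.1,
                         pleiotropy=("directional", 0.05, 0.02))
            if mr_egger(h).extra["intercept_p"] < 0.05:
                hits += 1
        assert hits / n_rep >= 0.8

    def test_k_below_three_is_hard_error(self):
        h = harmonized_set_from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(ValueError):
            mr_egger(h)


class TestWeightedMedian:
    def test_equal_weights_reduce_to_plain_median(self):
        be = np.full(11, 0.2)
        bo = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10, 0.11])
        h = harmonized_set_from_arrays(be, np.full(11, 0.01), bo, np.full(11, 0.02))
        res = weighted_median(h, n_boot=50, seed=1)
        assert res.beta == pytest.approx(float(np.median(bo / be)))

    def test_robust_to_single_wild_outlier(self, rng):
        be = rng.normal(0.2, 0.02, 11)
        so = np.full(11, 0.02)
        bo = 0.4 * be + rng.normal(0, 0.005, 11)
        clean = harmonized_set_from_arrays(be, np.full(11, 0.01), bo, so)
        bo_bad = bo.copy()
        bo_bad[0] = 5.0  # ratio ~ 25 vs ~0.4
        dirty = harmonized_set_from_arrays(be, np.full(11, 0.01), bo_bad, so)
        r_clean = weighted_median(clean, n_boot=200, seed=2)
        r_dirty = weighted_median(dirty, n_boot=200, seed=2)
        assert abs(r_dirty.beta - r_clean.beta) < 2 * r_clean.se

    def test_less_biased_than_ivw_under_forty_pct_invalid(self):
        med_err, ivw_err = [], []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            k = 100
            gamma = rng.normal(0.2, 0.05, k)
            alpha = np.where(np.arange(k) < 40, rng.normal(0.02, 0.005, k), 0.0)
            se_out = np.full(k, 0.01)
            be = rng.normal(gamma, 0.005)
            bo = rng.normal(0.3 * gamma + alpha, se_out)
            h = harmonized_set_from_arrays(be, np.full(k, 0.005), bo, se_out)
            med_err.append(abs(weighted_median(h, n_boot=2, seed=seed).beta - 0.3))
            ivw_err.append(abs(ivw(h).beta - 0.3))
        assert np.median(med_err) < np.median(ivw_err)


class TestModeEstimator:
    def test_identical_ratios_degenerate_density(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        h = harmonized_set_from_arrays(be, np.full(4, 0.01), 0.7 * be, np.full(4, 0.02))
        res = mode_estimator(h, weighted=True, n_boot=10, seed=3)
        assert res.beta == pytest.approx(0.7)

    def test_bimodal_ratios_pick_majority_cluster(self):
        be = np.full(13, 0.2)
        ratios = np.concatenate([np.full(10, 0.2) + np.linspace(-0.01, 0.01, 10),
                                 np.full(3, 0.9)])
        h = harmonized_set_from_arrays(be, np.full(13, 0.01), ratios * be, np.full(13, 0.02))
        res = mode_estimator(h, weighted=False, n_boot=10, seed=4)
        assert abs(res.beta - 0.2) < 0.05

    def test_simple_equals_weighted_under_symmetric_weights(self):
        # Equal exposure betas and equal outcome SEs make the two weightings agree.
        be = np.full(9, 0.2)
        bo = np.linspace(0.05, 0.09, 9)
        h = harmonized_set_from_arrays(be, np.full(9, 0.01), bo, np.full(9, 0.02))
        simple = mode_estimator(h, weighted=False, n_boot=5, seed=5)
        weighted = mode_estimator(h, weighted=True, n_boot=5, seed=5)
        assert simple.beta == pytest.approx(weighted.beta)


class TestRunAllMethods:
    def test_noiseless_proportional_fixture_all_methods_agree(self, proportional_hset):
        results, info = run_all_methods(proportional_hset, seed=1, n_boot=20)
        assert len(results) == 5
        for res in results:
            assert res.beta == pytest.approx(0.5, abs=1e-6)
        assert info["direction_consistent"]

    def test_k2_degrades_to_ivw(self):
        h = harmonized_set_from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        results, info = run_all_methods(h, seed=1)
        assert [r.method for r in results] == ["ivw"]
        assert info["degraded"] is not None

    def test_k1_degrades_to_wald(self):
        h = harmonized_set_from_arrays([0.1], [0.01], [0.05], [0.01])
        results, info = run_all_methods(h, seed=1)
        assert [r.method for r in results] == ["wald"]

    def test_null_simulation_yields_small_estimates(self):
        h = sim_hset(9, k=100, true_beta=0.0)
        results, _ = run_all_methods(h, seed=9, n_boot=20)
        for res in results:
            assert abs(res.beta) < 0.05

    def test_empty_set_is_hard_error(self):
        from mrkit.harmonize import HarmonizedSet

        with pytest.raises(ValueError):
            run_all_methods(HarmonizedSet("e", "o", []), seed=0)


class TestClassification:
    def test_significant_or_above_one_is_risk_factor(self):
        from mrkit.estimators import MRResult

        res = MRResult(method="ivw", k=10, beta=np.log(1.4), se=0.1, pval=0.02)
        cls = classify_effect(res)
        assert cls.label == "risk_factor" and not cls.loo_required

    def test_borderline_protective_triggers_leave_one_out(self):
        from mrkit.estimators import MRResult

        res = MRResult(method="ivw", k=10, beta=np.log(0.8), se=0.1, pval=0.045)
        cls = classify_effect(res)
        assert cls.label == "protective_factor" and cls.loo_required

    def test_nonsignificant_is_null(self):
        from mrkit.estimators import MRResult

        res = MRResult(method="ivw", k=10, beta=0.1, se=0.1, pval=0.2)
        assert classify_effect(res).label == "null"

    def test_non_ivw_input_rejected(self):
        from mrkit.estimators import MRResult

        with pytest.raises(ValueError):
            classify_effect(MRResult(method="egger", k=10, beta=0.1, se=0.1, pval=0.01))


class TestResultInvariants:
    def test_or_and_ci_consistency(self, noisy_hset):
        res = ivw(noisy_hset)
        assert res.or_ == pytest.approx(np.exp(res.beta))
        assert res.ci_low < res.or_ < res.ci_high
        assert res.ci_low == pytest.approx(np.exp(res.beta - 1.96 * res.se))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 10), seed=st.integers(0, 50))
    def test_scale_equivariance(self, c, seed):
        """Multiplying exposure betas by c divides the estimates by c."""
        h = sim_hset(seed, k=12, true_beta=0.2)
        be, se, bo, so = h.arrays()
        scaled = harmonized_set_from_arrays(be * c, se * c, bo, so)
        for fn in (lambda s: ivw(s), lambda s: mr_egger(s),
                   lambda s: weighted_median(s, n_boot=2, seed=0)):
            assert fn(scaled).beta == pytest.approx(fn(h).beta / c, rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 50))
    def test_outcome_sign_flip_negates_estimates(self, seed):
        h = sim_hset(seed, k=12, true_beta=0.2)
        be, se, bo, so = h.arrays()
        flipped = harmonized_set_from_arrays(be, se, -bo, so)
        for fn in (ivw, mr_egger):
            a, b = fn(h), fn(flipped)
            assert b.beta == pytest.approx(-a.beta, rel=1e-9)
            assert b.pval == pytest.approx(a.pval, rel=1e-9)
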