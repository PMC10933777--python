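"""Estimator battery: Wald ratio, IVW variants, Egger, median, mode, MVMR."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from causalmr import (
    ValidationError,
    egger,
    ivw,
    mediation,
    mvmr_ivw,
    ratio_set,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import make_harmonised


class TestWaldRatio:
    def test_published_blood_pressure_example(self):
        """SNP dosage effects 0.0617 on systolic BP and 0.0652 on CAD give a
        causal log-odds ratio of 1.06 per SD of BP."""
        est = wald_ratio(0.0617, 0.01, 0.0652, 0.0275)
        assert round(est.estimate, 2) == 1.06

    def test_zero_outcome_association(self):
        assert wald_ratio(0.5, 0.01, 0.0, 0.05).estimate == 0.0

    def test_delta_method_se(self):
        est = wald_ratio(0.5, 0.01, 0.2, 0.05)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_association_rejected(self):
        with pytest.raises(ValidationError, match="ratio"):
            wald_ratio(0.0, 0.01, 0.1, 0.05)


class TestRatioSet:
    def test_single_snp_matches_wald_ratio(self):
        h = make_harmonised([0.1], [0.01], [0.05], [0.02])
        rs = ratio_set(h)
        w = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert rs.beta[0] == pytest.approx(w.estimate)
        assert rs.se[0] == pytest.approx(w.se)

    def test_second_order_reduces_to_first_order_without_exposure_noise(self):
        h = make_harmonised([0.1, 0.2], [0.0 + 1e-300, 1e-300], [0.05, 0.1], [0.02, 0.03])
        np.testing.assert_allclose(ratio_set(h, "second_order").se, ratio_set(h).se)

    def test_weights_are_inverse_variances(self):
        be = np.array([0.1, 0.2, 0.05])
        so = np.array([0.02, 0.01, 0.05])
        h = make_harmonised(be, 0.01, [0.05, 0.1, 0.02], so)
        rs = ratio_set(h)
        np.testing.assert_allclose(rs.weights, (be / so) ** 2)

    def test_zero_exposure_beta_names_the_snp(self):
        h = make_harmonised([0.1, 0.0], 0.01, [0.05, 0.02], 0.02)
        with pytest.raises(ValidationError, match="rs002"):
            ratio_set(h)


class TestIvw:
    def test_hand_computed_weighted_mean(self):
        # ratios {0.1,0.2,0.3} with ratio SEs {0.05,0.05,0.10}
        be = np.array([1.0, 1.0, 1.0])
        bo = np.array([0.1, 0.2, 0.3])
        so = np.array([0.05, 0.05, 0.10])
        est = ivw(make_harmonised(be, 0.001, bo, so), model="fixed")
        w = 1 / so**2
        assert est.estimate == pytest.approx(float((w * bo).sum() / w.sum()))
        assert est.estimate == pytest.approx(1.5 / 9)

    def test_single_instrument_degenerates_to_wald(self):
        h = make_harmonised([0.1], 0.01, [0.05], 0.02)
        est = ivw(h)
        w = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.estimate == pytest.approx(w.estimate)
        assert est.se == pytest.approx(w.se)

    def test_homogeneous_ratios_make_models_agree(self):
        be = np.array([0.1, 0.2, 0.4])
        bo = 0.5 * be
        h = make_harmonised(be, 0.001, bo, [0.01, 0.02, 0.04])
        fixed, mult, add = (ivw(h, model=m) for m in ("fixed", "multiplicative", "additive"))
        assert fixed.estimate == pytest.approx(mult.estimate) == pytest.approx(add.estimate)
        assert fixed.se == pytest.approx(mult.se) == pytest.approx(add.se)
        assert add.extras["tau2"] == 0.0

    def test_fixed_equals_weighted_through_origin_regression(self, harmonised_basic):
        """Independent oracle: statsmodels WLS of outcome on exposure betas
        through the origin with weights 1/se_O²."""
        h = harmonised_basic
        kept = h.kept
        res = sm.WLS(
            kept["beta_outcome"],
            kept["beta_exposure"],
            weights=1.0 / kept["se_outcome"] ** 2,
        ).fit()
        est = ivw(h, model="fixed")
        assert est.estimate == pytest.approx(res.params.iloc[0], abs=1e-12)
        assert est.se == pytest.approx(
            float(np.sqrt(res.normalized_cov_params.iloc[0, 0])), abs=1e-12
        )

    def test_multiplicative_se_never_below_fixed(self, harmonised_basic):
        fixed = ivw(harmonised_basic, model="fixed")
        mult = ivw(harmonised_basic, model="multiplicative")
        assert mult.estimate == pytest.approx(fixed.estimate)
        assert mult.se >= fixed.se

    @given(st.lists(st.booleans(), min_size=5, max_size=5))
    @settings(deadline=None, max_examples=16, derandomize=True)
    def test_allele_relabelling_invariance(self, flips):
        """Jointly sign-flipping (beta_E, beta_O) of any SNP subset leaves
        every pooled estimate unchanged."""
        rng = np.random.default_rng(0)
        be = rng.uniform(0.05, 0.2, 5)
        bo = 0.3 * be + rng.normal(0, 0.01, 5)
        sgn = np.where(flips, -1.0, 1.0)
        h1 = make_harmonised(be, 0.01, bo, 0.02)
        h2 = make_harmonised(be * sgn, 0.01, bo * sgn, 0.02)
        for model in ("fixed", "multiplicative", "additive"):
            assert ivw(h2, model=model).estimate == pytest.approx(
                ivw(h1, model=model).estimate
            )
        assert egger(h2).estimate == pytest.approx(egger(h1).estimate)


class TestEgger:
    def test_exact_line_through_origin(self):
        be = np.array([0.05, 0.1, 0.15, 0.2])
        h = make_harmonised(be, 0.01, 0.5 * be, 0.02)
        est = egger(h)
        assert est.estimate == pytest.approx(0.5, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_shifted_line_recovered_exactly(self):
        be = np.array([0.05, 0.1, 0.15, 0.2])
        h = make_harmonised(be, 0.01, 0.5 * be + 0.02, 0.02)
        est = egger(h)
        assert est.estimate == pytest.approx(0.5, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.02, abs=1e-10)

    def test_matches_statsmodels_wls_with_intercept(self):
        rng = np.random.default_rng(3)
        be = rng.uniform(0.05, 0.3, 8)
        bo = 0.4 * be + 0.01 + rng.normal(0, 0.01, 8)
        so = rng.uniform(0.01, 0.03, 8)
        h = make_harmonised(be, 0.01, bo, so)
        res = sm.WLS(bo, sm.add_constant(be), weights=1 / so**2).fit()
        est = egger(h)
        assert est.estimate == pytest.approx(res.params[1], abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(res.params[0], abs=1e-10)

    def test_orientation_invariance(self):
        be = np.array([0.05, -0.1, 0.15, 0.2])
        bo = np.array([0.03, -0.06, 0.08, 0.11])
        h1 = make_harmonised(be, 0.01, bo, 0.02)
        h2 = make_harmonised(-be, 0.01, -bo, 0.02)
        assert egger(h1).estimate == pytest.approx(egger(h2).estimate)
        assert egger(h1).extras["intercept"] == pytest.approx(egger(h2).extras["intercept"])

    def test_too_few_instruments(self):
        h = make_harmonised([0.1, 0.2], 0.01, [0.05, 0.1], 0.02)
        with pytest.raises(ValidationError):
            egger(h)

    def test_constant_exposure_unidentifiable(self):
        h = make_harmonised([0.1, 0.1, 0.1], 0.01, [0.05, 0.06, 0.04], 0.02)
        with pytest.raises(ValidationError, match="unidentifiable"):
            egger(h)


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        h = make_harmonised(np.ones(5), 0.01, [1.0, 2.0, 3.0, 4.0, 5.0], 1.0)
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.estimate == pytest.approx(3.0)

    def test_dominant_weight_pulls_to_that_snp(self):
        # SNP with ratio 4 carries ~90% of the total weight
        se_o = np.array([1.0, 1.0, 1.0, 1.0 / 6.0, 1.0])
        h = make_harmonised(np.ones(5), 0.001, [1.0, 2.0, 3.0, 4.0, 5.0], se_o)
        est = weighted_median(h, n_boot=50, seed=0)
        assert abs(est.estimate - 4.0) < 0.1

    def test_seed_reproducibility(self, harmonised_basic):
        a = weighted_median(harmonised_basic, n_boot=100, seed=7)
        b = weighted_median(harmonised_basic, n_boot=100, seed=7)
        assert a.se == b.se and a.estimate == b.estimate


class TestWeightedMode:
    def test_majority_cluster_wins_over_mean(self):
        bo = np.array([0.20, 0.21, 0.19, 0.20, 0.22, 1.0, 1.02])
        h = make_harmonised(np.ones(7), 0.001, bo, 0.02)
        est = weighted_mode(h, n_boot=20, seed=0)
        assert abs(est.estimate - 0.2) < 0.05
        w = 1 / 0.02**2
        ivw_mean = bo.mean()  # equal weights
        assert abs(est.estimate - 0.2) < abs(ivw_mean - 0.2)

    def test_degenerate_identical_ratios(self):
        h = make_harmonised(np.ones(4), 0.001, 0.4 * np.ones(4), 0.02)
        est = weighted_mode(h, n_boot=20, seed=0)
        assert est.estimate == pytest.approx(0.4, abs=1e-9)

    def test_smoothing_never_adds_local_maxima(self):
        """Gaussian-kernel density: the count of interior local maxima is
        non-increasing in the bandwidth factor."""
        from causalmr.estimators import _mode_bandwidth

        rng = np.random.default_rng(5)
        beta = np.concatenate([rng.normal(0.2, 0.01, 6), rng.normal(1.0, 0.02, 3)])
        w = np.ones_like(beta)

        def n_maxima(phi):
            from scipy import stats as ss

            bw = _mode_bandwidth(beta, phi)
            grid = np.linspace(beta.min() - 3 * bw, beta.max() + 3 * bw, 512)
            dens = ss.norm.pdf((grid[None, :] - beta[:, None]) / bw).sum(0)
            interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
            return int(interior.sum())

        counts = [n_maxima(phi) for phi in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestMvmr:
    def test_single_exposure_reduces_to_ivw(self, harmonised_basic):
        kept = harmonised_basic.kept
        res = mvmr_ivw(
            kept["beta_exposure"].to_numpy()[:, None],
            kept["beta_outcome"].to_numpy(),
            kept["se_outcome"].to_numpy(),
        )
        assert res[0].estimate == pytest.approx(
            ivw(harmonised_basic, model="fixed").estimate, abs=1e-12
        )

    def test_orthogonal_exposures_equal_separate_fits(self):
        x1 = np.array([1.0, 1.0, -1.0, -1.0])
        x2 = np.array([1.0, -1.0, 1.0, -1.0])  # orthogonal under equal weights
        y = 0.3 * x1 + 0.7 * x2
        se = np.ones(4) * 0.1
        joint = mvmr_ivw(np.column_stack([x1, x2]), y, se)
        uni1 = mvmr_ivw(x1[:, None], y, se)
        uni2 = mvmr_ivw(x2[:, None], y, se)
        assert joint[0].estimate == pytest.approx(uni1[0].estimate, abs=1e-12)
        assert joint[1].estimate == pytest.approx(uni2[0].estimate, abs=1e-12)
        assert joint[0].estimate == pytest.approx(0.3)
        assert joint[1].estimate == pytest.approx(0.7)

    def test_duplicated_exposure_column_collinear(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValidationError, match="collinear"):
            mvmr_ivw(np.column_stack([x, x]), x, np.ones(4) * 0.1)


class TestMediation:
    def test_difference_and_product_arithmetic(self):
        res = mediation(beta_total=0.5, c_direct=0.3, a_exposure_mediator=0.5, b_mediator_outcome=0.4)
        assert res.indirect_difference == pytest.approx(0.2)
        assert res.indirect_product == pytest.approx(0.2)

    def test_methods_agree_in_linear_gaussian_system(self):
        """X→M→Y plus a direct path: regression-based difference and product
        estimators agree within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        n = 20_000
        x = rng.standard_normal(n)
        m = 0.5 * x + rng.standard_normal(n)
        y = 0.4 * m + 0.2 * x + rng.standard_normal(n)

        beta_tot = np.polyfit(x, y, 1)[0]
        a_hat = np.polyfit(x, m, 1)[0]
        X = np.column_stack([np.ones(n), x, m])
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        c_hat, b_hat = coef[1], coef[2]
        res = mediation(beta_tot, c_hat, a_hat, b_hat)
        assert res.indirect_difference == pytest.approx(res.indirect_product, abs=0.02)
        assert res.indirect_product == pytest.approx(0.2, abs=0.03)
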