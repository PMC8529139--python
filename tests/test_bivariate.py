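"""Bivariate binomial-normal likelihood, ML fit and pooled summaries."""

import math

import numpy as np
import pytest
from scipy import special, stats

import dtameta as dm
from dtameta.bivariate import binom_bivariate_loglik, mahalanobis_inside


def brute_force_loglik(mu, sigma, studies, half_width=8.0, n_grid=601):
    """Dense-grid 2-D numeric integration oracle for the marginal loglik."""
    sd1 = math.sqrt(sigma[0][0])
    sd2 = math.sqrt(sigma[1][1])
    a = np.linspace(mu[0] - half_width * sd1, mu[0] + half_width * sd1, n_grid)
    b = np.linspace(mu[1] - half_width * sd2, mu[1] + half_width * sd2, n_grid)
    A, B = np.meshgrid(a, b, indexing="ij")
    pos = np.dstack([A, B])
    density = stats.multivariate_normal(mean=mu, cov=sigma).pdf(pos)
    total = 0.0
    for s in studies:
        f = (
            stats.binom.pmf(s.tp, s.tp + s.fn, special.expit(A))
            * stats.binom.pmf(s.tn, s.fp + s.tn, special.expit(B))
            * density
        )
        integral = np.trapezoid(np.trapezoid(f, b, axis=1), a)
        total += math.log(integral)
    return total


def make_set(rows):
    return dm.StudySet(
        [dm.Study2x2(study_id=f"s{i}", tp=r[0], fn=r[1], fp=r[2], tn=r[3])
         for i, r in enumerate(rows)]
    )


class TestLoglik:
    def test_degenerate_sigma_collapses_to_binomials(self, mir21):
        mu = (1.0, 1.2)
        got = binom_bivariate_loglik(mu, np.zeros((2, 2)), mir21)
        want = sum(
            stats.binom.logpmf(s.tp, s.tp + s.fn, special.expit(mu[0]))
            + stats.binom.logpmf(s.tn, s.fp + s.tn, special.expit(mu[1]))
            for s in mir21
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_single_study_closed_form(self):
        s = make_set([(8, 2, 2, 8)])
        mu = (special.logit(0.8), special.logit(0.8))
        got = binom_bivariate_loglik(mu, np.zeros((2, 2)), s)
        want = 2 * stats.binom.logpmf(8, 10, 0.8)
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_quadrature_matches_dense_grid_integration(self, seed):
        """Gauss-Hermite vs brute-force 2-D grid on 2-study toys, 1e-5."""
        rng = np.random.default_rng(seed)
        mu = rng.normal(0.8, 0.5, 2)
        sd = rng.uniform(0.3, 0.9, 2)
        rho = rng.uniform(-0.7, 0.7)
        sigma = np.array(
            [[sd[0] ** 2, rho * sd[0] * sd[1]],
             [rho * sd[0] * sd[1], sd[1] ** 2]]
        )
        studies = make_set([(8, 2, 3, 7), (15, 6, 4, 18)])
        got = binom_bivariate_loglik(mu, sigma, studies, quad_nodes=51)
        want = brute_force_loglik(mu.tolist(), sigma.tolist(), studies)
        assert got == pytest.approx(want, abs=1e-5)

    def test_quadrature_refinement_on_fixture(self, mir21):
        mu = (1.1, 1.5)
        sigma = np.array([[0.6, 0.3], [0.3, 0.5]])
        v25 = binom_bivariate_loglik(mu, sigma, mir21, quad_nodes=25)
        v51 = binom_bivariate_loglik(mu, sigma, mir21, quad_nodes=51)
        assert v25 == pytest.approx(v51, abs=1e-6)

    def test_non_psd_sigma_rejected(self, mir21):
        with pytest.raises(ValueError):
            binom_bivariate_loglik((0, 0), [[1.0, 2.0], [2.0, 1.0]], mir21)


class TestFit:
    def test_too_few_trials_refused(self):
        s = make_set([(8, 2, 2, 8), (9, 1, 3, 7), (7, 3, 2, 8)])
        with pytest.raises(dm.InsufficientStudiesError):
            dm.fit_bivariate(s)

    def test_identical_trials_recover_aggregate_proportion(self):
        # four copies of (8,2,2,8): no between-study signal, mu at logit 0.8
        s = make_set([(8, 2, 2, 8)] * 4)
        fit = dm.fit_bivariate(s)
        assert special.expit(fit.mu[0]) == pytest.approx(0.8, abs=1e-3)
        assert special.expit(fit.mu[1]) == pytest.approx(0.8, abs=1e-3)
        assert fit.sigma[0, 0] < 0.01 and fit.sigma[1, 1] < 0.01

    def test_reparameterisation_invariance(self, toy_studies):
        f1 = dm.fit_bivariate(toy_studies, param="logsd_rho")
        f2 = dm.fit_bivariate(toy_studies, param="cholesky")
        assert np.allclose(f1.mu, f2.mu, atol=1e-5)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-4)

    def test_trial_order_irrelevant(self, toy_studies):
        rev = dm.StudySet(list(toy_studies)[::-1])
        f1 = dm.fit_bivariate(toy_studies)
        f2 = dm.fit_bivariate(rev)
        assert np.allclose(f1.mu, f2.mu, atol=1e-5)
        assert np.allclose(f1.sigma, f2.sigma, atol=1e-4)

    def test_normal_approx_agrees_roughly_with_glmm(self, mir21):
        fit_n = dm.fit_bivariate(mir21, method="normal_approx")
        fit_g = dm.fit_bivariate(mir21)
        assert special.expit(fit_n.mu[0]) == pytest.approx(
            special.expit(fit_g.mu[0]), abs=0.05)
        assert special.expit(fit_n.mu[1]) == pytest.approx(
            special.expit(fit_g.mu[1]), abs=0.05)

    def test_parameter_recovery_from_large_synthetic_studies(self):
        cfg = dm.SimConfig(
            n_studies=200,
            mu=(1.0, 1.5),
            sigma=((0.2, 0.0), (0.0, 0.3)),
            arm_size_law=("fixed", 2000),
            prevalence_law=("fixed", 0.5),
            seed=7,
        )
        fit = dm.fit_bivariate(dm.simulate_studies(cfg))
        # 200 studies, sigma1=0.2 -> MC SE of mu1 ~ sqrt(0.2/200) ~ 0.032
        assert fit.mu[0] == pytest.approx(1.0, abs=3 * math.sqrt(0.2 / 200))
        assert fit.mu[1] == pytest.approx(1.5, abs=3 * math.sqrt(0.3 / 200))


class TestPooledSummary:
    def test_point_estimates_inside_cis(self, mir21_summary):
        s = mir21_summary
        assert s.sens_ci[0] < s.sens < s.sens_ci[1]
        assert s.spec_ci[0] < s.spec < s.spec_ci[1]
        assert s.plr_ci[0] < s.plr < s.plr_ci[1]
        assert s.nlr_ci[0] < s.nlr < s.nlr_ci[1]
        assert s.dor_ci[0] < s.dor < s.dor_ci[1]

    def test_ratio_identities(self, mir21_summary):
        s = mir21_summary
        assert s.plr == pytest.approx(s.sens / (1 - s.spec))
        assert s.nlr == pytest.approx((1 - s.sens) / s.spec)
        assert s.dor == pytest.approx(s.plr / s.nlr)

    def test_chance_level_mu_gives_unit_ratios(self, mir21_fit):
        from dataclasses import replace

        fit = replace(mir21_fit, mu=np.zeros(2))
        s = dm.pooled_summary(fit)
        assert s.sens == s.spec == 0.5
        assert s.plr == s.nlr == s.dor == pytest.approx(1.0)


class TestPredictRegion:
    def test_prediction_contains_confidence_pointwise(self, mir21_fit):
        conf = dm.predict_region(mir21_fit, kind="confidence", n_points=60)
        # map each confidence point back to logit space and check it is
        # inside the prediction ellipse
        for fpr, sens in conf:
            z = (special.logit(sens), -special.logit(fpr))
            assert mahalanobis_inside(mir21_fit, z, kind="prediction", level=0.95)

    def test_lower_level_nested_inside_higher(self, mir21_fit):
        inner = dm.predict_region(mir21_fit, level=0.5, kind="prediction", n_points=40)
        for fpr, sens in inner:
            z = (special.logit(sens), -special.logit(fpr))
            assert mahalanobis_inside(mir21_fit, z, kind="prediction", level=0.95)

    def test_prediction_region_consistent_with_study_cloud(self, mir21, mir21_fit):
        """Nearly all observed study points are compatible with the 95%
        prediction region once their own sampling noise is added (the
        region is for the *true* accuracy pair of a new study, so raw
        points scatter beyond it)."""
        rep = dm.detect_outliers(mir21, mir21_fit, within="observed")
        inside = len(mir21) - len(rep.flagged_ids)
        assert inside >= 0.8 * len(mir21)

    def test_bad_level_rejected(self, mir21_fit):
        with pytest.raises(ValueError):
            dm.predict_region(mir21_fit, level=1.5)
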