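"""Cochran Q / I-squared, Spearman threshold screen, Deeks asymmetry test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dtameta as dm
from dtameta.heterogeneity import cochran_q, i_squared


class TestCochranQ:
    def test_identical_studies_give_zero(self):
        q, df, p = cochran_q([1.3, 1.3], [0.2, 0.2])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_three_study_case(self):
        # y = (0, 0, 3), unit variances: pooled mean 1, Q = 1 + 1 + 4 = 6
        q, df, p = cochran_q([0.0, 0.0, 3.0], [1.0, 1.0, 1.0])
        assert q == pytest.approx(6.0)
        assert df == 2

    def test_single_study_rejected(self):
        with pytest.raises(dm.InsufficientStudiesError):
            cochran_q([1.0], [0.5])

    def test_fixture_shows_significant_heterogeneity(self, mir21):
        het = dm.heterogeneity(mir21)
        assert het.q_sens > het.df and het.p_sens < 0.05
        assert het.i2_sens > 50.0


class TestISquared:
    def test_zero_q(self):
        assert i_squared(0.0, 5) == 0.0

    def test_formula_point(self):
        assert i_squared(4.0, 2) == pytest.approx(50.0)

    def test_truncation_below_df(self):
        assert i_squared(1.0, 5) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(q=st.floats(0, 1e6), df=st.integers(1, 500))
    def test_always_in_percentage_range(self, q, df):
        assert 0.0 <= i_squared(q, df) <= 100.0


def pairs_to_set(pairs):
    """Build a StudySet whose (logit sens, logit fpr) ranks follow pairs."""
    studies = []
    for i, (a, b) in enumerate(pairs):
        tp = 10 + 5 * a
        fp = 10 + 5 * b
        studies.append(
            dm.Study2x2(study_id=f"p{i}", tp=int(tp), fn=20, fp=int(fp), tn=20)
        )
    return dm.StudySet(studies)


class TestThresholdSpearman:
    def test_perfectly_monotone_pairs(self):
        res = dm.threshold_spearman(pairs_to_set([(1, 2), (2, 3), (3, 4)]))
        assert res.rho == pytest.approx(1.0)

    def test_antitone_pairs(self):
        res = dm.threshold_spearman(pairs_to_set([(1, 4), (2, 3), (3, 2)]))
        assert res.rho == pytest.approx(-1.0)

    def test_tied_ranks_match_brute_force(self):
        # 5 pairs, one tie in x: brute-force average-rank Pearson oracle
        pairs = [(1, 2), (2, 1), (2, 5), (4, 3), (5, 4)]
        res = dm.threshold_spearman(pairs_to_set(pairs))
        x = np.array([p[0] for p in pairs], float)
        y = np.array([p[1] for p in pairs], float)

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        want = float(np.corrcoef(rx, ry)[0, 1])
        assert res.rho == pytest.approx(want, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self, mir21):
        # doubling all counts keeps each logit ratio, hence the ranks —
        # for tables without zero cells (corrected cells do not scale)
        clean = mir21.subset(lambda s: not s.has_zero_cell())
        base = dm.threshold_spearman(clean)
        doubled = dm.StudySet(
            [
                dm.Study2x2(study_id=s.study_id, tp=2 * s.tp, fn=2 * s.fn,
                            fp=2 * s.fp, tn=2 * s.tn)
                for s in clean
            ]
        )
        res = dm.threshold_spearman(doubled)
        assert res.rho == pytest.approx(base.rho, abs=1e-12)

    def test_exact_permutation_p_close_to_t_for_moderate_rho(self):
        pairs = [(1, 2), (2, 1), (3, 5), (4, 3), (5, 4), (6, 6), (7, 5)]
        t_res = dm.threshold_spearman(pairs_to_set(pairs), method="t")
        e_res = dm.threshold_spearman(pairs_to_set(pairs), method="exact")
        assert e_res.rho == t_res.rho
        assert e_res.p == pytest.approx(t_res.p, abs=0.15)

    def test_no_threshold_effect_on_fixture(self, mir21):
        res = dm.threshold_spearman(mir21)
        assert not res.threshold_effect

    def test_too_few_studies(self):
        with pytest.raises(dm.InsufficientStudiesError):
            dm.threshold_spearman(pairs_to_set([(1, 2), (2, 3)]))


class TestDeeks:
    def test_hand_weighted_least_squares_oracle(self):
        # lnDOR = (2, 2.5, 3) at ESS = (100, 50, 25): WLS slope 10.304
        # (weighted means 0.12612 / 2.28571; Sxy 2.22951, Sxx 0.216387)
        import statsmodels.api as sm

        ess = np.array([100.0, 50.0, 25.0])
        lnd = np.array([2.0, 2.5, 3.0])
        x = sm.add_constant(1.0 / np.sqrt(ess))
        res = sm.WLS(lnd, x, weights=ess).fit()
        assert res.params[1] == pytest.approx(10.304, abs=0.001)

    def test_slope_scaling_law_under_ess_rescale(self, mir21):
        """slope(c * ESS) = sqrt(c) * slope(ESS) exactly: the regressor
        1/sqrt(ESS) shrinks by sqrt(c) while the weights only rescale."""
        import statsmodels.api as sm
        from dtameta.heterogeneity import _ess
        from dtameta.metrics import metrics_table

        lnd = np.array([math.log(m.dor) for m in metrics_table(mir21)])
        ess = _ess(mir21)
        for c in (4.0, 0.25):
            x1 = sm.add_constant(1.0 / np.sqrt(ess))
            x2 = sm.add_constant(1.0 / np.sqrt(c * ess))
            s1 = sm.WLS(lnd, x1, weights=ess).fit().params[1]
            s2 = sm.WLS(lnd, x2, weights=c * ess).fit().params[1]
            assert s2 == pytest.approx(math.sqrt(c) * s1, rel=1e-10)

    def test_type_i_error_calibrated_under_null(self):
        """lnDOR independent of ESS: rejection rate at alpha=.10 in the
        binomial 95% band over 500 replicates."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2021)
        n, reps, alpha = 50, 500, 0.10
        rejections = 0
        for _ in range(reps):
            ess = rng.uniform(20, 400, n)
            # mean independent of ess; variance proportional to 1/ess as
            # the weighted regression assumes
            lnd = rng.normal(2.0, 4.0 / np.sqrt(ess), n)
            x = sm.add_constant(1.0 / np.sqrt(ess))
            p = sm.WLS(lnd, x, weights=ess).fit().pvalues[1]
            rejections += p < alpha
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 1.96 * se + 1e-9

    def test_fixture_shows_small_study_asymmetry(self, mir21):
        # these 30 tables contain several tiny trials with near-perfect
        # accuracy; the funnel is genuinely asymmetric
        res = dm.deeks_test(mir21)
        assert res.slope > 0
        assert res.p < 0.05

    def test_too_few_studies(self):
        s = dm.StudySet([
            dm.Study2x2(study_id="a", tp=5, fn=5, fp=5, tn=5),
            dm.Study2x2(study_id="b", tp=6, fn=4, fp=4, tn=6),
        ])
        with pytest.raises(dm.InsufficientStudiesError):
            dm.deeks_test(s)

    def test_funnel_coordinates_shape(self, mir21):
        from dtameta.heterogeneity import funnel_coordinates

        coords = funnel_coordinates(mir21)
        assert list(coords.columns) == ["study_id", "inv_sqrt_ess", "dor"]
        assert len(coords) == 30
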