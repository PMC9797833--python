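import numpy as np
import pytest

from ctstrain.stats import (
    DEFAULT_SEGMENT_VIEW_MAP,
    classify_patient,
    classify_view,
    cohen_kappa,
    compare_correlations,
    confusion_metrics,
    consensus_view_labels,
    fleiss_kappa,
    linfit_r2,
    roc_and_optimal_cutoff,
    two_prop_ztest,
)


def make_labels(default="normal", **overrides):
    """{reader: {segment: label}} with per-(reader, segment) overrides
    given as r{reader}s{segment}='label'."""
    labels = {r: {s: default for s in range(1, 17)} for r in (1, 2, 3)}
    for key, val in overrides.items():
        r, s = key[1:].split("s")
        labels[int(r)][int(s)] = val
    return labels


class TestConsensus:
    def test_all_normal(self):
        views, study = consensus_view_labels(make_labels())
        assert views == {"2CH": False, "3CH": False, "4CH": False}
        assert study is False

    def test_single_reader_vote_insufficient(self):
        views, study = consensus_view_labels(
            make_labels(r1s3="hypokinetic"))
        assert not study

    def test_two_reader_akinetic_marks_mapped_view(self):
        # segment 14 (apical septal) maps to the 4CH view
        assert 14 in DEFAULT_SEGMENT_VIEW_MAP["4CH"]
        views, study = consensus_view_labels(
            make_labels(r1s14="akinetic", r2s14="akinetic"))
        assert views == {"2CH": False, "3CH": False, "4CH": True}
        assert study

    def test_mapping_covers_all_sixteen_segments(self):
        segs = sorted(s for v in DEFAULT_SEGMENT_VIEW_MAP.values() for s in v)
        assert segs == list(range(1, 17))

    def test_missing_entries_rejected(self):
        labels = make_labels()
        del labels[2][9]
        with pytest.raises(ValueError, match="missing"):
            consensus_view_labels(labels)


class TestRoc:
    def test_separable_scores(self):
        scores = [-0.30, -0.28, -0.25, -0.08, -0.05, -0.02]
        truth = [0, 0, 0, 1, 1, 1]
        roc = roc_and_optimal_cutoff(scores, truth)
        assert roc.auc == 1.0
        assert roc.operating_point == (1.0, 1.0)
        assert -0.25 < roc.optimal_threshold < -0.08

    def test_auc_equals_pair_count(self):
        scores = np.array([-0.30, -0.25, -0.10, -0.05])
        truth = np.array([0, 0, 1, 1], dtype=bool)
        roc = roc_and_optimal_cutoff(scores, truth)
        conc = np.mean([
            1.0 if sa > sn else 0.5 if sa == sn else 0.0
            for sa in scores[truth] for sn in scores[~truth]
        ])
        assert roc.auc == pytest.approx(conc) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_matches_mann_whitney_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 500))
        scores = np.round(rng.normal(size=n), 2)  # ties included
        truth = rng.random(n) < 0.4
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        roc = roc_and_optimal_cutoff(scores, truth)
        pos, neg = scores[truth], scores[~truth]
        conc = np.mean([(pos[:, None] > neg[None, :]) +
                        0.5 * (pos[:, None] == neg[None, :])])
        assert roc.auc == pytest.approx(conc, abs=1e-12)
        # independent cross-check against sklearn
        from sklearn.metrics import roc_auc_score
        assert roc.auc == pytest.approx(roc_auc_score(truth, scores),
                                        abs=1e-12)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=200)
        truth = rng.random(200) < 0.5
        assert roc_and_optimal_cutoff(scores, truth).auc == \
            pytest.approx(0.5, abs=0.1)

    def test_roc_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=120)
        truth = rng.random(120) < 0.4
        roc = roc_and_optimal_cutoff(scores, truth)
        # raising tau (requiring less-negative LS) can only lose abnormal
        # calls: sensitivity non-increasing, specificity non-decreasing
        order = np.argsort(roc.thresholds)
        assert np.all(np.diff(roc.sensitivity[order]) <= 1e-12)
        assert np.all(np.diff(roc.specificity[order]) >= -1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_and_optimal_cutoff([0.1, 0.2], [1, 1])


class TestClassification:
    # view cutoffs from the training-cohort operating points
    TAUS = {"2CH": -0.218, "3CH": -0.154, "4CH": -0.166}

    def test_strong_shortening_is_normal(self):
        assert classify_view(-0.30, "2CH", self.TAUS) is False

    def test_weak_shortening_is_abnormal(self):
        assert classify_view(-0.10, "3CH", self.TAUS) is True

    def test_equality_counts_abnormal(self):
        assert classify_view(-0.166, "4CH", self.TAUS) is True

    def test_single_threshold_mode(self):
        assert classify_view(-0.20, "2CH", -0.170) is False
        assert classify_view(-0.15, "2CH", -0.170) is True

    def test_missing_view_threshold_raises(self):
        with pytest.raises(ValueError, match="threshold"):
            classify_view(-0.2, "4CH", {"2CH": -0.218})

    @pytest.mark.parametrize("views,expected", [
        ((False, False, False), False),
        ((False, True, False), True),
        ((True, True, True), True),
    ])
    def test_patient_rule(self, views, expected):
        assert classify_patient(views) is expected

    def test_patient_requires_views(self):
        with pytest.raises(ValueError):
            classify_patient([])


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        m = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert m.accuracy == 100.0 and m.fp == 0 and m.fn == 0

    def test_undefined_rate_reported_absent(self):
        m = confusion_metrics([0, 0], [0, 0])
        assert m.sensitivity is None and m.ppv is None
        assert m.specificity == 100.0

    def test_wald_ci_contains_point_estimate(self):
        m = confusion_metrics([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        for name in ("accuracy", "sensitivity", "specificity", "ppv"):
            p = getattr(m, name)
            lo, hi = m.ci[name]
            assert lo <= p <= hi
            assert 0.0 <= lo and hi <= 100.0


class TestAgreement:
    def test_cohen_identical_sequences(self):
        a = np.array([0, 1, 1, 0, 1, 0])
        assert cohen_kappa(a, a).kappa == pytest.approx(1.0)

    def test_cohen_matches_direct_formula(self):
        # 2x2 table counts (a, b, c, d) = (20, 5, 10, 15)
        a = np.repeat([1, 1, 0, 0], [20, 5, 10, 15])
        b = np.repeat([1, 0, 1, 0], [20, 5, 10, 15])
        n = 50
        po = (20 + 15) / n
        pe = ((25 / n) * (30 / n)) + ((25 / n) * (20 / n))
        expected = (po - pe) / (1 - pe)
        assert cohen_kappa(a, b).kappa == pytest.approx(expected, abs=1e-12)

    def test_cohen_independent_raters_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        assert abs(cohen_kappa(a, b).kappa) < 0.1

    def test_cohen_degenerate_undefined(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]).kappa is None

    def test_fleiss_perfect_agreement(self):
        ratings = np.tile(np.array([[0], [1], [0], [1], [1]]), (1, 3))
        assert fleiss_kappa(ratings).kappa == pytest.approx(1.0)

    def test_fleiss_matches_hand_computation(self):
        # 4 subjects x 3 raters, categories {0, 1}
        ratings = np.array([[0, 0, 1], [1, 1, 1], [0, 1, 1], [0, 0, 0]])
        # counts per subject: n_i0, n_i1 -> P_i = sum n(n-1) / (m(m-1))
        table = np.array([[2, 1], [0, 3], [1, 2], [3, 0]])
        p_i = ((table * (table - 1)).sum(axis=1)) / (3 * 2)
        p_bar = p_i.mean()
        p_j = table.sum(axis=0) / table.sum()
        p_e = (p_j**2).sum()
        expected = (p_bar - p_e) / (1 - p_e)
        assert fleiss_kappa(ratings).kappa == pytest.approx(expected,
                                                            abs=1e-12)

    def test_fleiss_independent_raters_near_zero(self):
        rng = np.random.default_rng(21)
        ratings = rng.integers(0, 2, size=(500, 3))
        assert abs(fleiss_kappa(ratings).kappa) < 0.1


class TestProportionAndCorrelationTests:
    def test_equal_proportions(self):
        z, p = two_prop_ztest(30, 100, 60, 200)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_direct_pooled_formula(self):
        z, p = two_prop_ztest(30, 100, 45, 100)
        pool = 75 / 200
        se = np.sqrt(pool * (1 - pool) * (1 / 100 + 1 / 100))
        z_direct = (0.30 - 0.45) / se
        from scipy.stats import norm
        assert z == pytest.approx(z_direct, abs=1e-12)
        assert p == pytest.approx(2 * norm.sf(abs(z_direct)), abs=1e-12)

    def test_balanced_cohorts_not_significant(self):
        _, p = two_prop_ztest(59, 150, 54, 150)
        assert p > 0.05

    def test_degenerate_pooled_proportion(self):
        with pytest.warns(UserWarning):
            z, p = two_prop_ztest(0, 10, 0, 10)
        assert (z, p) == (0.0, 1.0)

    def test_equal_correlations(self):
        z, p = compare_correlations(0.5, 0.5, 100, 100)
        assert z == 0.0 and p == 1.0

    def test_large_r2_gap_significant(self):
        # correlations corresponding to R^2 of 0.38 vs 0.89 at n = 144
        z, p = compare_correlations(np.sqrt(0.38), np.sqrt(0.89), 144, 144)
        assert p < 0.05

    def test_antisymmetry(self):
        z1, _ = compare_correlations(0.3, 0.8, 50, 60)
        z2, _ = compare_correlations(0.8, 0.3, 50, 60)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 0.5, 50, 50)


class TestLinearFit:
    def test_collinear_points(self):
        x = np.arange(10.0)
        fit = linfit_r2(x, 3 * x - 2)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(3.0)
        assert np.allclose(fit.band_hi - fit.band_lo, 0.0, atol=1e-8)

    def test_noisy_line_definitional_r2(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 100)
        y = 2 * x + rng.normal(0, 1, 100)
        fit = linfit_r2(x, y)
        resid = y - (fit.intercept + fit.slope * x)
        r2_direct = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert fit.r2 == pytest.approx(r2_direct, abs=1e-12)
        se = 1.0 / np.sqrt(((x - x.mean()) ** 2).sum())
        assert fit.slope == pytest.approx(2.0, abs=3 * se)

    def test_r2_invariant_under_affine_x_rescale(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 50)
        y = x + rng.normal(0, 0.2, 50)
        assert linfit_r2(x, y).r2 == pytest.approx(
            linfit_r2(5 * x - 3, y).r2, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linfit_r2(np.ones(5), np.arange(5.0))
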