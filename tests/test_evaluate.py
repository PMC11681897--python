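import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from speckleshock import (
    ClassifierConfig,
    ConfusionMatrix,
    classify,
    cohens_d,
    confusion,
    diagnostics,
    invert_summary,
    mann_whitney_u,
    roc,
    screen_shock,
    shock_index,
    spearman,
)


class TestClassify:
    def test_study_median_positive_at_default_cutoff(self):
        cfg = ClassifierConfig.default_for("roi_diff")
        assert cfg.cutoff == 6966.43
        assert classify([6249.0], cfg)[0]  # shock-group median

    def test_control_median_negative(self):
        cfg = ClassifierConfig.default_for("roi_diff")
        assert not classify([14406.0], cfg)[0]

    def test_tie_at_cutoff_is_negative(self):
        cfg = ClassifierConfig(metric="roi_diff", cutoff=100.0)
        assert not classify([100.0], cfg)[0]

    def test_above_rule(self):
        cfg = ClassifierConfig(metric="SI", cutoff=0.9, positive_if="above")
        assert list(classify([1.2, 0.6, 0.9], cfg)) == [True, False, False]

    def test_nonfinite_rejected(self):
        cfg = ClassifierConfig.default_for("roi_ratio")
        with pytest.raises(ValueError):
            classify([np.nan], cfg)


class TestConfusionDiagnostics:
    def test_perfect_split(self):
        truth = [True] * 20 + [False] * 20
        cm = confusion(truth, truth)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (20, 20, 0, 0)

    def test_map_predictor_counts(self):
        cm = ConfusionMatrix(tp=8, fp=0, fn=12, tn=20)
        d = diagnostics(cm)
        assert d["accuracy"] == pytest.approx(0.70)
        assert d["recall"] == pytest.approx(0.40)

    def test_sbp_predictor_metrics(self):
        cm = ConfusionMatrix(tp=11, fp=0, fn=9, tn=20)
        d = diagnostics(cm)
        assert d["accuracy"] == pytest.approx(0.7750)
        assert d["recall"] == pytest.approx(0.5500)
        assert d["f1"] == pytest.approx(0.7097, abs=5e-5)

    def test_reconstructed_matrix_metrics(self):
        cm = ConfusionMatrix(tp=11, fp=2, fn=9, tn=18)
        d = diagnostics(cm)
        assert d["accuracy"] == pytest.approx(0.725)
        assert d["recall"] == pytest.approx(0.55)
        assert d["f1"] == pytest.approx(2 / 3, abs=1e-9)

    def test_undefined_recall_flagged(self):
        cm = ConfusionMatrix(tp=0, fp=3, fn=0, tn=5)
        assert diagnostics(cm)["recall"] is None

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=0, fp=0, fn=0, tn=0)


class TestInvertSummary:
    def test_unique_solution_725(self):
        cm = invert_summary(0.725, 0.55, 20, 20)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (11, 2, 9, 18)

    def test_unique_solution_825(self):
        cm = invert_summary(0.825, 0.75, 20, 20)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (15, 2, 5, 18)

    def test_perfect(self):
        cm = invert_summary(1.0, 1.0, 20, 20)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (20, 20, 0, 0)

    def test_round_trip_with_diagnostics(self):
        for acc, rec in [(0.725, 0.55), (0.825, 0.75), (0.775, 0.55), (0.70, 0.40)]:
            cm = invert_summary(acc, rec, 20, 20)
            d = diagnostics(cm)
            assert d["accuracy"] == pytest.approx(acc, abs=1e-12)
            assert d["recall"] == pytest.approx(rec, abs=1e-12)

    def test_inconsistent_rejected(self):
        with pytest.raises(ValueError):
            invert_summary(0.1, 1.0, 20, 20)  # implies negative tn


class TestRoc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 4, 10, 11, 12, 13]
        truth = [True] * 4 + [False] * 4
        assert roc(scores, truth, "below").auc == 1.0

    def test_pair_counting_example(self):
        r = roc([1, 2, 3, 4], [True, False, True, False], "below")
        assert r.auc == pytest.approx(0.75)

    def test_auc_equals_u_over_n1n2(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n1, n2 = rng.integers(3, 8, 2)
            scores = rng.integers(0, 6, n1 + n2).astype(float)  # ties likely
            truth = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
            r = roc(scores, truth, "above")
            # oracle: exhaustive pair counting with ties at half
            wins = sum(
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a in scores[truth]
                for b in scores[~truth]
            )
            assert r.auc == pytest.approx(wins / (n1 * n2), abs=1e-12)

    def test_complement_under_label_flip(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=30)
        truth = rng.random(30) < 0.5
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        a1 = roc(scores, truth, "below").auc
        a2 = roc(scores, ~truth, "below").auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        truth = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        r1 = roc(scores, truth, "below")
        r2 = roc(np.exp(scores), truth, "below")
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert np.allclose(r1.sensitivity, r2.sensitivity)

    def test_youden_criterion_separates(self):
        scores = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        truth = [True, True, True, False, False, False]
        r = roc(scores, truth, "below")
        assert r.associated_criterion == 3.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [True, True, True], "below")


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res["U"] == 0.0
        assert res["p_two_sided"] == pytest.approx(1 / 3, abs=1e-12)

    def test_exact_matches_enumeration_oracle(self):
        x = [1.0, 5.0, 2.5, 7.0]
        y = [3.0, 6.0, 4.0]
        res = mann_whitney_u(x, y)
        # oracle: enumerate all label assignments directly
        combined = np.array(x + y)
        n1 = len(x)
        u_obs = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        mu = len(x) * len(y) / 2
        count = total = 0
        for idx in itertools.combinations(range(len(combined)), n1):
            xs = combined[list(idx)]
            ys = np.delete(combined, list(idx))
            u = stats.mannwhitneyu(xs, ys, alternative="two-sided").statistic
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
            total += 1
        assert res["p_two_sided"] == pytest.approx(count / total, abs=1e-12)

    def test_identical_samples_p_one(self):
        x = list(range(10))
        assert mann_whitney_u(x, x)["p_two_sided"] == pytest.approx(1.0, abs=0.02)

    def test_large_sample_close_to_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.8, 1, 25)
        res = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res["p_two_sided"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_power_under_shift(self):
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(0, 1, 20)
            y = rng.normal(1.5, 1, 20)
            if mann_whitney_u(x, y)["p_two_sided"] < 0.05:
                rejections += 1
        assert rejections / reps > 0.9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSpearman:
    def test_perfectly_decreasing(self):
        res = spearman([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert res["rs"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks of y=[2,1,4,3,5]: sum d^2 = 4 -> rs = 1 - 24/120 = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res["rs"] == pytest.approx(0.8, abs=1e-12)

    @given(
        st.lists(
            st.integers(min_value=-100, max_value=100),
            min_size=4,
            max_size=20,
            unique=True,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, x):
        # integer inputs keep exp() strictly monotone in float arithmetic
        rng = np.random.default_rng(11)
        y = rng.normal(size=len(x))
        a = spearman(np.asarray(x, float), y)
        b = spearman(np.exp(np.asarray(x, float) / 100.0), y)
        assert a["rs"] == pytest.approx(b["rs"], abs=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        mine = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert mine["rs"] == pytest.approx(ref.statistic, abs=1e-12)
        assert mine["p_two_sided"] == pytest.approx(ref.pvalue, rel=1e-6)


class TestCohensD:
    # printed two-group moments: (study mean, sd, control mean, sd, expected d)
    TABLE = [
        ("Age", 68.8, 15.4, 41.7, 12.0, -2.0),
        ("Height", 160.5, 8.5, 164.2, 6.7, 0.5),
        ("Weight", 55.2, 8.9, 66.9, 13.3, 1.0),
        ("MAP", 71.4, 18.5, 93.8, 12.9, 1.4),
        ("SBP", 91.9, 18.6, 127.4, 19.4, 1.9),
        ("DBP", 61.3, 19.1, 77.0, 11.1, 1.0),
        ("BT", 36.8, 1.5, 36.2, 0.1, -0.6),
        ("HR", 112.9, 24.4, 76.9, 7.7, -2.0),
        ("RR", 21.9, 3.2, 18.7, 0.9, -1.4),
        ("SpO2", 94.6, 6.9, 99.2, 0.5, 0.9),
        ("ROI1", 33674.6, 15748.0, 36319.7, 11362.2, 0.2),
        ("ROI2", 24656.0, 11762.1, 21681.6, 7396.1, -0.3),
        ("ROI_diff", 9018.7, 7620.0, 14638.1, 5970.7, 0.8),
    ]

    @pytest.mark.parametrize("name,ms,ss,mc,sc,expected", TABLE)
    def test_printed_effect_sizes(self, name, ms, ss, mc, sc, expected):
        # age sign: control-minus-study on these moments gives -2.0 after
        # the same rounding used in the printed column
        d = cohens_d(ms, ss, 20, mc, sc, 20)
        assert round(d, 1) == pytest.approx(expected, abs=0.15)

    def test_sbp_exact_value(self):
        d = cohens_d(91.9, 18.6, 20, 127.4, 19.4, 20)
        assert d == pytest.approx(1.868, abs=1e-3)
        assert round(d, 1) == 1.9

    def test_hr_sign(self):
        d = cohens_d(112.9, 24.4, 20, 76.9, 7.7, 20)
        assert round(d, 1) == -2.0

    def test_si_known_rounding_discrepancy(self):
        # recomputes to -2.40 from the printed (rounded) moments, not -2.5
        d = cohens_d(1.3, 0.4, 20, 0.6, 0.1, 20)
        assert d == pytest.approx(-2.401, abs=1e-3)

    def test_equal_means_zero(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0

    def test_pooled_sd_weighting(self):
        # with n1 = n2 this equals the average-of-variances form
        d = cohens_d(0.0, 1.0, 20, 1.0, 3.0, 20)
        assert d == pytest.approx(1.0 / np.sqrt(5.0))


class TestShockIndexAndScreening:
    def test_study_medians(self):
        res = shock_index(111.0, 93.5)
        assert res["SI"] == pytest.approx(1.187, abs=1e-3)
        assert res["flag"]

    def test_control_medians(self):
        res = shock_index(78.0, 126.0)
        assert res["SI"] == pytest.approx(0.619, abs=1e-3)
        assert not res["flag"]

    def test_zero_sbp(self):
        with pytest.raises(ValueError):
            shock_index(80.0, 0.0)

    def test_screen_sbp_criterion(self):
        res = screen_shock({"SBP": 91.9, "MAP": 80.0, "lactate": 1.0})
        assert res["shock"]
        assert res["criteria"] == ["SBP<95"]

    def test_screen_negative(self):
        assert not screen_shock({"SBP": 120.0, "MAP": 80.0, "lactate": 1.0})["shock"]

    def test_screen_lactate_alone(self):
        res = screen_shock({"lactate": 4.5})
        assert res["shock"]
        assert res["criteria"] == ["lactate>2"]

    def test_missing_values_do_not_fire(self):
        assert not screen_shock({"SBP": float("nan")})["shock"]
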