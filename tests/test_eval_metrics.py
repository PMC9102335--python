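import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnsvm.errors import ShapeError, UndefinedMetricError
from cnsvm.eval_metrics import (
    ConfusionMatrix,
    basic_rates,
    cohen_kappa,
    confusion,
    evaluate,
    mse,
    roc_auc,
    segment_cube,
)
from cnsvm.synthetic_data import simulate_cube
from conftest import quick_separable_config

WORKED_TABLE = ConfusionMatrix(tp=45, fn=5, fp=10, tn=40)


class TestConfusion:
    def test_hand_count(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_all_wrong(self):
        c = confusion([0, 0], [1, 1])
        assert c.tp == 0 and c.tn == 0 and c.fp == 2

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            confusion([1, 0], [1])


class TestBasicRates:
    def test_worked_example(self):
        accuracy, sensitivity, specificity = basic_rates(WORKED_TABLE)
        assert accuracy == pytest.approx(0.85)
        assert sensitivity == pytest.approx(0.90)
        assert specificity == pytest.approx(0.80)

    def test_perfect_classifier(self):
        assert basic_rates(ConfusionMatrix(5, 0, 5, 0)) == (1.0, 1.0, 1.0)

    def test_zero_denominator_reported_absent(self):
        _, sensitivity, _ = basic_rates(ConfusionMatrix(tp=0, fn=0, fp=1, tn=1))
        assert sensitivity is None


class TestRocAuc:
    def test_three_vs_three_fixture(self):
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        _, auc = roc_auc(labels, scores)
        assert auc == pytest.approx(8 / 9)

    def test_perfect_separation(self):
        _, auc = roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0

    def test_all_ties_is_half(self):
        _, auc = roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_curve_anchors_and_monotonicity(self):
        roc, _ = roc_auc([1, 0, 1, 0, 1], [0.9, 0.6, 0.6, 0.2, 0.4])
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)
        assert (np.diff(roc[:, 0]) >= 0).all() and (np.diff(roc[:, 1]) >= 0).all()

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1], [0.5, 0.6])

    def test_random_scores_give_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=4000)
        scores = rng.random(4000)
        _, auc = roc_auc(labels, scores)
        assert auc == pytest.approx(0.5, abs=0.05)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_auc_invariant_under_monotone_transforms(self, data):
        n = data.draw(st.integers(4, 20))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < len(l)
            )
        )
        # a coarse grid keeps the transforms strictly monotone in float64
        scores = np.array(
            data.draw(st.lists(st.floats(-5, 5), min_size=n, max_size=n))
        ).round(3)
        _, auc = roc_auc(labels, scores)
        for transform in (np.exp, lambda x: 2 * x + 1, lambda x: x**3):
            _, auc_t = roc_auc(labels, transform(scores))
            assert auc_t == pytest.approx(auc)


class TestKappa:
    def test_worked_example(self):
        # p_o = 0.85, p_e = 0.5 -> kappa = 0.70
        assert cohen_kappa(WORKED_TABLE) == pytest.approx(0.70)

    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionMatrix(10, 0, 10, 0)) == 1.0

    def test_independent_prediction_is_zero(self):
        assert cohen_kappa(ConfusionMatrix(25, 25, 25, 25)) == pytest.approx(0.0)

    def test_degenerate_expected_agreement_is_zero(self):
        assert cohen_kappa(ConfusionMatrix(tp=5, fp=0, tn=0, fn=0)) == 0.0

    def test_formula_matches_permutation_estimate(self):
        # chance agreement estimated by shuffling predictions
        rng = np.random.default_rng(1)
        yt = np.concatenate([np.ones(60, int), np.zeros(40, int)])
        yp = yt.copy()
        yp[rng.choice(100, 25, replace=False)] ^= 1
        c = confusion(yt, yp)
        p_o = (c.tp + c.tn) / c.total
        chance = np.mean(
            [np.mean(rng.permutation(yp) == yt) for _ in range(4000)]
        )
        kappa_mc = (p_o - chance) / (1 - chance)
        assert cohen_kappa(c) == pytest.approx(kappa_mc, abs=0.02)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        tp=st.integers(0, 40), fp=st.integers(0, 40),
        tn=st.integers(0, 40), fn=st.integers(0, 40),
    )
    def test_accuracy_prevalence_identity(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0 or tp + fn == 0 or tn + fp == 0:
            return
        c = ConfusionMatrix(tp, fp, tn, fn)
        accuracy, sensitivity, specificity = basic_rates(c)
        prevalence = (tp + fn) / c.total
        assert accuracy == pytest.approx(
            sensitivity * prevalence + specificity * (1 - prevalence)
        )


class TestMSE:
    def test_worked_example(self):
        assert mse([1, 0], [0.9, 0.2]) == pytest.approx(0.025)

    def test_exact_scores(self):
        assert mse([1, 0, 1], [1.0, 0.0, 1.0]) == 0.0

    def test_uninformative_scores(self):
        assert mse([1, 0], [0.5, 0.5]) == 0.25


class TestEvaluate:
    def test_report_consistent_with_own_confusion(self, hybrid_model, separable_sets):
        _, test = separable_sets
        report = evaluate(hybrid_model, test)
        c = report.confusion
        assert report.accuracy == pytest.approx((c.tp + c.tn) / c.total)
        assert report.kappa == pytest.approx(cohen_kappa(c))
        assert 0.0 <= report.auc <= 1.0 and report.mse >= 0.0

    def test_quality_flags_on_strong_model(self, hybrid_model, separable_sets):
        _, test = separable_sets
        flags = evaluate(hybrid_model, test).quality_flags
        assert flags["auc_ok"] and flags["kappa_ok"]

    def test_cnn_only_backbone_is_evaluable(self, trained_backbone, separable_sets):
        handle, _ = trained_backbone
        _, test = separable_sets
        report = evaluate(handle, test)
        assert 0.0 <= report.accuracy <= 1.0


class TestSegmentCube:
    def test_mask_shape_matches_cube(self, hybrid_model):
        cfg = quick_separable_config(seed=17)
        cube, _ = simulate_cube(cfg, (5, 7), np.zeros((5, 7), int))
        mask = segment_cube(hybrid_model, cube)
        assert mask.shape == (5, 7)
        assert ((mask.scores >= 0) & (mask.scores <= 1)).all()

    def test_all_healthy_cube_mostly_healthy(self, hybrid_model):
        cfg = quick_separable_config(seed=18)
        cube, _ = simulate_cube(cfg, (8, 8), np.zeros((8, 8), int))
        mask = segment_cube(hybrid_model, cube)
        assert mask.labels.mean() <= 0.05
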