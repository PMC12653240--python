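"""Metric arithmetic vs loop-based oracles and sklearn; report aggregation
reproducing the published full-cohort table; ROC/AUC; Grad-CAM behavior."""

import numpy as np
import pytest

from gliomgmt import nn, reference_results as ref
from gliomgmt.evaluation import (BasicMetrics, ConfusionMatrix, basic_metrics,
                                 class_report, confusion, grad_cam,
                                 reconstruct_confusion_from_report,
                                 roc_auc, roc_points, round2)


class TestConfusion:
    def test_perfect_predictions_have_no_errors(self):
        cm = confusion([0, 1, 1, 0], [0, 1, 1, 0])
        assert (cm.fp, cm.fn) == (0, 0)
        assert cm.total == 4

    def test_counts_match_loop_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        cm = confusion(y, p)
        tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
        fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
        fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)

    def test_all_positives_missed(self):
        cm = confusion([1] * 7, [0] * 7)
        assert (cm.tp, cm.fn) == (0, 7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([0, 1], [0])


class TestBasicMetrics:
    def test_published_class0_row_f1(self):
        # precision 0.96, recall 0.89 -> F1 rounds to 0.92
        f1 = 2 * 0.96 * 0.89 / (0.96 + 0.89)
        assert round2(f1) == 0.92

    def test_f1_equals_precision_when_balanced(self):
        m = basic_metrics(ConfusionMatrix(tp=30, tn=50, fp=10, fn=10))
        assert m.precision == m.recall == m.f1

    def test_zero_tp_with_fn_gives_zero_recall_and_f1(self):
        m = basic_metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=3))
        assert (m.recall, m.f1) == (0.0, 0.0)

    def test_exhaustive_small_count_grid_matches_loop_arithmetic(self):
        """All confusion matrices with entries in [0, 5]."""
        for tp in range(6):
            for tn in range(6):
                for fp in range(6):
                    for fn in range(6):
                        total = tp + tn + fp + fn
                        if total == 0:
                            with pytest.raises(ValueError):
                                basic_metrics(ConfusionMatrix(tp, tn, fp, fn))
                            continue
                        m = basic_metrics(ConfusionMatrix(tp, tn, fp, fn))
                        assert m.accuracy == (tp + tn) / total
                        prec = tp / (tp + fp) if tp + fp else 0.0
                        rec = tp / (tp + fn) if tp + fn else 0.0
                        assert m.precision == prec
                        assert m.recall == rec
                        expected_f1 = (2 * prec * rec / (prec + rec)
                                       if prec + rec else 0.0)
                        assert m.f1 == pytest.approx(expected_f1)


class TestClassReport:
    def test_published_macro_f1_from_per_class_f1(self):
        assert round2((0.92 + 0.96) / 2) == 0.94

    def test_published_weighted_f1_from_supports(self):
        w = (438 * 0.92 + 852 * 0.96) / 1290
        assert round2(w) == 0.95

    def test_report_matches_sklearn_on_random_data(self):
        from sklearn.metrics import classification_report

        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 300)
        p = rng.integers(0, 2, 300)
        report = class_report(y, p)
        sk = classification_report(y, p, output_dict=True, zero_division=0)
        for c in (0, 1):
            for key in ("precision", "recall", "f1-score"):
                mine = report.per_class[c][key.replace("-score", "")]
                assert mine == pytest.approx(sk[str(c)][key])
        assert report.accuracy == pytest.approx(sk["accuracy"])
        assert report.macro_avg["f1"] == pytest.approx(sk["macro avg"]["f1-score"])
        assert report.weighted_avg["f1"] == pytest.approx(
            sk["weighted avg"]["f1-score"])

    def test_single_class_input_degenerates_to_that_class(self):
        report = class_report([0, 0, 0], [0, 0, 1])
        assert list(report.per_class) == [0]
        assert report.macro_avg == {k: report.per_class[0][k]
                                    for k in ("precision", "recall", "f1")}

    def test_text_table_prints_published_style_rows(self):
        y = [0, 0, 1, 1]
        p = [0, 1, 1, 1]
        text = class_report(y, p, [0.1, 0.6, 0.8, 0.9]).to_text()
        assert "Macro avg" in text and "Weighted avg" in text
        assert "AUC" in text


class TestRocAuc:
    def test_perfect_separation_scores_one(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_tied_scores_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_pairwise_enumeration_example(self):
        # positives {0.9, 0.4}, negatives {0.6, 0.1}: 3 of 4 pairs won
        assert roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1], [0.2, 0.4])

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_trapezoidal_roc_integration(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 50)
        if len(set(y)) < 2:
            y[0], y[1] = 0, 1
        s = rng.random(50).round(2)    # coarse scores force ties
        pts = roc_points(y, s)
        trapezoid = np.trapezoid(pts[:, 1], pts[:, 0])
        assert roc_auc(y, s) == pytest.approx(trapezoid, abs=1e-12)

    def test_score_negation_complements_auc(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        s = rng.random(40)
        assert roc_auc(y, s) + roc_auc(y, -s) == pytest.approx(1.0)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        s = rng.random(60).round(1)
        assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s))


class TestReconstructConfusion:
    def test_published_recalls_and_supports_imply_diagonal(self):
        cm = reconstruct_confusion_from_report(ref.REPORT_RECALL,
                                               ref.REPORT_SUPPORT)
        assert (cm.tn, cm.tp) == (390, 835)   # diagonal per class
        assert (cm.fp, cm.fn) == (48, 17)

    def test_implied_precisions_match_published_table(self):
        cm = reconstruct_confusion_from_report(ref.REPORT_RECALL,
                                               ref.REPORT_SUPPORT)
        prec0 = cm.tn / (cm.tn + cm.fn)
        prec1 = cm.tp / (cm.tp + cm.fp)
        assert round2(prec0) == ref.REPORT_PRECISION[0]
        assert round2(prec1) == ref.REPORT_PRECISION[1]

    def test_perfect_recall_puts_supports_on_diagonal(self):
        cm = reconstruct_confusion_from_report({0: 1.0, 1: 1.0},
                                               {0: 10, 1: 20})
        assert (cm.tn, cm.tp, cm.fp, cm.fn) == (10, 20, 0, 0)

    def test_negative_implied_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            reconstruct_confusion_from_report({0: 1.5, 1: 0.5}, {0: -4, 1: 4})


class _QuadrantModel:
    """Linear probe whose score depends only on the top-left input quadrant.

    The target layer has two channels: channel 0 carries the top-left
    quadrant's content, channel 1 the rest; the score reads only channel 0,
    so Grad-CAM should weight channel 0 and localize there.
    """

    def __init__(self, size=32):
        self.size = size

    def _activation(self, image):
        x = np.asarray(image, dtype=np.float64).mean(axis=-1)
        h = self.size // 2
        quad = np.zeros_like(x)
        quad[:h, :h] = x[:h, :h]
        rest = x - quad
        return nn.Tensor(np.stack([quad, rest], axis=-1)[None],
                         requires_grad=True)

    def forward_with_activations(self, image):
        act = self._activation(image)
        channel0 = nn.mul(act, nn.Tensor(np.array([1.0, 0.0])))
        return nn.mean(channel0), {"input": act}


class TestGradCam:
    def test_quadrant_sensitive_model_localizes_mass(self):
        rng = np.random.default_rng(7)
        image = rng.random((32, 32, 3)) + 0.5
        hm = grad_cam(_QuadrantModel(), image, target_layer="input")
        mass = hm.values.sum()
        quadrant_mass = hm.values[:16, :16].sum()
        assert quadrant_mass / mass >= 0.90

    def test_all_negative_pre_relu_map_stays_zero(self):
        class NegModel(_QuadrantModel):
            def forward_with_activations(self, image):
                x = nn.Tensor(-np.abs(np.asarray(image, dtype=np.float64))[None])
                score = nn.mean(x)
                return score, {"input": x}

        hm = grad_cam(NegModel(), np.ones((8, 8, 3)), target_layer="input")
        assert hm.values.max() == 0.0

    def test_output_contract_shape_and_range(self):
        from gliomgmt.fusion import BackboneSpec, FusionConfig, build_fusion_model

        model = build_fusion_model(FusionConfig(
            backbones=(BackboneSpec("efficientnet_b0", (4,), 8),
                       BackboneSpec("resnet50", (4,), 8)),
            input_size=32, seed=0))
        hm = grad_cam(model, np.random.default_rng(8).random((32, 32, 3)))
        assert hm.values.shape == (32, 32)
        assert hm.values.min() >= 0.0 and hm.values.max() <= 1.0

    def test_positive_scaling_of_activations_leaves_heatmap_unchanged(self):
        class ScaledModel(_QuadrantModel):
            scale = 1.0

            def forward_with_activations(self, image):
                x = nn.Tensor(np.asarray(image, dtype=np.float64)[None]
                              * self.scale)
                h = self.size // 2
                w = np.zeros((1, self.size, self.size, 3))
                w[0, :h, :h, :] = 1.0
                return nn.mean(nn.mul(x, nn.Tensor(w))), {"input": x}

        rng = np.random.default_rng(9)
        image = rng.random((16, 16, 3))
        m = ScaledModel(size=16)
        base = grad_cam(m, image, target_layer="input").values
        m.scale = 37.5
        scaled = grad_cam(m, image, target_layer="input").values
        np.testing.assert_allclose(scaled, base, atol=1e-10)

    def test_layer_without_spatial_extent_rejected(self):
        class FlatModel:
            def forward_with_activations(self, image):
                x = nn.Tensor(np.asarray(image, dtype=np.float64)[None])
                pooled = nn.global_avg_pool(x)
                return nn.mean(pooled), {"pooled": pooled}

        with pytest.raises(ValueError, match="spatial"):
            grad_cam(FlatModel(), np.ones((8, 8, 3)), target_layer="pooled")
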