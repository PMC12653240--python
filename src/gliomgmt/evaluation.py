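"""Classification evaluation (confusion matrix, accuracy/precision/recall/F1,
ROC-AUC, report aggregation) and Grad-CAM heatmaps.

Conventions, stated once: the positive class is 1 (methylated); rates with a
zero denominator are 0; report values are additionally rendered at two
decimals, rounded half away from zero; AUC is the Mann–Whitney rank
statistic with ties counted 1/2, which equals the trapezoidal area under
the empirical ROC curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .pipeline import SliceStack, resize_plane


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (report formatting)."""
    return float(np.sign(x) * np.floor(abs(x) * 100.0 + 0.5) / 100.0)


@dataclass
class ConfusionMatrix:
    """Binary counts with class 1 (methylated) as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_array(self) -> np.ndarray:
        """2x2 array, rows = true class (0, 1), columns = predicted class."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=int)


def confusion(labels, predictions) -> ConfusionMatrix:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {predictions.shape}")
    bad = set(np.unique(labels)) | set(np.unique(predictions))
    if not bad <= {0, 1}:
        raise ValueError(f"classes must be coded 0/1, got {sorted(bad)}")
    return ConfusionMatrix(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))))


@dataclass
class BasicMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


def basic_metrics(cm: ConfusionMatrix) -> BasicMetrics:
    """Accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 = 2PR/(P+R); zero denominators give 0."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return BasicMetrics(accuracy=(cm.tp + cm.tn) / cm.total,
                        precision=precision, recall=recall, f1=f1)


@dataclass
class ClassReport:
    """Per-class rows plus accuracy, macro and support-weighted aggregates."""

    per_class: dict                      # class -> {precision, recall, f1, support}
    accuracy: float
    macro_avg: dict                      # {precision, recall, f1}
    weighted_avg: dict
    auc: float | None = None

    def rounded(self) -> "ClassReport":
        rc = {c: {k: (v if k == "support" else round2(v)) for k, v in row.items()}
              for c, row in self.per_class.items()}
        return ClassReport(
            per_class=rc, accuracy=round2(self.accuracy),
            macro_avg={k: round2(v) for k, v in self.macro_avg.items()},
            weighted_avg={k: round2(v) for k, v in self.weighted_avg.items()},
            auc=None if self.auc is None else round2(self.auc))

    def to_text(self) -> str:
        r = self.rounded()
        total = sum(row["support"] for row in self.per_class.values())
        lines = [f"{'':<14}{'Precision':>10}{'Recall':>10}{'F1 Score':>10}{'Support':>10}"]
        for c in sorted(r.per_class):
            row = r.per_class[c]
            lines.append(f"{c:<14}{row['precision']:>10.2f}{row['recall']:>10.2f}"
                         f"{row['f1']:>10.2f}{row['support']:>10d}")
        lines.append(f"{'Accuracy':<14}{'':>10}{'':>10}{r.accuracy:>10.2f}{total:>10d}")
        for name, agg in (("Macro avg", r.macro_avg), ("Weighted avg", r.weighted_avg)):
            lines.append(f"{name:<14}{agg['precision']:>10.2f}{agg['recall']:>10.2f}"
                         f"{agg['f1']:>10.2f}{total:>10d}")
        if r.auc is not None:
            lines.append(f"{'AUC':<14}{'':>10}{'':>10}{r.auc:>10.2f}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {"per_class": {str(c): row for c, row in self.per_class.items()},
                   "accuracy": self.accuracy, "macro_avg": self.macro_avg,
                   "weighted_avg": self.weighted_avg, "auc": self.auc}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def class_report(labels, predictions, probabilities=None) -> ClassReport:
    """Two-class report; each class is scored as positive in turn."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    cm = confusion(labels, predictions)  # also validates codes/lengths
    per_class = {}
    for c in sorted(set(labels.tolist())):
        m = basic_metrics(confusion((labels == c).astype(int),
                                    (predictions == c).astype(int)))
        per_class[c] = {"precision": m.precision, "recall": m.recall,
                        "f1": m.f1, "support": int(np.sum(labels == c))}
    total = sum(r["support"] for r in per_class.values())
    macro = {k: float(np.mean([r[k] for r in per_class.values()]))
             for k in ("precision", "recall", "f1")}
    weighted = {k: float(sum(r[k] * r["support"] for r in per_class.values()) / total)
                for k in ("precision", "recall", "f1")}
    auc = None
    if probabilities is not None and len(set(labels.tolist())) == 2:
        auc = roc_auc(labels, probabilities)
    return ClassReport(per_class=per_class,
                       accuracy=float(np.mean(labels == predictions)),
                       macro_avg=macro, weighted_avg=weighted, auc=auc)


def roc_auc(labels, scores) -> float:
    """AUC as the Mann–Whitney statistic (ties 1/2) over (n1 * n0) pairs."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 wins
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(labels, scores) -> np.ndarray:
    """Empirical ROC as (fpr, tpr, threshold) rows, thresholds descending."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    n1 = max(int(np.sum(labels == 1)), 1)
    n0 = max(int(np.sum(labels == 0)), 1)
    rows = []
    for t in thresholds:
        pred = scores >= t
        rows.append((np.sum(pred & (labels == 0)) / n0,
                     np.sum(pred & (labels == 1)) / n1, t))
    return np.asarray(rows)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def reconstruct_confusion_from_report(recalls: dict, supports: dict) -> ConfusionMatrix:
    """Imply the 2x2 matrix from per-class recall and support.

    Per class, correct predictions = round(recall * support); the rest of
    the class's support goes to the other class. Consistency check for
    published reports whose raw confusion matrix is not printed as text.
    """
    if sorted(recalls) != [0, 1] or sorted(supports) != [0, 1]:
        raise ValueError("expected per-class entries for classes 0 and 1")
    correct = {c: _round_half_up(recalls[c] * supports[c]) for c in (0, 1)}
    off = {c: supports[c] - correct[c] for c in (0, 1)}
    if min(min(correct.values()), min(off.values())) < 0:
        raise ValueError("implied confusion counts are negative")
    return ConfusionMatrix(tp=correct[1], tn=correct[0],
                           fp=off[0], fn=off[1])


@dataclass
class Heatmap:
    """Normalized Grad-CAM map aligned with the input's spatial grid."""

    values: np.ndarray
    target_layer: str
    source: tuple = ("", -1)

    def __post_init__(self):
        v = self.values
        if v.min() < 0 or v.max() > 1.0 + 1e-6:
            raise ValueError("heatmap values must lie in [0, 1]")
        if v.max() > 0 and abs(v.max() - 1.0) > 1e-6:
            raise ValueError("nonzero heatmaps must be normalized to max 1")


def grad_cam(model, image, target_layer: str = "all") -> Heatmap:
    """Gradient-weighted class activation map for one input image.

    ``model`` must expose ``forward_with_activations(image) -> (score,
    {layer_name: activation Tensor})`` with NHWC activations. Channel
    weights are the spatial means of d(score)/d(activation); the map is the
    ReLU of the weighted activation sum, bilinearly upsampled to the input
    grid. With ``target_layer='all'`` the per-layer maps are averaged (for
    the fusion classifier: across both backbones). The result is min-max
    normalized to [0, 1]; an identically zero raw map stays zero.
    """
    if isinstance(image, SliceStack):
        source = (image.case_id, image.slice_index)
        image = image.pixels
    else:
        source = ("", -1)
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape[:2]

    score, activations = model.forward_with_activations(image)
    if target_layer != "all":
        if target_layer not in activations:
            raise KeyError(f"unknown layer {target_layer!r}; "
                           f"available: {sorted(activations)}")
        activations = {target_layer: activations[target_layer]}
    for name, act in activations.items():
        if act.data.ndim != 4:
            raise ValueError(f"layer {name!r} has no spatial extent "
                             f"(shape {act.data.shape})")
    score.backward()

    maps = []
    for act in activations.values():
        a = act.data[0]
        g = act.grad[0] if act.grad is not None else np.zeros_like(a)
        weights = g.mean(axis=(0, 1))
        cam = np.maximum((a * weights).sum(axis=-1), 0.0)
        maps.append(resize_plane(cam, (h, w), order=1))
    cam = np.maximum(np.mean(maps, axis=0), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = (cam - cam.min()) / (peak - cam.min()) if peak > cam.min() else cam / peak
    layer_name = target_layer if target_layer != "all" else "+".join(activations)
    return Heatmap(values=cam, target_layer=layer_name, source=source)


def save_heatmap_overlay(heatmap: Heatmap, image: np.ndarray, path) -> None:
    """Write a PNG of the grayscale input with the heatmap overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    base = np.asarray(image, dtype=float)
    if base.ndim == 3:
        base = base.mean(axis=-1)
    ax.imshow(base, cmap="gray")
    ax.imshow(heatmap.values, cmap="jet", alpha=0.4)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
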