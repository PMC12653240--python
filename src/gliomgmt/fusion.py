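"""Dual-backbone feature-fusion classifier for MGMT promoter methylation.

Two convolutional feature extractors process the 3-channel slice in
parallel; each is reduced by global average pooling and the two feature
vectors are concatenated into one fused representation. The fused vector
passes through the fixed classification head — dense 512 (ReLU), dropout
0.3, dense 256 (ReLU), dropout 0.3, dense 1 (sigmoid) — yielding the
probability that the MGMT promoter is methylated. A score > 0.5 predicts
methylated (class 1); a score <= 0.5 predicts unmethylated (class 0).

The extractors mirror the EfficientNetB0 / ResNet50 pairing of the original
design at the interface level: they are compact seeded CNN stand-ins whose
final feature widths default to the stock 1280 and 2048, so the fused
dimension is 3328. No pretrained weights are shipped or downloaded; asking
for ``pretrained=True`` falls back to seeded random initialization with a
warning. Every kept slice inherits its case's MGMT label (per-frame
supervision).
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .framereject import RejectionThreshold, frame_stats, stack_to_gray8
from .pipeline import MRIStudy, SliceStack, make_slice_stack, tumor_slice_indices

HEAD_UNITS = (512, 256)
DROPOUT_RATE = 0.3
STATUS_NAMES = {0: "unmethylated", 1: "methylated"}


@dataclass(frozen=True)
class BackboneSpec:
    """A named stand-in feature extractor.

    ``channels`` are the widths of the 3x3 conv + ReLU + 2x2 max-pool
    blocks; ``feature_width`` is the width of the final 1x1 convolutional
    stage whose global average pool feeds the fusion.
    """

    name: str
    channels: tuple = (16, 32, 64)
    feature_width: int = 256


#: Default pairing; feature widths match the stock backbone definitions so
#: the fused vector is 1280 + 2048 = 3328 wide.
DEFAULT_BACKBONES = (
    BackboneSpec("efficientnet_b0", channels=(16, 24, 40, 80), feature_width=1280),
    BackboneSpec("resnet50", channels=(16, 32, 64, 128), feature_width=2048),
)


@dataclass
class FusionConfig:
    backbones: tuple = DEFAULT_BACKBONES
    input_size: int = 256
    pretrained: bool = False
    freeze_backbones: bool = False
    seed: int = 0

    def validate(self) -> None:
        if len(self.backbones) != 2:
            raise ValueError("exactly two backbones are required")
        for spec in self.backbones:
            if self.input_size % (2 ** len(spec.channels)):
                raise ValueError(
                    f"input_size {self.input_size} incompatible with backbone "
                    f"{spec.name}: needs divisibility by {2 ** len(spec.channels)}")


@dataclass
class TrainConfig:
    """Training protocol: BCE loss, Adam(lr=0.001), batch 32, 20 epochs,
    early stop on validation accuracy (patience 5, restore best), halve the
    learning rate after 3 epochs of validation-loss plateau."""

    loss: str = "bce"
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 20
    early_stop_patience: int = 5
    plateau_patience: int = 3
    plateau_factor: float = 0.5

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "bce":
            raise ValueError("only binary cross-entropy is supported")


@dataclass
class Prediction:
    probability: float
    label: int
    case_id: str = ""
    slice_index: int = -1

    def __post_init__(self):
        expected = 1 if self.probability > 0.5 else 0
        if self.label != expected:
            raise ValueError("label must equal the >0.5 cut of probability")


@dataclass
class StudySummary:
    case_id: str
    mean_probability: float
    label: int             # from mean probability by the >0.5 rule
    majority_label: int    # majority vote over kept slices (tie -> 0)
    n_kept: int
    n_rejected: int


class _Backbone(nn.Module):
    def __init__(self, spec: BackboneSpec, cin: int, rng, dtype=np.float32):
        self.spec = spec
        self.blocks = []
        c = cin
        for width in spec.channels:
            self.blocks.append(nn.Conv2D(c, width, rng=rng, dtype=dtype))
            c = width
        self.final = nn.Conv2D(c, spec.feature_width, k=1, rng=rng, dtype=dtype)

    def parameters(self):
        params = []
        for b in self.blocks:
            params.extend(b.parameters())
        params.extend(self.final.parameters())
        return params

    def forward(self, x):
        h = x
        for conv in self.blocks:
            h = nn.max_pool2(nn.relu(conv(h)))
        feature_map = nn.relu(self.final(h))   # last convolutional stage
        return nn.global_avg_pool(feature_map), feature_map


class FusionModel(nn.Module):
    def __init__(self, cfg: FusionConfig, dtype=np.float32):
        cfg.validate()
        if cfg.pretrained:
            warnings.warn("pretrained weights are unavailable offline; "
                          "falling back to seeded random initialization")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbones = [_Backbone(spec, 3, rng, dtype) for spec in cfg.backbones]
        self.fused_dim = sum(spec.feature_width for spec in cfg.backbones)
        self.fc1 = nn.Dense(self.fused_dim, HEAD_UNITS[0], rng=rng, dtype=dtype)
        self.fc2 = nn.Dense(HEAD_UNITS[0], HEAD_UNITS[1], rng=rng, dtype=dtype)
        self.out = nn.Dense(HEAD_UNITS[1], 1, rng=rng, dtype=dtype)

    def parameters(self):
        params = []
        for b in self.backbones:
            params.extend(b.parameters())
        return params + self.head_parameters()

    def head_parameters(self):
        return (self.fc1.parameters() + self.fc2.parameters()
                + self.out.parameters())

    def trainable_parameters(self):
        if self.cfg.freeze_backbones:
            return self.head_parameters()
        return self.parameters()

    def head_parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.head_parameters()))

    def forward(self, x: "nn.Tensor", train: bool = False, rng=None):
        """Return (probabilities (N,), logits (N,), activations dict)."""
        feats, activations = [], {}
        for backbone in self.backbones:
            pooled, fmap = backbone.forward(x)
            feats.append(pooled)
            activations[backbone.spec.name] = fmap
        fused = nn.concat(feats, axis=-1)
        h = nn.relu(self.fc1(fused))
        h = nn.dropout(h, DROPOUT_RATE, rng, train) if train else h
        h = nn.relu(self.fc2(h))
        h = nn.dropout(h, DROPOUT_RATE, rng, train) if train else h
        logits = nn.reshape(self.out(h), (-1,))
        return nn.sigmoid(logits), logits, activations

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        s = self.cfg.input_size
        if images.shape[1:] != (s, s, 3):
            raise ValueError(f"expected input shape (N, {s}, {s}, 3), "
                             f"got {images.shape}")
        out = []
        for i in range(0, len(images), batch_size):
            probs, _, _ = self.forward(nn.Tensor(images[i:i + batch_size]))
            out.append(probs.data)
        return np.concatenate(out) if out else np.empty(0)

    def forward_with_activations(self, image: np.ndarray):
        """Grad-CAM hook: score Tensor and named conv feature maps for one image."""
        probs, _, activations = self.forward(nn.Tensor(
            np.asarray(image, dtype=np.float32)[None]))
        return nn.mean(probs), activations


def build_fusion_model(cfg: FusionConfig | None = None) -> FusionModel:
    return FusionModel(cfg or FusionConfig())


def head_parameter_count(fused_dim: int) -> int:
    """Closed-form parameter count of the fixed dense head."""
    d1, d2 = HEAD_UNITS
    return fused_dim * d1 + d1 + d1 * d2 + d2 + d2 * 1 + 1


def predict_status(probability: float) -> tuple:
    """Apply the decision rule: > 0.5 -> (1, 'methylated'), else (0, 'unmethylated')."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability {probability} outside [0, 1]")
    label = 1 if probability > 0.5 else 0
    return label, STATUS_NAMES[label]


def _epoch_metrics(tp, tn, fp, fn):
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


def _as_xy(data, input_size):
    if isinstance(data, tuple) and len(data) == 2:
        x, y = data
        return (np.asarray(x, dtype=np.float32),
                np.asarray(y, dtype=np.float32))
    xs, ys = [], []
    for item in data:
        if isinstance(item, SliceStack):
            if item.label is None:
                raise ValueError(f"slice {item.case_id}/{item.slice_index} "
                                 "has no label")
            xs.append(item.pixels)
            ys.append(item.label)
        else:
            xs.append(np.asarray(item[0]))
            ys.append(item[1])
    if not xs:
        return np.empty((0, input_size, input_size, 3), dtype=np.float32), np.empty(0)
    return np.stack(xs).astype(np.float32), np.asarray(ys, dtype=np.float32)


def _eval_loss_and_counts(model, x, y, batch_size):
    losses, counts = [], np.zeros(4)
    for i in range(0, len(x), batch_size):
        probs, logits, _ = model.forward(nn.Tensor(x[i:i + batch_size]))
        losses.append(float(nn.bce_with_logits(logits, y[i:i + batch_size]).data)
                      * len(probs.data))
        pred = probs.data > 0.5
        yy = y[i:i + batch_size] > 0.5
        counts += [np.sum(pred & yy), np.sum(~pred & ~yy),
                   np.sum(pred & ~yy), np.sum(~pred & yy)]
    return sum(losses) / len(x), counts.astype(int)


def train_classifier(train_data, val_data, fcfg: FusionConfig,
                     tcfg: TrainConfig | None = None):
    """Train the fusion classifier; returns (model, history).

    ``history`` is a list of per-epoch dicts with keys epoch, loss, acc,
    precision, recall, f1, val_loss, val_acc, val_precision, val_recall,
    val_f1 and lr. Training metrics accumulate confusion counts at the 0.5
    cut over the epoch's batches; validation metrics are computed after the
    epoch. Early stopping restores the weights of the best-validation-
    accuracy epoch.
    """
    tcfg = tcfg or TrainConfig()
    tcfg.validate()
    x_tr, y_tr = _as_xy(train_data, fcfg.input_size)
    x_va, y_va = _as_xy(val_data, fcfg.input_size)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be nonempty")
    if len(np.unique(y_tr)) < 2:
        warnings.warn("training set contains a single class; proceeding")

    model = build_fusion_model(fcfg)
    opt = nn.Adam(model.trainable_parameters(), lr=tcfg.learning_rate)
    stopper = nn.EarlyStopping(patience=tcfg.early_stop_patience, mode="max")
    scheduler = nn.ReduceLROnPlateau(lr=tcfg.learning_rate,
                                     factor=tcfg.plateau_factor,
                                     patience=tcfg.plateau_patience)
    rng = np.random.default_rng(fcfg.seed + 1)
    history, best_state = [], None
    n = len(x_tr)
    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(n)
        losses, counts = [], np.zeros(4)
        for i in range(0, n, tcfg.batch_size):
            idx = order[i:i + tcfg.batch_size]
            probs, logits, _ = model.forward(nn.Tensor(x_tr[idx]),
                                             train=True, rng=rng)
            loss = nn.bce_with_logits(logits, y_tr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            pred = probs.data > 0.5
            yy = y_tr[idx] > 0.5
            counts += [np.sum(pred & yy), np.sum(~pred & ~yy),
                       np.sum(pred & ~yy), np.sum(~pred & yy)]
        acc, prec, rec, f1 = _epoch_metrics(*counts)
        val_loss, val_counts = _eval_loss_and_counts(model, x_va, y_va,
                                                     tcfg.batch_size)
        val_acc, val_prec, val_rec, val_f1 = _epoch_metrics(*val_counts)
        history.append({"epoch": epoch, "loss": sum(losses) / n, "acc": acc,
                        "precision": prec, "recall": rec, "f1": f1,
                        "val_loss": val_loss, "val_acc": val_acc,
                        "val_precision": val_prec, "val_recall": val_rec,
                        "val_f1": val_f1, "lr": opt.lr})
        if stopper.best is None or val_acc > stopper.best:
            best_state = [a.copy() for a in model.state_arrays()]
        stop = stopper.update(epoch, val_acc)
        opt.lr = scheduler.update(val_loss)
        if stop:
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history


def classify_study(model: FusionModel, study: MRIStudy,
                   rejection_threshold: RejectionThreshold):
    """Slice extraction -> frame rejection -> per-slice prediction.

    Uses the study's tumor mask to pick slices when present, otherwise all
    axial slices. Returns (predictions, summary); the study-level label
    applies the > 0.5 rule to the mean probability over kept slices.
    """
    if study.mask is not None:
        indices = tumor_slice_indices(study)
    else:
        indices = list(range(study.n_slices))
    stacks = [make_slice_stack(study, k, target_size=model.cfg.input_size)
              for k in indices]
    stats = [frame_stats(stack_to_gray8(s.pixels, (s.case_id, s.slice_index)))
             for s in stacks]
    kept = [s for s, st in zip(stacks, stats)
            if st.area_ratio >= rejection_threshold.value]
    if not kept:
        raise ValueError(
            f"study {study.case_id}: every slice was rejected at threshold "
            f"{rejection_threshold.value:.4f}; review the threshold")
    probs = model.predict_proba(np.stack([s.pixels for s in kept]))
    predictions = [Prediction(probability=float(p),
                              label=predict_status(float(p))[0],
                              case_id=s.case_id, slice_index=s.slice_index)
                   for p, s in zip(probs, kept)]
    mean_p = float(np.mean(probs))
    votes = sum(p.label for p in predictions)
    summary = StudySummary(case_id=study.case_id, mean_probability=mean_p,
                           label=predict_status(mean_p)[0],
                           majority_label=1 if votes * 2 > len(predictions) else 0,
                           n_kept=len(kept),
                           n_rejected=len(stacks) - len(kept))
    return predictions, summary


def save_fusion_model(model: FusionModel, path) -> None:
    payload = {"config": model.cfg, "arrays": model.state_arrays(),
               "class": "FusionModel"}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_fusion_model(path) -> FusionModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload["class"] != "FusionModel":
        raise ValueError(f"checkpoint holds a {payload['class']}, not a FusionModel")
    model = FusionModel(payload["config"])
    model.load_state_arrays(payload["arrays"])
    return model
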