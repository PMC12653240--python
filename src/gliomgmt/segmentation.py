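"""2-D U-Net tumor segmentation with Dice/IoU evaluation.

The segmenter is a classic encoder-decoder with skip connections operating
on axial slices. Per encoder level: two 3x3 convolutions (ReLU) then 2x2
max pooling, doubling the filter count each level; the bottleneck applies
two more convolutions; per decoder level: nearest 2x upsampling, a 3x3
"up-convolution" halving the channels, concatenation with the matching
encoder feature map, and two 3x3 convolutions. A final 1x1 convolution with
sigmoid yields the per-pixel tumor probability; masks are cut at 0.5, the
same decision convention the classifier uses.

Both evaluation metrics follow the standard set definitions —
DSC = 2|A∩B| / (|A|+|B|) and IoU = |A∩B| / |A∪B| — with the convention
that two empty masks score 1.0. For any single pair, IoU = DSC/(2-DSC).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .pipeline import MRIStudy, SliceStack, resize_plane

__all__ = ["UNetConfig", "UNet", "SegmentationResult", "SegMetrics",
           "dice_coefficient", "iou", "build_unet", "unet_parameter_count",
           "train_segmenter", "segment_study", "save_model", "load_model"]


def _check_pair(a, b):
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice_coefficient(a, b) -> float:
    """DSC = 2|A∩B| / (|A|+|B|); both masks empty -> 1.0."""
    a, b = _check_pair(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(a, b) -> float:
    """IoU = |A∩B| / |A∪B|; both masks empty -> 1.0."""
    a, b = _check_pair(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class SegMetrics:
    dice: float
    iou: float


@dataclass
class SegmentationResult:
    """Per-slice output: probability map, its 0.5-cut mask, optional reference."""

    prob_map: np.ndarray
    mask: np.ndarray
    reference: np.ndarray | None = None

    def metrics(self) -> SegMetrics:
        if self.reference is None:
            raise ValueError("no reference mask to score against")
        return SegMetrics(dice=dice_coefficient(self.mask, self.reference),
                          iou=iou(self.mask, self.reference))


@dataclass
class UNetConfig:
    depth: int = 4
    base_filters: int = 32
    input_shape: tuple = (256, 256, 3)
    loss: str = "dice_plus_bce"   # 'dice' | 'bce' | 'dice_plus_bce'
    use_skips: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        h, w, _ = self.input_shape
        d = 2 ** self.depth
        if h % d or w % d:
            raise ValueError(
                f"input spatial dims {h}x{w} must be divisible by 2^depth = {d}")
        if self.loss not in ("dice", "bce", "dice_plus_bce"):
            raise ValueError(f"unknown loss {self.loss!r}")


class UNet(nn.Module):
    """Encoder-decoder segmentation network; see module docstring for layout."""

    def __init__(self, cfg: UNetConfig, dtype=np.float32):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f, d, cin = cfg.base_filters, cfg.depth, cfg.input_shape[2]
        self.enc = []
        c = cin
        for i in range(d):
            fi = f * 2 ** i
            self.enc.append([nn.Conv2D(c, fi, rng=rng, dtype=dtype),
                             nn.Conv2D(fi, fi, rng=rng, dtype=dtype)])
            c = fi
        fb = f * 2 ** d
        self.bottleneck = [nn.Conv2D(c, fb, rng=rng, dtype=dtype),
                           nn.Conv2D(fb, fb, rng=rng, dtype=dtype)]
        self.dec = []
        c = fb
        for i in reversed(range(d)):
            fi = f * 2 ** i
            cat = 2 * fi if cfg.use_skips else fi
            self.dec.append([nn.Conv2D(c, fi, rng=rng, dtype=dtype),   # up-conv
                             nn.Conv2D(cat, fi, rng=rng, dtype=dtype),
                             nn.Conv2D(fi, fi, rng=rng, dtype=dtype)])
            c = fi
        self.head = nn.Conv2D(c, 1, k=1, rng=rng, dtype=dtype)

    def parameters(self):
        params = []
        for block in self.enc + [self.bottleneck] + self.dec:
            for layer in block:
                params.extend(layer.parameters())
        params.extend(self.head.parameters())
        return params

    def forward(self, x: "nn.Tensor") -> tuple:
        """Return (probabilities, logits), both (N, H, W, 1)."""
        h = x
        skips = []
        for conv1, conv2 in self.enc:
            h = nn.relu(conv1(h))
            h = nn.relu(conv2(h))
            skips.append(h)
            h = nn.max_pool2(h)
        h = nn.relu(self.bottleneck[0](h))
        h = nn.relu(self.bottleneck[1](h))
        for (up, conv1, conv2), skip in zip(self.dec, reversed(skips)):
            h = nn.upsample2(h)
            h = nn.relu(up(h))
            if self.cfg.use_skips:
                h = nn.concat([skip, h], axis=-1)
            h = nn.relu(conv1(h))
            h = nn.relu(conv2(h))
        logits = self.head(h)
        return nn.sigmoid(logits), logits

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Probability maps (N, H, W) for a float image batch (N, H, W, C)."""
        h, w, cin = self.cfg.input_shape
        images = np.asarray(images, dtype=np.float32)
        if images.shape[1:] != (h, w, cin):
            raise ValueError(f"expected input shape (N, {h}, {w}, {cin}), "
                             f"got {images.shape}")
        probs, _ = self.forward(nn.Tensor(images))
        return probs.data[..., 0]


def build_unet(cfg: UNetConfig) -> UNet:
    return UNet(cfg)


def unet_parameter_count(depth: int, base_filters: int, in_channels: int,
                         use_skips: bool = True) -> int:
    """Closed-form weight count of the architecture defined by :class:`UNet`.

    Counts 3x3 convs as 9*cin*cout + cout and the final 1x1 conv as cout + 1,
    walking the documented layout layer by layer.
    """
    def conv(cin, cout, k=3):
        return k * k * cin * cout + cout

    f, total = base_filters, 0
    c = in_channels
    for i in range(depth):
        fi = f * 2 ** i
        total += conv(c, fi) + conv(fi, fi)
        c = fi
    fb = f * 2 ** depth
    total += conv(c, fb) + conv(fb, fb)
    c = fb
    for i in reversed(range(depth)):
        fi = f * 2 ** i
        cat = 2 * fi if use_skips else fi
        total += conv(c, fi) + conv(cat, fi) + conv(fi, fi)
        c = fi
    total += conv(c, 1, k=1)
    return total


@dataclass
class SegTrainHistory:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    train_dice: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)


def _seg_loss(cfg: UNetConfig, probs, logits, masks):
    if cfg.loss == "bce":
        return nn.bce_with_logits(logits, masks)
    if cfg.loss == "dice":
        return nn.soft_dice_loss(probs, masks)
    return nn.add(nn.bce_with_logits(logits, masks),
                  nn.soft_dice_loss(probs, masks))


def _batch_dice(model: UNet, images: np.ndarray, masks: np.ndarray,
                batch_size: int) -> float:
    scores = []
    for i in range(0, len(images), batch_size):
        pred = model.predict(images[i:i + batch_size]) >= 0.5
        for p, m in zip(pred, masks[i:i + batch_size]):
            scores.append(dice_coefficient(p, m[..., 0]))
    return float(np.mean(scores))


def train_segmenter(train_pairs, val_pairs, cfg: UNetConfig,
                    epochs: int = 10, batch_size: int = 8,
                    lr: float = 1e-3) -> tuple:
    """Train a U-Net on (image, mask) pairs.

    ``train_pairs``/``val_pairs`` are sequences of (SliceStack-or-array,
    binary mask) with spatial shape matching ``cfg.input_shape``. Returns
    (model, history); the metric trajectory is deterministic for a fixed
    ``cfg.seed``.
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training set")

    def to_arrays(pairs):
        imgs = np.stack([p.pixels if isinstance(p, SliceStack) else np.asarray(p)
                         for p, _ in pairs]).astype(np.float32)
        msk = np.stack([np.asarray(m, dtype=np.float32)[..., None] for _, m in pairs])
        return imgs, msk

    x_tr, y_tr = to_arrays(train_pairs)
    x_va, y_va = to_arrays(val_pairs) if len(val_pairs) else (None, None)

    model = build_unet(cfg)
    opt = nn.Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(cfg.seed + 1)
    history = SegTrainHistory()
    n = len(x_tr)
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            xb = nn.Tensor(x_tr[idx])
            probs, logits = model.forward(xb)
            loss = _seg_loss(cfg, probs, logits, y_tr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.train_dice.append(_batch_dice(model, x_tr, y_tr, batch_size))
        if x_va is not None:
            history.val_dice.append(_batch_dice(model, x_va, y_va, batch_size))
    return model, history


def segment_study(model: UNet, study: MRIStudy) -> tuple:
    """Segment every axial slice and assemble the 3-D VOI mask.

    Slices are preprocessed exactly as at training time (per-channel min-max
    normalization + bilinear resize to the model's input size); predicted
    masks are inverse-resized with nearest-neighbor back to the study's
    voxel grid and stacked along the third axis.
    """
    from .pipeline import make_slice_stack  # local import avoids cycle at module load

    h_in, w_in, _ = model.cfg.input_shape
    hh, ww, n_slices = study.shape
    results = []
    voi = np.zeros((hh, ww, n_slices), dtype=np.uint8)
    for k in range(n_slices):
        stack = make_slice_stack(study, k, target_size=h_in)
        prob = model.predict(stack.pixels[None])[0]
        mask = (prob >= 0.5).astype(np.uint8)
        back = (resize_plane(mask.astype(np.float64), (hh, ww), order=0) > 0.5
                ).astype(np.uint8)
        ref = study.mask[:, :, k] if study.mask is not None else None
        results.append(SegmentationResult(prob_map=prob, mask=mask, reference=None
                                          if ref is None else ref))
        voi[:, :, k] = back
    return results, voi


def save_model(model: nn.Module, path) -> None:
    """Persist model weights plus config to ``path``."""
    payload = {"config": getattr(model, "cfg", None),
               "arrays": model.state_arrays(),
               "class": type(model).__name__}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> UNet:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload["class"] != "UNet":
        raise ValueError(f"checkpoint holds a {payload['class']}, not a UNet")
    model = UNet(payload["config"])
    model.load_state_arrays(payload["arrays"])
    return model
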