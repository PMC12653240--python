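"""Empty-frame rejection: largest-component area-ratio statistic with an
automatic dataset-level threshold.

Non-informative (empty or near-empty) axial slices are excluded before
classifier training. Per frame: convert to 8-bit grayscale, threshold with
Otsu's method under both photometric polarities, clean each candidate
foreground with a 3x3 morphological opening then closing, keep the polarity
whose largest 8-connected component is bigger, and record that component's
area as a fraction of the frame area, ``largest_component_area / (H * W)``.
Across the dataset, a threshold on this ratio is found by 1-D 2-means
clustering (midpoint of the two centers); when the clustering is degenerate
a conservative low-quantile fallback is used. Frames with ratio strictly
below the threshold are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

#: structuring element for opening/closing and 8-connectivity labeling
_STRUCT3 = np.ones((3, 3), dtype=bool)

#: 2-means degeneracy guards (center separation, minimum cluster share) and
#: the fallback quantile; surfaced here so they are configurable in one place
MIN_CENTER_SEPARATION = 0.05
MIN_CLUSTER_FRACTION = 0.05
FALLBACK_QUANTILE = 0.05


@dataclass
class Gray8Frame:
    """An 8-bit grayscale frame with provenance (case_id, slice_index)."""

    pixels: np.ndarray
    source: tuple = ("", -1)

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError(f"expected a nonempty 2-D frame, got shape {p.shape}")
        if p.min() < 0 or p.max() > 255:
            raise ValueError("Gray8Frame values must lie in [0, 255]")


@dataclass
class FrameStats:
    """Largest-foreground-component statistics of one frame."""

    largest_component_area: int
    area_ratio: float
    polarity: str
    shape: tuple
    source: tuple = ("", -1)


@dataclass
class RejectionThreshold:
    value: float
    method: str  # 'bimodal' | 'quantile_fallback'
    quantile_used: float | None = None


def to_gray8(frame: np.ndarray, source: tuple = ("", -1)) -> Gray8Frame:
    """Linearly map min -> 0, max -> 255, rounding half away from zero.

    A constant frame has zero dynamic range and maps to all zeros.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not np.isfinite(frame).all():
        raise ValueError("frame contains NaN or Inf pixels")
    lo, hi = frame.min(), frame.max()
    if hi == lo:
        return Gray8Frame(np.zeros(frame.shape, dtype=np.uint8), source)
    scaled = (frame - lo) * (255.0 / (hi - lo))
    return Gray8Frame(np.floor(scaled + 0.5).astype(np.uint8), source)


def stack_to_gray8(pixels: np.ndarray, source: tuple = ("", -1)) -> Gray8Frame:
    """Channel-mean reduction of an (H, W, C) stack, then :func:`to_gray8`."""
    return to_gray8(np.asarray(pixels, dtype=np.float64).mean(axis=-1), source)


def otsu_threshold(frame: Gray8Frame) -> int:
    """Otsu threshold t in [0, 255] over the 256-bin histogram.

    Maximizes the between-class variance of the split (<= t) vs (> t);
    ties are broken toward the smallest t. A single-valued frame returns
    that value (its foreground under either polarity is then empty).
    """
    hist = np.bincount(frame.pixels.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                      # weight of class <= t
    m0 = np.cumsum(hist * levels)             # unnormalized mean of class <= t
    w1 = total - w0
    mu_total = m0[-1]
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return int(frame.pixels.flat[0])
    mu0 = np.where(valid, m0 / np.maximum(w0, 1e-300), 0.0)
    mu1 = np.where(valid, (mu_total - m0) / np.maximum(w1, 1e-300), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(sigma_b))  # argmax takes the first (smallest) maximizer


def _refined_component(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Opening then closing (3x3, one iteration), largest 8-connected area."""
    refined = ndimage.binary_opening(mask, structure=_STRUCT3)
    refined = ndimage.binary_closing(refined, structure=_STRUCT3)
    labeled, n = ndimage.label(refined, structure=_STRUCT3)
    if n == 0:
        return np.zeros_like(mask, dtype=bool), 0
    areas = np.bincount(labeled.ravel())[1:]
    best = int(areas.argmax()) + 1
    return labeled == best, int(areas.max())


def foreground_mask(frame: Gray8Frame) -> tuple[np.ndarray, str]:
    """Select the photometric polarity with the larger refined component.

    Bright-on-dark foreground: pixels > Otsu threshold; dark-on-bright:
    pixels at or below it (the photometric complement, i.e. thresholding
    the inverted frame at the mirrored threshold). The tie goes to
    bright_on_dark (tumor-bright FLAIR prior). A constant frame is
    non-informative and yields an empty foreground under either polarity.
    """
    if frame.pixels.min() == frame.pixels.max():
        return np.zeros(frame.pixels.shape, dtype=bool), "bright_on_dark"
    t = otsu_threshold(frame)
    bright_mask, bright_area = _refined_component(frame.pixels > t)
    dark_mask, dark_area = _refined_component(frame.pixels <= t)
    if dark_area > bright_area:
        return dark_mask, "dark_on_bright"
    return bright_mask, "bright_on_dark"


def frame_stats(frame: Gray8Frame) -> FrameStats:
    mask, polarity = foreground_mask(frame)
    h, w = frame.pixels.shape
    area = int(mask.sum())
    return FrameStats(largest_component_area=area,
                      area_ratio=area / (h * w),
                      polarity=polarity, shape=(h, w), source=frame.source)


def largest_component_area(mask: np.ndarray) -> int:
    """Area of the largest 8-connected component of a binary mask."""
    labeled, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_STRUCT3)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


def auto_threshold(ratios, seed: int = 0) -> RejectionThreshold:
    """Dataset-level threshold from the distribution of area ratios.

    Fits two 1-D k-means centers (10 restarts, seeded) and returns their
    midpoint. Degenerate clusterings — center separation below
    ``MIN_CENTER_SEPARATION`` or either cluster holding less than
    ``MIN_CLUSTER_FRACTION`` of the frames — fall back to the conservative
    ``FALLBACK_QUANTILE`` of the ratios.
    """
    ratios = np.asarray(list(ratios), dtype=np.float64)
    if ratios.size == 0:
        raise ValueError("auto_threshold needs at least one ratio")
    if ratios.size < 2 or np.ptp(ratios) == 0.0:
        return RejectionThreshold(value=float(np.quantile(ratios, FALLBACK_QUANTILE)),
                                  method="quantile_fallback",
                                  quantile_used=FALLBACK_QUANTILE)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assign = km.fit_predict(ratios.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    frac = np.bincount(assign, minlength=2) / ratios.size
    if (centers[1] - centers[0] < MIN_CENTER_SEPARATION
            or frac.min() < MIN_CLUSTER_FRACTION):
        return RejectionThreshold(value=float(np.quantile(ratios, FALLBACK_QUANTILE)),
                                  method="quantile_fallback",
                                  quantile_used=FALLBACK_QUANTILE)
    return RejectionThreshold(value=float(centers.mean()), method="bimodal")


def filter_frames(frames, stats, threshold: RejectionThreshold):
    """Split ``frames`` into (kept, rejected) by the strict < rule.

    ``stats`` holds the per-frame :class:`FrameStats` aligned with ``frames``;
    a frame is rejected iff its area_ratio < threshold.value. Order is
    preserved and kept + rejected partition the input.
    """
    if len(frames) != len(stats):
        raise ValueError("frames and stats must align")
    kept, rejected = [], []
    for f, s in zip(frames, stats):
        (rejected if s.area_ratio < threshold.value else kept).append(f)
    return kept, rejected


@dataclass
class RejectionDiagnostics:
    """Histogram + empirical CDF of area ratios, for the diagnostic plots."""

    bin_edges: np.ndarray          # 51 edges of 50 bins on [0, 1]
    density: np.ndarray            # normalized so the histogram integrates to 1
    sorted_ratios: np.ndarray
    cdf: np.ndarray                # empirical CDF evaluated at sorted_ratios
    threshold: float
    threshold_cdf: float           # fraction of frames with ratio <= threshold


def rejection_diagnostics(ratios, threshold: RejectionThreshold) -> RejectionDiagnostics:
    ratios = np.asarray(list(ratios), dtype=np.float64)
    if ratios.size == 0:
        raise ValueError("rejection_diagnostics needs at least one ratio")
    density, edges = np.histogram(ratios, bins=50, range=(0.0, 1.0), density=True)
    order = np.sort(ratios)
    cdf = np.arange(1, ratios.size + 1) / ratios.size
    threshold_cdf = float(np.searchsorted(order, threshold.value, side="right")
                          / ratios.size)
    return RejectionDiagnostics(bin_edges=edges, density=density,
                                sorted_ratios=order, cdf=cdf,
                                threshold=threshold.value,
                                threshold_cdf=threshold_cdf)
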