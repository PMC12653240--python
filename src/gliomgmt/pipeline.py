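"""Study I/O, tumor-slice extraction, 3-channel slice stacks, and
leakage-free patient-level splits.

The classification input convention follows the training protocol of the
pipeline: for each axial slice intersecting the tumor, the T1-CE, T2 and
FLAIR slices are each min-max normalized to [0, 1], resized to 256 x 256
with bilinear interpolation, and stacked into a 3-channel image (channel
order T1-CE, T2, FLAIR — fixed, and identical at train and test time).
Plain T1 is loaded when present but feeds nothing downstream.

Axial = third array axis; slice indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import LABELS_HEADER

REQUIRED_MODALITIES = ("t1ce", "t2", "flair")
OPTIONAL_MODALITIES = ("t1",)
CHANNEL_ORDER = ("t1ce", "t2", "flair")
DEFAULT_TARGET_SIZE = 256
SUBSETS = ("train", "val", "test")


@dataclass
class MRIStudy:
    """One subject: co-registered modality volumes, optional mask and label."""

    case_id: str
    volumes: dict
    mask: np.ndarray | None = None
    mgmt_label: int | None = None

    def __post_init__(self):
        missing = [m for m in REQUIRED_MODALITIES if m not in self.volumes]
        if missing:
            raise ValueError(
                f"study {self.case_id}: missing required modalities {missing}; "
                f"found {sorted(self.volumes)}")
        shapes = {v.shape for v in self.volumes.values()}
        if self.mask is not None:
            shapes.add(self.mask.shape)
        if len(shapes) != 1:
            raise ValueError(f"study {self.case_id}: inconsistent shapes {shapes}")

    @property
    def shape(self):
        return next(iter(self.volumes.values())).shape

    @property
    def n_slices(self) -> int:
        return self.shape[2]


@dataclass
class SliceStack:
    """One 2-D training sample: (H, W, 3) floats in [0, 1] with provenance."""

    pixels: np.ndarray
    case_id: str
    slice_index: int
    label: int | None = None

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got {p.shape}")
        if p.min() < 0.0 or p.max() > 1.0 + 1e-6:
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass
class SplitAssignment:
    """Patient-level train/val/test assignment."""

    assignment: dict
    fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def subset(self, name: str) -> list:
        return sorted(cid for cid, s in self.assignment.items() if s == name)

    def sizes(self) -> dict:
        return {s: len(self.subset(s)) for s in SUBSETS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.assignment.items()),
                            columns=["case_id", "subset"])


def _find_modality_file(case_dir: Path, case_id: str, mod: str) -> Path | None:
    for suffix in (".nii.gz", ".nii"):
        p = case_dir / f"{case_id}_{mod}{suffix}"
        if p.exists():
            return p
    return None


def read_study(case_dir, mgmt_label: int | None = None) -> MRIStudy:
    """Load a case folder of ``<id>_<modality>.nii[.gz]`` files.

    The folder name is the case ID. A ``<id>_seg`` file, when present, is
    attached as the binary tumor mask.
    """
    case_dir = Path(case_dir)
    if not case_dir.is_dir():
        raise FileNotFoundError(f"case directory not found: {case_dir}")
    case_id = case_dir.name
    volumes, found = {}, []
    for mod in REQUIRED_MODALITIES + OPTIONAL_MODALITIES:
        p = _find_modality_file(case_dir, case_id, mod)
        if p is not None:
            volumes[mod] = np.asarray(nib.load(p).dataobj, dtype=np.float32)
            found.append(mod)
    missing = [m for m in REQUIRED_MODALITIES if m not in volumes]
    if missing:
        raise FileNotFoundError(
            f"case {case_id}: missing modality file(s) {missing}; "
            f"found {found}, expected at least {list(REQUIRED_MODALITIES)}")
    mask = None
    seg_path = _find_modality_file(case_dir, case_id, "seg")
    if seg_path is not None:
        mask = (np.asarray(nib.load(seg_path).dataobj) > 0).astype(np.uint8)
    return MRIStudy(case_id=case_id, volumes=volumes, mask=mask,
                    mgmt_label=mgmt_label)


def load_labels(csv_path) -> dict:
    """Read ``train_labels.csv`` into {5-digit case_id: 0/1}."""
    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path, dtype={LABELS_HEADER[0]: str})
    if list(table.columns) != list(LABELS_HEADER):
        raise ValueError(
            f"{csv_path}: expected header {','.join(LABELS_HEADER)}, "
            f"got {','.join(map(str, table.columns))}")
    labels = {}
    for i, row in enumerate(table.itertuples(index=False), start=2):
        raw_id, value = row
        try:
            value = int(value)
        except (TypeError, ValueError):
            raise ValueError(f"{csv_path}, row {i}: MGMT_value {value!r} is not an integer")
        if value not in (0, 1):
            raise ValueError(f"{csv_path}, row {i}: MGMT_value must be 0 or 1, got {value}")
        cid = str(raw_id).strip().zfill(5)
        if cid in labels:
            raise ValueError(f"{csv_path}, row {i}: duplicate case ID {cid}")
        labels[cid] = value
    return labels


def tumor_slice_indices(study: MRIStudy) -> list:
    """Ascending 0-based indices of axial slices with >= 1 mask pixel."""
    if study.mask is None:
        raise ValueError(
            f"study {study.case_id} has no tumor mask; run segmentation first "
            "or process all slices explicitly")
    return [k for k in range(study.n_slices) if study.mask[:, :, k].any()]


def minmax_normalize(plane: np.ndarray) -> np.ndarray:
    """Min-max map to [0, 1]; a constant plane maps to all zeros."""
    plane = np.asarray(plane, dtype=np.float64)
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


def resize_plane(plane: np.ndarray, target, order: int = 1) -> np.ndarray:
    """Resize a 2-D plane to ``target`` (an int for square output, or (th, tw)).

    Output pixel (i, j) samples input coordinate ((i + 0.5) * H/th - 0.5,
    (j + 0.5) * W/tw - 0.5) — pixel centers, no corner alignment — with
    spline order 1 (bilinear) for images or 0 (nearest) for masks; edges are
    clamped.
    """
    plane = np.asarray(plane, dtype=np.float64)
    h, w = plane.shape
    th, tw = (target, target) if np.isscalar(target) else target
    rows = (np.arange(th) + 0.5) * (h / th) - 0.5
    cols = (np.arange(tw) + 0.5) * (w / tw) - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(plane, [rr, cc], order=order, mode="nearest")


def make_slice_stack(study: MRIStudy, slice_index: int,
                     target_size: int = DEFAULT_TARGET_SIZE) -> SliceStack:
    """Build the 3-channel (T1-CE, T2, FLAIR) normalized slice sample."""
    if not 0 <= slice_index < study.n_slices:
        raise IndexError(f"slice_index {slice_index} out of range "
                         f"[0, {study.n_slices})")
    channels = []
    for mod in CHANNEL_ORDER:
        plane = minmax_normalize(study.volumes[mod][:, :, slice_index])
        plane = resize_plane(plane, target_size, order=1)
        channels.append(np.clip(plane, 0.0, 1.0))
    return SliceStack(pixels=np.stack(channels, axis=-1).astype(np.float32),
                      case_id=study.case_id, slice_index=slice_index,
                      label=study.mgmt_label)


def resize_mask(mask_plane: np.ndarray, target: int) -> np.ndarray:
    """Nearest-neighbor mask resize (preserves binary values)."""
    return (resize_plane(mask_plane.astype(np.float64), target, order=0) > 0.5
            ).astype(np.uint8)


def _largest_remainder(total: int, fractions) -> list:
    """Integer allocation of ``total`` by fractions; remainder ties go to the
    later subset (so 585 at 0.8/0.1/0.1 gives 468/58/59)."""
    ideal = [total * f for f in fractions]
    base = [int(np.floor(x + 1e-9)) for x in ideal]  # guard fp droop on exact seats
    leftover = total - sum(base)
    order = sorted(range(len(fractions)),
                   key=lambda i: (ideal[i] - base[i], i), reverse=True)
    for i in order[:leftover]:
        base[i] += 1
    return base


def split_patients(ids, labels=None, fractions=(0.8, 0.1, 0.1),
                   seed: int = 0) -> SplitAssignment:
    """Stratified patient-level split with largest-remainder rounding.

    Global subset sizes are fixed first by largest-remainder rounding of
    ``len(ids) * fractions``; cases are then allocated class by class, again
    by largest remainder, constrained so the global sizes are met exactly.
    Every slice of a patient inherits the patient's subset, which prevents
    leakage across subsets.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case IDs")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_active = sum(1 for f in fractions if f > 0)
    if len(ids) < n_active:
        raise ValueError(f"need at least {n_active} cases for fractions {fractions}")

    totals = _largest_remainder(len(ids), fractions)
    rng = np.random.default_rng(seed)

    if labels is None:
        classes = {None: ids}
    else:
        classes = {}
        for cid in ids:
            classes.setdefault(labels[cid], []).append(cid)

    # per-class floors, then distribute remaining seats by largest remainder
    # subject to the global column totals
    keys = sorted(classes, key=lambda k: (k is None, k))
    cells = {(c, s): int(np.floor(len(classes[c]) * fractions[s] + 1e-9))
             for c in keys for s in range(3)}
    col_used = [sum(cells[(c, s)] for c in keys) for s in range(3)]
    need = {c: len(classes[c]) - sum(cells[(c, s)] for s in range(3)) for c in keys}
    candidates = sorted(
        ((c, s) for c in keys for s in range(3)),
        key=lambda cs: (len(classes[cs[0]]) * fractions[cs[1]] - cells[cs],
                        cs[1], str(cs[0])),
        reverse=True)
    for c, s in candidates:
        while need[c] > 0 and col_used[s] < totals[s]:
            cells[(c, s)] += 1
            col_used[s] += 1
            need[c] -= 1
            break
    # any seats still unplaced (column capacity hit): put wherever room remains
    for c in keys:
        while need[c] > 0:
            s = next(i for i in (2, 1, 0) if col_used[i] < totals[i])
            cells[(c, s)] += 1
            col_used[s] += 1
            need[c] -= 1

    assignment = {}
    for c in keys:
        members = sorted(classes[c])
        rng.shuffle(members)
        pos = 0
        for s, name in enumerate(SUBSETS):
            for cid in members[pos:pos + cells[(c, s)]]:
                assignment[cid] = name
            pos += cells[(c, s)]
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions),
                           seed=seed)
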