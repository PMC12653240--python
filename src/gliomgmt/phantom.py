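"""Synthetic BraTS-like phantom cohorts with known ground truth.

Each phantom case emulates one subject of the RSNA-MICCAI BraTS-2021 MGMT
cohort: four co-registered 3-D volumes (t1, t1ce, t2, flair) in NIfTI format,
a binary tumor mask, a five-digit case folder, and a ``train_labels.csv``
with columns ``BraTS21ID,MGMT_value`` (0 = not methylated, 1 = methylated).

The anatomy is deliberately simple — an ellipsoidal "brain" containing an
ellipsoidal tumor — but the modality contrasts follow radiological
expectations: the tumor is bright on FLAIR and T2 (edema/water content),
rim-enhanced on T1-CE (blood–brain-barrier breakdown), and slightly
hypointense on plain T1. The methylation label modulates only the *texture
variance* inside the tumor, never its size or shape, so a classifier must
learn appearance (the radiogenomic premise) and segmentation difficulty is
label-independent.

Intensities are in arbitrary units on [0, 1000] before noise; MRI has no
standard intensity scale, and downstream normalization must not assume one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

MODALITIES = ("t1", "t1ce", "t2", "flair")
LABELS_FILENAME = "train_labels.csv"
LABELS_HEADER = ("BraTS21ID", "MGMT_value")

#: Tumor-minus-background intensity offsets, arbitrary units.
DEFAULT_CONTRAST = {
    "t1": -120.0,         # tumor mildly hypointense
    "t1ce": (60.0, 380.0),  # (core, rim): rim enhancement
    "t2": 300.0,          # bright
    "flair": 420.0,       # brightest (edema)
}

#: Background (healthy brain) intensity per modality, arbitrary units.
BRAIN_LEVEL = {"t1": 520.0, "t1ce": 470.0, "t2": 380.0, "flair": 330.0}


@dataclass
class PhantomParams:
    """Geometry, contrast and noise settings for one phantom case.

    Defaults follow the typical BraTS matrix (240 x 240 x 155 voxels); use
    :meth:`desk_scale` for the 64 x 64 x 32 grids used in tests and desk
    experiments.
    """

    volume_shape: tuple = (240, 240, 155)
    brain_axes: tuple = (100.0, 110.0, 65.0)
    tumor_center: tuple = (150, 130, 90)
    tumor_axes: tuple = (22.0, 26.0, 18.0)
    modality_contrast: dict = field(default_factory=lambda: dict(DEFAULT_CONTRAST))
    class_effect: float = 160.0
    noise_sd: float = 30.0
    seed: int = 0

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "PhantomParams":
        """Small grids (64 x 64 x 32) for fast, fully offline experiments."""
        kw = dict(
            volume_shape=(64, 64, 32),
            brain_axes=(27.0, 29.0, 13.0),
            tumor_center=(40, 34, 18),
            tumor_axes=(8.0, 8.0, 6.0),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(a < 0 for a in self.tumor_axes) or any(a < 0 for a in self.brain_axes):
            raise ValueError("semi-axes must be >= 0")
        for ax_name, c, a, n in zip("xyz", self.tumor_center, self.tumor_axes,
                                    self.volume_shape):
            if c - a < 0 or c + a > n - 1:
                raise ValueError(
                    f"tumor extends outside the volume along axis {ax_name}: "
                    f"center {c} +/- {a} exceeds [0, {n - 1}]")
        # conservative containment check: tumor ellipsoid inside brain ellipsoid
        bc = tuple((n - 1) / 2.0 for n in self.volume_shape)
        margin = sum(((abs(c - b) + a) / ba) ** 2
                     for c, b, a, ba in zip(self.tumor_center, bc,
                                            self.tumor_axes, self.brain_axes)
                     if ba > 0)
        if any(ba == 0 for ba in self.brain_axes) or margin > 1.0 + 1e-9:
            raise ValueError("tumor ellipsoid is not contained in the brain ellipsoid")


@dataclass
class PhantomCase:
    """One generated subject: four modality volumes, tumor mask, and label."""

    case_id: str
    volumes: dict
    mask: np.ndarray
    mgmt_label: int

    def __post_init__(self):
        if sorted(self.volumes) != sorted(MODALITIES):
            raise ValueError(f"expected modalities {MODALITIES}, got {sorted(self.volumes)}")
        shapes = {v.shape for v in self.volumes.values()} | {self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent volume/mask shapes: {shapes}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        if len(self.case_id) != 5 or not self.case_id.isdigit():
            raise ValueError(f"case_id must be a 5-digit string, got {self.case_id!r}")
        if self.mgmt_label not in (0, 1):
            raise ValueError("mgmt_label must be 0 or 1")


def _ellipsoid_mask(shape, center, axes) -> np.ndarray:
    if any(a == 0 for a in axes):
        return np.zeros(shape, dtype=np.uint8)
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return (q <= 1.0).astype(np.uint8)


def generate_phantom_case(params: PhantomParams, mgmt_label: int,
                          case_id: str = "00000") -> PhantomCase:
    """Generate one phantom subject; bitwise reproducible from ``params.seed``."""
    params.validate()
    if mgmt_label not in (0, 1):
        raise ValueError("mgmt_label must be 0 or 1")
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.volume_shape)
    center = tuple((n - 1) / 2.0 for n in shape)

    brain = _ellipsoid_mask(shape, center, params.brain_axes).astype(bool)
    tumor = _ellipsoid_mask(shape, params.tumor_center, params.tumor_axes)
    tumor_b = tumor.astype(bool)
    core = _ellipsoid_mask(shape, params.tumor_center,
                           tuple(0.65 * a for a in params.tumor_axes)).astype(bool)
    rim = tumor_b & ~core

    # class-conditional texture: extra zero-mean speckle inside the tumor
    texture = rng.normal(0.0, 1.0, shape)

    volumes = {}
    for mod in MODALITIES:
        vol = np.zeros(shape, dtype=np.float64)
        vol[brain] = BRAIN_LEVEL[mod]
        contrast = params.modality_contrast[mod]
        if isinstance(contrast, tuple):  # (core, rim) pair, used for t1ce
            c_core, c_rim = contrast
            vol[core] += c_core
            vol[rim] += c_rim
        else:
            vol[tumor_b] += contrast
        if mgmt_label == 1 and params.class_effect > 0:
            vol[tumor_b] += params.class_effect * texture[tumor_b]
        vol += rng.normal(0.0, params.noise_sd, shape)
        volumes[mod] = vol.astype(np.float32)

    return PhantomCase(case_id=case_id, volumes=volumes, mask=tumor,
                       mgmt_label=int(mgmt_label))


def write_case(case: PhantomCase, out_dir: Path) -> Path:
    """Write one case folder of gzipped NIfTI files (4 modalities + mask)."""
    case_dir = Path(out_dir) / case.case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for mod, vol in case.volumes.items():
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                 case_dir / f"{case.case_id}_{mod}.nii.gz")
    nib.save(nib.Nifti1Image(case.mask.astype(np.uint8), affine),
             case_dir / f"{case.case_id}_seg.nii.gz")
    return case_dir


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_cohort(n_cases: int, methylated_fraction: float,
                    params: PhantomParams, out_dir) -> pd.DataFrame:
    """Write ``n_cases`` phantom folders plus ``train_labels.csv``.

    Exactly ``round(n_cases * methylated_fraction)`` cases (half-up rounding)
    receive label 1; label order is shuffled by ``params.seed``. Case IDs are
    sequential five-digit strings. Per-case noise fields are seeded from
    ``params.seed`` and the case index, so cohorts are reproducible and cases
    mutually independent.
    """
    if n_cases < 0:
        raise ValueError("n_cases must be >= 0")
    if not 0.0 <= methylated_fraction <= 1.0:
        raise ValueError("methylated_fraction must lie in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_pos = _round_half_up(n_cases * methylated_fraction)
    labels = np.array([1] * n_pos + [0] * (n_cases - n_pos), dtype=int)
    rng = np.random.default_rng(params.seed)
    rng.shuffle(labels)

    rows = []
    for i in range(n_cases):
        case_id = f"{i:05d}"
        case_seed = (params.seed * 100003 + i) % (2 ** 31 - 1)
        case_params = PhantomParams(**{**vars(params), "seed": case_seed})
        case = generate_phantom_case(case_params, int(labels[i]), case_id=case_id)
        write_case(case, out_dir)
        rows.append({"BraTS21ID": case_id, "MGMT_value": int(labels[i])})

    table = pd.DataFrame(rows, columns=list(LABELS_HEADER))
    table.to_csv(out_dir / LABELS_FILENAME, index=False)
    return table
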