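"""Desk-scale recovery experiments on phantom cohorts.

These recipes exercise every pipeline stage end to end at sizes a single
CPU handles in minutes: 64 x 64 x 32 phantom volumes, a reduced-width
U-Net, and reduced-width fusion backbones. They are the package's own
validation experiments: the segmenter must recover the known tumor masks
of held-out phantoms, and the classifier must recover the class-conditional
texture signal above the majority-class rate — and must NOT recover
anything when the labels are shuffled (negative control).
"""

from __future__ import annotations

import numpy as np

from .evaluation import roc_auc
from .framereject import RejectionThreshold
from .fusion import (BackboneSpec, FusionConfig, TrainConfig, classify_study,
                     train_classifier)
from .phantom import PhantomParams, generate_phantom_case
from .pipeline import MRIStudy, make_slice_stack, resize_mask, tumor_slice_indices
from .segmentation import UNetConfig, dice_coefficient, segment_study, train_segmenter

#: reduced-width backbone pair for offline experiments (stock-width pair in
#: fusion.DEFAULT_BACKBONES)
EXPERIMENT_BACKBONES = (
    BackboneSpec("efficientnet_b0", channels=(8, 16), feature_width=32),
    BackboneSpec("resnet50", channels=(8, 16), feature_width=48),
)


def _phantom_study(seed: int, label: int, case_id: str) -> MRIStudy:
    params = PhantomParams.desk_scale(seed=seed % (2 ** 31 - 1))
    case = generate_phantom_case(params, label, case_id=case_id)
    return MRIStudy(case_id=case.case_id, volumes=case.volumes,
                    mask=case.mask, mgmt_label=case.mgmt_label)


def make_phantom_studies(n_cases: int, seed: int, id_offset: int = 0) -> list:
    """Alternating-label in-memory phantom cohort (balanced classes)."""
    return [_phantom_study(seed * 1009 + i, i % 2, f"{id_offset + i:05d}")
            for i in range(n_cases)]


def segmentation_recovery(seed: int = 0, n_cases: int = 20, n_train: int = 16,
                          input_size: int = 64, epochs: int = 8) -> dict:
    """Train a small U-Net on phantom tumor slices; score held-out VOIs.

    Training pairs are every tumor-bearing slice plus every fourth
    background slice (so the model learns to emit empty masks off-tumor).
    Held-out volumes are segmented slice by slice and the assembled VOI is
    scored against the known tumor ellipsoid.
    """
    studies = make_phantom_studies(n_cases, seed)
    train, heldout = studies[:n_train], studies[n_train:]

    pairs = []
    for study in train:
        tumor = set(tumor_slice_indices(study))
        background = [k for k in range(study.n_slices) if k not in tumor][::4]
        for k in sorted(tumor) + background:
            stack = make_slice_stack(study, k, target_size=input_size)
            pairs.append((stack, resize_mask(study.mask[:, :, k], input_size)))

    cfg = UNetConfig(depth=2, base_filters=8,
                     input_shape=(input_size, input_size, 3),
                     loss="dice_plus_bce", seed=seed)
    model, history = train_segmenter(pairs, [], cfg, epochs=epochs, batch_size=8)

    dices = []
    for study in heldout:
        _, voi = segment_study(model, study)
        dices.append(dice_coefficient(voi, study.mask))
    return {"heldout_dice": float(np.mean(dices)),
            "per_case_dice": dices,
            "final_train_dice": history.train_dice[-1],
            "n_train_slices": len(pairs),
            "n_heldout_cases": len(heldout)}


def separable_image_fit(seed: int = 0, n: int = 64, size: int = 32,
                        epochs: int = 20) -> dict:
    """Fit the fusion classifier to class-coded mean-intensity images."""
    rng = np.random.default_rng(seed)
    labels = (np.arange(n) % 2).astype(float)
    images = rng.random((n, size, size, 3)).astype(np.float32) * 0.3
    images[labels == 1] += 0.5
    images = np.clip(images, 0, 1)
    split = int(n * 0.75)
    fcfg = FusionConfig(backbones=EXPERIMENT_BACKBONES, input_size=size,
                        seed=seed)
    _, history = train_classifier((images[:split], labels[:split]),
                                  (images[split:], labels[split:]),
                                  fcfg, TrainConfig(epochs=epochs))
    return {"best_train_accuracy": max(h["acc"] for h in history),
            "epochs_run": len(history), "n_images": n}


def _slices_for(studies, input_size):
    xs, ys = [], []
    for study in studies:
        for k in tumor_slice_indices(study):
            xs.append(make_slice_stack(study, k, target_size=input_size).pixels)
            ys.append(study.mgmt_label)
    return np.stack(xs).astype(np.float32), np.asarray(ys, dtype=float)


def classifier_phantom_recovery(seed: int = 0, n_train_cases: int = 20,
                                n_eval_cases: int = 12, input_size: int = 32,
                                epochs: int = 12,
                                shuffle_labels: bool = False) -> dict:
    """End-to-end methylation recovery from the phantom texture signal.

    Trains on per-frame supervision (every kept slice inherits its case's
    label), then classifies held-out phantom studies generated from fresh
    seeds. With ``shuffle_labels=True`` the training labels are permuted at
    the case level — the negative control that must collapse to the
    majority-class rate.
    """
    train_studies = make_phantom_studies(n_train_cases, seed)
    eval_studies = make_phantom_studies(n_eval_cases, seed + 7919,
                                        id_offset=n_train_cases)

    if shuffle_labels:
        rng = np.random.default_rng(seed + 13)
        perm = rng.permutation([s.mgmt_label for s in train_studies])
        # image content keeps its true texture; only the claimed labels move
        for study, wrong in zip(train_studies, perm):
            study.mgmt_label = int(wrong)

    n_val = max(2, n_train_cases // 5)
    x_tr, y_tr = _slices_for(train_studies[:-n_val], input_size)
    x_va, y_va = _slices_for(train_studies[-n_val:], input_size)

    fcfg = FusionConfig(backbones=EXPERIMENT_BACKBONES, input_size=input_size,
                        seed=seed)
    model, history = train_classifier((x_tr, y_tr), (x_va, y_va), fcfg,
                                      TrainConfig(epochs=epochs))

    threshold = RejectionThreshold(value=0.1, method="fixed")
    correct, labels, mean_probs = 0, [], []
    for study in eval_studies:
        _, summary = classify_study(model, study, threshold)
        correct += summary.label == study.mgmt_label
        labels.append(study.mgmt_label)
        mean_probs.append(summary.mean_probability)
    labels = np.asarray(labels)
    majority = max(np.mean(labels == 0), np.mean(labels == 1))
    auc = roc_auc(labels, mean_probs) if len(set(labels.tolist())) == 2 else None
    return {"study_accuracy": correct / len(eval_studies),
            "majority_rate": float(majority),
            "study_auc": auc,
            "n_eval_cases": len(eval_studies),
            "epochs_run": len(history)}
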