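"""Evaluation: label propagation, Dice/kappa overlap, endpoint error.

Atlas-based segmentation transfer: template (atlas) labels are pushed
through the recovered template→target field with nearest-neighbour
interpolation, then scored per structure against the ground-truth labels
with the kappa-style similarity index

    KI = 2·TP / (2·TP + FN + FP),

algebraically the Dice coefficient 2|G∩E| / (|G| + |E|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ShapeMismatchError
from .grids import DisplacementField, ScalarImage, _sample_coords, image_gradient

__all__ = [
    "LabelImage",
    "propagate_labels",
    "kappa_index",
    "endpoint_error",
    "gradient_mask",
]


@dataclass(frozen=True)
class LabelImage:
    """Nonnegative integer structure labels on a grid; 0 is background."""

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            rounded = np.rint(lab)
            if not np.allclose(lab, rounded):
                raise ValueError("labels must be integers")
            lab = rounded.astype(np.int64)
        if lab.min(initial=0) < 0:
            raise ValueError("labels must be >= 0")
        object.__setattr__(self, "labels", lab.astype(np.int64, copy=False))

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def present_labels(self) -> np.ndarray:
        return np.unique(self.labels)


def propagate_labels(atlas_labels: LabelImage, fld: DisplacementField) -> LabelImage:
    """Warp a label image through ``T = x + u`` with nearest-neighbour
    sampling (linear interpolation of labels is meaningless)."""
    if atlas_labels.shape != fld.shape:
        raise ShapeMismatchError(
            f"labels shape {atlas_labels.shape} != field shape {fld.shape}"
        )
    coords = _sample_coords(atlas_labels.shape, fld)
    out = ndimage.map_coordinates(
        atlas_labels.labels, coords, order=0, mode="nearest"
    )
    return LabelImage(out)


def kappa_index(ground_truth: LabelImage, estimate: LabelImage, label: int) -> float:
    """Dice/kappa overlap of one structure between two label images.

    1.0 means perfect spatial correspondence, 0.0 no overlap.  Raises
    DegenerateInputError when the structure is absent from both images.
    """
    if ground_truth.shape != estimate.shape:
        raise ShapeMismatchError("label images have different shapes")
    g = ground_truth.labels == label
    e = estimate.labels == label
    tp = int(np.count_nonzero(g & e))
    fp = int(np.count_nonzero(~g & e))
    fn = int(np.count_nonzero(g & ~e))
    if tp + fp + fn == 0:
        raise DegenerateInputError(
            f"label {label} absent from both images; KI undefined"
        )
    return 2.0 * tp / (2.0 * tp + fn + fp)


def endpoint_error(
    estimate: DisplacementField, truth: DisplacementField
) -> np.ndarray:
    """Per-point Euclidean distance between two displacement fields (px)."""
    if estimate.shape != truth.shape:
        raise ShapeMismatchError("fields have different grid shapes")
    return np.sqrt(np.sum((estimate.vectors - truth.vectors) ** 2, axis=-1))


def gradient_mask(image: ScalarImage, rel_threshold: float = 0.05) -> np.ndarray:
    """Boolean mask of gradient-bearing points: gradient magnitude above
    ``rel_threshold`` times its maximum.  Flat regions carry no registration
    information, so recovery error is meaningful only inside this mask."""
    gmag = np.sqrt(np.sum(image_gradient(image) ** 2, axis=-1))
    top = gmag.max()
    if top == 0:
        return np.zeros(image.shape, dtype=bool)
    return gmag > rel_threshold * top
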