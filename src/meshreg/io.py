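"""NIfTI reading/writing for images, displacement fields, and labels.

Images are stored as plain scalar NIfTI volumes; displacement fields as
multi-component NIfTI with the vector components on the last axis (a
``(*grid, d)`` data block).  Voxel spacing round-trips through the header
zooms.  All in-memory APIs work on arrays; these helpers only exist at the
filesystem boundary.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .grids import DisplacementField, ScalarImage
from .metrics import LabelImage

__all__ = [
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "read_labels",
    "write_labels",
]


def _load(path) -> tuple:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()
    return data, zooms


def read_image(path) -> ScalarImage:
    """Read a scalar NIfTI image (trailing singleton axes are squeezed)."""
    data, zooms = _load(path)
    data = np.squeeze(data)
    spacing = tuple(float(z) for z in zooms[: data.ndim]) or None
    if spacing and len(spacing) != data.ndim:
        spacing = None
    return ScalarImage(np.asarray(data, dtype=np.float64), spacing=spacing)


def write_image(image: ScalarImage, path) -> None:
    nii = nib.Nifti1Image(image.values, affine=np.eye(4))
    nii.header.set_zooms(image.spacing)
    nib.save(nii, str(path))


def read_field(path) -> DisplacementField:
    """Read a displacement field stored as a (*grid, d) NIfTI block."""
    data, _ = _load(path)
    data = np.squeeze(data)
    d = data.shape[-1]
    if d != data.ndim - 1:
        raise ValueError(
            f"file {path} does not look like a displacement field "
            f"(shape {data.shape}: last axis must hold the {data.ndim - 1} components)"
        )
    return DisplacementField(np.asarray(data, dtype=np.float64))


def write_field(fld: DisplacementField, path) -> None:
    nib.save(nib.Nifti1Image(fld.vectors, affine=np.eye(4)), str(path))


def read_labels(path) -> LabelImage:
    data, _ = _load(path)
    data = np.squeeze(data)
    return LabelImage(np.rint(data).astype(np.int64))


def write_labels(labels: LabelImage, path) -> None:
    nib.save(
        nib.Nifti1Image(labels.labels.astype(np.int32), affine=np.eye(4)), str(path)
    )
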