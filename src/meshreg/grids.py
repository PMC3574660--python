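"""Gridded scalar images, displacement fields, and their discrete operators.

Conventions
-----------
All quantities live on the pixel/voxel grid, indexed 0-based in array
(``ij``) order.  A displacement field ``u`` stores one vector per grid
point, in *grid units*; the transform it encodes is ``T(p) = p + u(p)``.
Warping is a pull-back: the warped image sampled at ``p`` reads the source
image at ``p + u(p)``.  Physical voxel spacing only rescales intensity
gradients; displacements and Jacobians are kept in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ShapeMismatchError

__all__ = [
    "ScalarImage",
    "DisplacementField",
    "JacobianField",
    "warp_image",
    "image_gradient",
    "jacobian_determinants",
    "negative_jacobian_fraction",
    "invert_displacement",
]


@dataclass(frozen=True)
class ScalarImage:
    """A single-channel intensity image on a regular 2-D or 3-D grid.

    Parameters
    ----------
    values : ndarray
        Scalar intensity per grid point; coerced to float64.
    spacing : tuple of float, optional
        Physical size of one grid step per axis.  Defaults to 1.0 per axis.
    """

    values: np.ndarray
    spacing: tuple = field(default=None)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim not in (2, 3):
            raise ValueError(f"ScalarImage must be 2-D or 3-D, got ndim={v.ndim}")
        if any(s < 2 for s in v.shape):
            raise ValueError(f"every image dimension must be >= 2, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("image values must be finite")
        sp = self.spacing
        if sp is None:
            sp = (1.0,) * v.ndim
        sp = tuple(float(s) for s in sp)
        if len(sp) != v.ndim or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be {v.ndim} positive floats, got {sp}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim


@dataclass(frozen=True)
class DisplacementField:
    """Per-grid-point displacement vectors ``u(p)`` in grid units.

    ``vectors`` has shape ``(*grid_shape, d)`` with ``d == len(grid_shape)``.
    The associated spatial transform is ``T(p) = p + u(p)``.
    """

    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim < 2:
            raise ValueError("vectors must have shape (*grid_shape, d)")
        d = v.shape[-1]
        if d != v.ndim - 1:
            raise ValueError(
                f"vector dimensionality {d} does not match grid ndim {v.ndim - 1}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("displacement components must be finite")
        object.__setattr__(self, "vectors", v)

    @property
    def shape(self) -> tuple:
        """Grid shape (without the trailing component axis)."""
        return self.vectors.shape[:-1]

    @property
    def ndim(self) -> int:
        return self.vectors.ndim - 1

    @classmethod
    def zeros(cls, shape) -> "DisplacementField":
        shape = tuple(int(s) for s in shape)
        return cls(np.zeros(shape + (len(shape),)))

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=-1))


@dataclass(frozen=True)
class JacobianField:
    """Per-grid-point determinant of the discrete Jacobian of ``T = x + u``."""

    determinants: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.determinants, dtype=np.float64)
        object.__setattr__(self, "determinants", d)


def _sample_coords(shape, fld: DisplacementField) -> np.ndarray:
    grid = np.indices(shape, dtype=np.float64)
    return grid + np.moveaxis(fld.vectors, -1, 0)


def warp_image(
    image: ScalarImage, fld: DisplacementField, interpolation: str = "linear"
) -> ScalarImage:
    """Resample ``image`` through ``T(p) = p + u(p)`` (pull-back warp).

    Out-of-domain samples clamp to the image border (replicate padding),
    which avoids injecting artificial zero intensities at the boundary.
    """
    if image.shape != fld.shape:
        raise ShapeMismatchError(
            f"image shape {image.shape} != field shape {fld.shape}"
        )
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    coords = _sample_coords(image.shape, fld)
    out = ndimage.map_coordinates(image.values, coords, order=order, mode="nearest")
    return ScalarImage(out, spacing=image.spacing)


def image_gradient(image: ScalarImage) -> np.ndarray:
    """Intensity gradient, central differences interior / one-sided at borders.

    Returns an array of shape ``(*image.shape, ndim)`` in units of intensity
    per grid step (per physical unit when spacing differs from 1).
    """
    grads = np.gradient(image.values, *image.spacing)
    if image.ndim == 1:  # np.gradient returns a bare array in 1-D
        grads = [grads]
    return np.stack(grads, axis=-1)


def jacobian_determinants(fld: DisplacementField) -> JacobianField:
    """Determinant of ``I + du/dp`` at every grid point (pixel units).

    Displacement derivatives use central differences in the interior and
    one-sided differences at the boundary.  The identity and any pure
    translation yield determinant exactly 1.
    """
    d = fld.ndim
    # J[..., i, j] = d u_i / d p_j
    J = np.empty(fld.shape + (d, d))
    for i in range(d):
        comp_grads = np.gradient(fld.vectors[..., i])
        if d == 1:
            comp_grads = [comp_grads]
        for j in range(d):
            J[..., i, j] = comp_grads[j]
    for i in range(d):
        J[..., i, i] += 1.0
    if d == 2:
        det = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    else:
        det = np.linalg.det(J)
    return JacobianField(det)


def negative_jacobian_fraction(jac: JacobianField) -> float:
    """Fraction of grid points with a negative Jacobian determinant (N_J)."""
    det = jac.determinants
    return float(np.count_nonzero(det < 0) / det.size)


def invert_displacement(
    fld: DisplacementField, n_iter: int = 30, tol: float = 1e-9
) -> DisplacementField:
    """Numerical inverse of a (small, smooth) displacement field.

    Solves the fixed point ``v(p) = -u(p + v(p))`` so that composing ``u``
    after ``v`` is (approximately) the identity.  Converges for fields whose
    Jacobian stays positive; used by the synthetic-data generator.
    """
    u = fld.vectors
    v = -u.copy()
    grid = np.indices(fld.shape, dtype=np.float64)
    for _ in range(n_iter):
        coords = grid + np.moveaxis(v, -1, 0)
        u_at = np.stack(
            [
                ndimage.map_coordinates(u[..., c], coords, order=1, mode="nearest")
                for c in range(fld.ndim)
            ],
            axis=-1,
        )
        v_new = -u_at
        step = np.max(np.abs(v_new - v))
        v = v_new
        if step < tol:
            break
    return DisplacementField(v)


def require_same_shape(a, b, what: str = "inputs") -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"{what} have mismatched shapes {a.shape} vs {b.shape}")
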