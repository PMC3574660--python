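"""Synthetic phantoms, smooth ground-truth warps, and registration pairs.

The phantom emulates the geometry that makes intersubject brain registration
hard at desk scale: nested smooth structures (ellipses perturbed by
low-frequency radial harmonics) with distinct intensity levels, standing in
for subcortical anatomy.  Ground-truth warps are Gaussian-smoothed white
noise rescaled to a prescribed peak amplitude; keeping the amplitude at or
below the smoothness scale keeps their Jacobians positive, so "recovered
topology is clean" is a property of the method, not of a broken truth.

All generators are pure functions of their spec (seed-deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

from .errors import ShapeMismatchError
from .grids import DisplacementField, ScalarImage, invert_displacement, warp_image
from .metrics import LabelImage, propagate_labels

__all__ = [
    "PhantomSpec",
    "WarpSpec",
    "RegistrationPair",
    "make_phantom",
    "make_smooth_warp",
    "make_registration_pair",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Nested-structure phantom parameters.

    ``intensity_levels`` gives one intensity per structure, outermost first;
    background is 0.  ``noise_sigma`` is the standard deviation of additive
    Gaussian intensity noise, in the same (arbitrary) intensity units.
    """

    shape: Tuple[int, ...] = (64, 64)
    n_structures: int = 3
    intensity_levels: Tuple[float, ...] = (0.4, 0.7, 1.0)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_structures != len(self.intensity_levels):
            raise ValueError("need one intensity level per structure")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_structures < 1:
            raise ValueError("need at least one structure")


@dataclass(frozen=True)
class WarpSpec:
    """Smooth random-warp parameters (amplitude and smoothness in pixels)."""

    shape: Tuple[int, ...] = (64, 64)
    amplitude_px: float = 3.0
    smoothness_sigma_px: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitude_px < 0 or self.smoothness_sigma_px <= 0:
            raise ValueError("amplitude must be >= 0 and smoothness > 0")
        if self.amplitude_px > self.smoothness_sigma_px:
            raise ValueError(
                "amplitude_px must not exceed smoothness_sigma_px "
                "(guards positive Jacobians of the generated warp)"
            )


@dataclass(frozen=True)
class RegistrationPair:
    """A synthetic registration problem with known answer.

    ``warp(template, truth_field) ≈ target``; ``labels`` segment the target,
    ``template_labels`` the template (the same structures carried through
    the deforming warp).
    """

    template: ScalarImage
    target: ScalarImage
    truth_field: DisplacementField
    labels: LabelImage
    template_labels: LabelImage


def make_phantom(spec: PhantomSpec) -> Tuple[ScalarImage, LabelImage]:
    """Render nested smooth blobs with the given intensity levels.

    Structures are concentric ellipses whose common boundary shape is
    perturbed by low-frequency radial harmonics; structure ``k`` (1-based
    label) occupies the k-th nested region, innermost structures overwrite
    outer ones.  Raises if the innermost structure would not fit the grid.
    """
    shape = tuple(int(s) for s in spec.shape)
    if len(shape) not in (2, 3):
        raise ValueError("phantoms are 2-D or 3-D")
    rng = np.random.default_rng(spec.seed)
    half = np.array(shape) / 2.0
    center = half + rng.uniform(-0.04, 0.04, size=len(shape)) * np.array(shape)
    semi_axes = np.array(shape) * rng.uniform(0.33, 0.40, size=len(shape))

    coords = np.indices(shape, dtype=np.float64)
    delta = coords - center.reshape(-1, *([1] * len(shape)))
    rho = np.sqrt(np.sum((delta / semi_axes.reshape(-1, *([1] * len(shape)))) ** 2, axis=0))

    # Low-frequency radial perturbation shared by all nested boundaries.
    theta = np.arctan2(delta[1], delta[0])
    bump = np.zeros(shape)
    for m in (2, 3, 4):
        amp = rng.uniform(0.02, 0.06)
        phase = rng.uniform(0, 2 * np.pi)
        bump += amp * np.cos(m * theta + phase)
    boundary = 1.0 + bump

    n = spec.n_structures
    scales = np.array([1.0 - 0.62 * k / n for k in range(n)])
    inner_px = scales[-1] * (1.0 - 0.06) * semi_axes.min()
    if inner_px < 2.0:
        raise ValueError(
            f"innermost structure would span {inner_px:.1f} px (< 2 px); "
            "reduce n_structures or enlarge the grid"
        )

    labels = np.zeros(shape, dtype=np.int64)
    values = np.zeros(shape)
    for k, (scale, level) in enumerate(zip(scales, spec.intensity_levels), start=1):
        inside = rho <= scale * boundary
        labels[inside] = k
        values[inside] = level
    if spec.noise_sigma > 0:
        values = values + rng.normal(0.0, spec.noise_sigma, size=shape)
    return ScalarImage(values), LabelImage(labels)


def make_smooth_warp(spec: WarpSpec) -> DisplacementField:
    """Gaussian-smoothed white-noise vector field rescaled so that its peak
    magnitude equals ``amplitude_px`` exactly (zero field for amplitude 0)."""
    shape = tuple(int(s) for s in spec.shape)
    d = len(shape)
    if spec.amplitude_px == 0.0:
        return DisplacementField.zeros(shape)
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(size=shape + (d,))
    smooth = np.stack(
        [
            ndimage.gaussian_filter(noise[..., c], sigma=spec.smoothness_sigma_px)
            for c in range(d)
        ],
        axis=-1,
    )
    mag = np.sqrt(np.sum(smooth**2, axis=-1))
    peak = mag.max()
    if peak == 0.0:  # pathological but possible at float precision
        return DisplacementField.zeros(shape)
    return DisplacementField(smooth * (spec.amplitude_px / peak))


def make_registration_pair(
    phantom_spec: PhantomSpec, warp_spec: WarpSpec
) -> RegistrationPair:
    """Build (template, target, truth, labels) with a known smooth warp.

    The target is the phantom; the template is the target pulled back
    through a generated smooth field ``w``.  The returned ``truth_field`` is
    the numerical inverse of ``w``, i.e. exactly the field a registration of
    template onto target should recover: ``warp(template, truth) ≈ target``.
    """
    if tuple(phantom_spec.shape) != tuple(warp_spec.shape):
        raise ShapeMismatchError("phantom and warp specs disagree on shape")
    target, labels = make_phantom(phantom_spec)
    w = make_smooth_warp(warp_spec)
    template = warp_image(target, w, interpolation="linear")
    template_labels = propagate_labels(labels, w)
    truth = (
        invert_displacement(w)
        if warp_spec.amplitude_px > 0
        else DisplacementField.zeros(warp_spec.shape)
    )
    return RegistrationPair(template, target, truth, labels, template_labels)
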