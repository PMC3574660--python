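"""Similarity measures and the optical-flow (demons-style) force.

The force is the intensity-conservation velocity

    v(p) = (A∘T(p) − B(p)) ∇B(p) / (||∇B(p)||² + (A∘T(p) − B(p))²)

whose renormalized denominator bounds ``||v|| <= 1/2`` pointwise (AM–GM),
keeping single-step updates within the small-motion regime.  The
displacement increment actually applied to the template is ``-v``; the
registration driver owns that sign.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import List
import warnings

import numpy as np

from .errors import DegenerateInputError
from .grids import DisplacementField, ScalarImage, image_gradient, require_same_shape

__all__ = [
    "SimilarityTrace",
    "ssd",
    "cross_correlation",
    "optical_flow_velocity",
    "histogram_match",
]


@dataclass
class SimilarityTrace:
    """Per-iteration similarity log (SSD and cross-correlation)."""

    ssd_values: List[float] = field(default_factory=list)
    cc_values: List[float] = field(default_factory=list)

    def append(self, ssd_value: float, cc_value: float) -> None:
        self.ssd_values.append(float(ssd_value))
        self.cc_values.append(float(cc_value))

    def __len__(self) -> int:
        return len(self.ssd_values)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "ssd", "cc"])
            for i, (s, c) in enumerate(zip(self.ssd_values, self.cc_values)):
                w.writerow([i, s, c])


def ssd(a: ScalarImage, b: ScalarImage) -> float:
    """Sum of squared intensity differences over the whole domain."""
    require_same_shape(a, b, "images")
    return float(np.sum((a.values - b.values) ** 2))


def cross_correlation(a: ScalarImage, b: ScalarImage) -> float:
    """Pearson cross-correlation factor of the two intensity vectors.

    Bounded in [-1, 1]; equals 1 at maximum similarity.  Raises
    DegenerateInputError when either image is constant (zero variance).
    """
    require_same_shape(a, b, "images")
    x = a.values.ravel()
    y = b.values.ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError(
            "cross-correlation undefined for constant image(s)"
        )
    cc = float(np.dot(xc, yc) / (sx * sy))
    return float(np.clip(cc, -1.0, 1.0))


def optical_flow_velocity(
    deformed_template: ScalarImage,
    target: ScalarImage,
    renormalized: bool = True,
) -> DisplacementField:
    """Per-point optical-flow velocity of the deformed template w.r.t. target.

    With ``renormalized`` (the default) the denominator is
    ``||∇B||² + d²`` with ``d = A∘T − B``, otherwise just ``||∇B||²``.
    Points where the denominator vanishes get velocity 0 (the unique
    continuous extension).  The displacement increment for the template is
    ``u = -v``.
    """
    require_same_shape(deformed_template, target, "images")
    d = deformed_template.values - target.values
    g = image_gradient(target)
    g2 = np.sum(g**2, axis=-1)
    denom = g2 + d**2 if renormalized else g2
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), 0.0)
    v = g * scale[..., None]
    return DisplacementField(v)


def histogram_match(
    source: ScalarImage, reference: ScalarImage, n_quantiles: int = 256
) -> ScalarImage:
    """Monotone intensity remapping of ``source`` onto ``reference`` quantiles.

    Quantile mapping with linear interpolation between ``n_quantiles``
    equally spaced quantiles.  A constant source carries no rankable
    information and is mapped to the reference median (with a warning).
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    src = source.values
    ref = reference.values
    if src.max() == src.min():
        warnings.warn(
            "histogram_match: constant source image mapped to reference median",
            stacklevel=2,
        )
        out = np.full_like(src, float(np.median(ref)))
        return ScalarImage(out, spacing=source.spacing)
    q = np.linspace(0.0, 1.0, n_quantiles)
    src_q = np.quantile(src, q)
    ref_q = np.quantile(ref, q)
    out = np.interp(src, src_q, ref_q)
    return ScalarImage(out, spacing=source.spacing)
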