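"""The mesh-deformation-constrained registration driver.

Alternating minimisation of SSD similarity plus a spring-mesh
regularization energy: each iteration (a) warps the template with the
current field, (b) adds the negated renormalized optical-flow velocity to
the field, (c) smooths the field with a few Jacobi spring-relaxation sweeps.
A multiresolution pyramid (factor-2 downsampling, coarse→fine) avoids local
minima; after the finest scale any residual negative-Jacobian points are
removed by extra relaxation sweeps; if the cross-correlation stopping
criterion is not met, the template is re-warped through the current
transform and the whole pass repeats (template updating), composing fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .errors import ShapeMismatchError
from .grids import (
    DisplacementField,
    ScalarImage,
    jacobian_determinants,
    negative_jacobian_fraction,
    warp_image,
)
from .mesh import SpringMesh, build_mesh, spring_relax
from .similarity import (
    SimilarityTrace,
    cross_correlation,
    histogram_match,
    optical_flow_velocity,
    ssd,
)

__all__ = [
    "RegistrationConfig",
    "ScaleLog",
    "RegistrationReport",
    "build_pyramid",
    "cc_threshold",
    "register_one_scale",
    "register",
    "compose_or_accumulate",
]


@dataclass(frozen=True)
class RegistrationConfig:
    """All tunables of the registration driver.

    Defaults follow the method's reference settings: resampling factor 2,
    ten iterations per scale, three relaxation sweeps per iteration, α=1.2
    in the cross-correlation stopping rule, at most three template updates.
    """

    resample_factor: int = 2
    min_coarse_dim: int = 32
    iters_per_scale: int = 10
    relax_iters: int = 3
    alpha: float = 1.2
    max_template_updates: int = 3
    cc_rule: str = "literal_clamped"
    renormalized_force: bool = True
    seed: int = 0
    #: relative SSD decrease below which a scale is considered converged
    ssd_rtol: float = 1e-4
    #: sweeps per post-hoc Jacobian-correction round (method uses 3–5)
    posthoc_relax_iters: int = 3
    posthoc_max_rounds: int = 3
    n_quantiles: int = 256

    def __post_init__(self):
        if self.resample_factor < 2:
            raise ValueError("resample_factor must be >= 2")
        if self.iters_per_scale < 1:
            raise ValueError("iters_per_scale must be >= 1")
        if not 1 <= self.relax_iters <= 10:
            raise ValueError("relax_iters must be in [1, 10]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.cc_rule not in ("literal_clamped", "fractional_gap"):
            raise ValueError("cc_rule must be 'literal_clamped' or 'fractional_gap'")
        if self.max_template_updates < 0:
            raise ValueError("max_template_updates must be >= 0")

    def to_dict(self) -> dict:
        return {
            "resample_factor": self.resample_factor,
            "min_coarse_dim": self.min_coarse_dim,
            "iters_per_scale": self.iters_per_scale,
            "relax_iters": self.relax_iters,
            "alpha": self.alpha,
            "max_template_updates": self.max_template_updates,
            "cc_rule": self.cc_rule,
            "renormalized_force": self.renormalized_force,
            "seed": self.seed,
            "ssd_rtol": self.ssd_rtol,
            "posthoc_relax_iters": self.posthoc_relax_iters,
            "posthoc_max_rounds": self.posthoc_max_rounds,
            "n_quantiles": self.n_quantiles,
        }


@dataclass
class ScaleLog:
    """Per-scale similarity trace (one entry per accepted iteration)."""

    pass_index: int
    shape: tuple
    ssd_values: List[float] = dc_field(default_factory=list)
    cc_values: List[float] = dc_field(default_factory=list)


@dataclass
class RegistrationReport:
    """Everything `register` produces besides side effects."""

    final_field: DisplacementField
    deformed_template: ScalarImage
    trace: SimilarityTrace
    per_scale: List[ScaleLog]
    nj_final: float
    n_template_updates: int
    scales_used: int
    cc_initial: float
    cc_final: float
    cc_stop_threshold: float
    converged: bool


def build_pyramid(image: ScalarImage, config: RegistrationConfig) -> List[ScalarImage]:
    """Gaussian smooth + downsample repeatedly; list ordered coarse→fine.

    Downsampling by ``resample_factor`` stops before any dimension would
    fall below ``min_coarse_dim``; the finest level is the original image.
    """
    factor = config.resample_factor
    levels = [image]
    while True:
        cur = levels[-1]
        next_shape = tuple(int(round(s / factor)) for s in cur.shape)
        if any(s < config.min_coarse_dim for s in next_shape):
            break
        smoothed = ndimage.gaussian_filter(cur.values, sigma=0.5 * factor)
        down = ndimage.zoom(smoothed, [n / s for n, s in zip(next_shape, cur.shape)], order=1)
        assert down.shape == next_shape
        levels.append(ScalarImage(down, spacing=cur.spacing))
    return levels[::-1]


def cc_threshold(cc0: float, alpha: float, rule: str = "literal_clamped") -> float:
    """Stopping threshold CC_t from the initial cross-correlation CC_0.

    ``literal_clamped``: CC_t = (1-CC_0)·α + CC_0, clamped at 0.999 (for
    α > 1 the raw value exceeds 1 whenever CC_0 < 1, which would make the
    criterion unreachable).  ``fractional_gap``: CC_0 + (1-CC_0)/α, the
    variant that closes a 1/α fraction of the remaining similarity gap.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if rule == "literal_clamped":
        return min((1.0 - cc0) * alpha + cc0, 0.999)
    if rule == "fractional_gap":
        return cc0 + (1.0 - cc0) / alpha
    raise ValueError(f"unknown cc rule {rule!r}")


def register_one_scale(
    template: ScalarImage,
    target: ScalarImage,
    init_field: DisplacementField,
    mesh: SpringMesh,
    config: RegistrationConfig,
    log: Optional[ScaleLog] = None,
) -> DisplacementField:
    """Alternating force/relaxation iterations at a single scale.

    Per iteration: warp template with the current field, add the negated
    optical-flow velocity, then ``relax_iters`` spring sweeps.  Stops at
    ``iters_per_scale`` iterations or when the relative SSD decrease drops
    below ``ssd_rtol``; an SSD increase reverts the step and stops (keeps
    the per-scale trace non-increasing).
    """
    if template.shape != target.shape or template.shape != init_field.shape:
        raise ShapeMismatchError("template/target/init_field shapes disagree")
    u = init_field
    prev_ssd = ssd(warp_image(template, u), target)
    for _ in range(config.iters_per_scale):
        warped = warp_image(template, u)
        v = optical_flow_velocity(warped, target, renormalized=config.renormalized_force)
        rough = DisplacementField(u.vectors - v.vectors)
        u_new = spring_relax(rough, mesh, n_iter=config.relax_iters)
        if not np.all(np.isfinite(u_new.vectors)):
            raise FloatingPointError("non-finite displacement during registration")
        warped_new = warp_image(template, u_new)
        cur_ssd = ssd(warped_new, target)
        if cur_ssd > prev_ssd:
            break  # step rejected: keep previous field
        u = u_new
        if log is not None:
            try:
                cc = cross_correlation(warped_new, target)
            except Exception:
                cc = 1.0  # constant images: already identical up to offset
            log.ssd_values.append(cur_ssd)
            log.cc_values.append(cc)
        if cur_ssd == 0.0 or (
            prev_ssd > 0 and (prev_ssd - cur_ssd) / prev_ssd < config.ssd_rtol
        ):
            prev_ssd = cur_ssd
            break
        prev_ssd = cur_ssd
    return u


def compose_or_accumulate(
    field_outer: DisplacementField, field_inner: DisplacementField
) -> DisplacementField:
    """Compose two pull-back displacement fields.

    ``u_total(p) = u_outer(p) + u_inner(p + u_outer(p))`` with linear
    interpolation of the inner field, so warping by the result equals
    warping by ``inner`` then by ``outer``.
    """
    if field_outer.shape != field_inner.shape:
        raise ShapeMismatchError("fields have different grid shapes")
    grid = np.indices(field_outer.shape, dtype=np.float64)
    coords = grid + np.moveaxis(field_outer.vectors, -1, 0)
    inner_at = np.stack(
        [
            ndimage.map_coordinates(
                field_inner.vectors[..., c], coords, order=1, mode="nearest"
            )
            for c in range(field_inner.ndim)
        ],
        axis=-1,
    )
    return DisplacementField(field_outer.vectors + inner_at)


def _upsample_field(
    fld: DisplacementField, fine_shape: tuple, factor: int
) -> DisplacementField:
    """Transfer a field to the next finer level: interpolate linearly and
    scale vectors by the resampling factor."""
    zooms = [f / c for f, c in zip(fine_shape, fld.shape)]
    comps = [
        ndimage.zoom(fld.vectors[..., c], zooms, order=1, mode="nearest")
        for c in range(fld.ndim)
    ]
    up = np.stack(comps, axis=-1) * float(factor)
    assert up.shape[:-1] == tuple(fine_shape)
    return DisplacementField(up)


def register(
    template: ScalarImage, target: ScalarImage, config: RegistrationConfig = None
) -> RegistrationReport:
    """Full registration of ``template`` onto ``target``.

    Pipeline: histogram-match the template to the target once, build
    pyramids, run the alternating minimisation coarse→fine, correct any
    residual negative-Jacobian points with extra relaxation sweeps, and —
    while the cross-correlation stays below the stopping threshold and
    template updates remain — re-warp the template through the current
    transform and repeat the whole pass, composing the fields.

    Inputs are assumed spatially pre-aligned (rigid/affine normalisation is
    upstream of this tool).  Never raises on non-convergence: the report
    carries a ``converged`` flag.
    """
    if config is None:
        config = RegistrationConfig()
    if template.shape != target.shape:
        raise ShapeMismatchError("template and target must share a grid")

    matched = histogram_match(template, target, n_quantiles=config.n_quantiles)
    cc0 = cross_correlation(matched, target)
    cc_stop = cc_threshold(cc0, config.alpha, config.cc_rule)

    pyr_target = build_pyramid(target, config)
    meshes = {}  # one mesh per level shape, reused across passes

    total = DisplacementField.zeros(target.shape)
    full_mesh = build_mesh(target.shape)
    per_scale: List[ScaleLog] = []
    n_updates = 0
    current_template = matched

    while True:
        pyr_template = build_pyramid(current_template, config)
        fld = DisplacementField.zeros(pyr_target[0].shape)
        for lvl, (tpl, tgt) in enumerate(zip(pyr_template, pyr_target)):
            if lvl > 0:
                fld = _upsample_field(fld, tgt.shape, config.resample_factor)
            if tgt.shape not in meshes:
                meshes[tgt.shape] = build_mesh(tgt.shape)
            log = ScaleLog(pass_index=n_updates, shape=tgt.shape)
            fld = register_one_scale(tpl, tgt, fld, meshes[tgt.shape], config, log)
            per_scale.append(log)

        total = compose_or_accumulate(fld, total)

        # Post-hoc topology correction: extra relaxation while folds remain.
        rounds = 0
        while (
            negative_jacobian_fraction(jacobian_determinants(total)) > 0
            and rounds < config.posthoc_max_rounds
        ):
            total = spring_relax(total, full_mesh, n_iter=config.posthoc_relax_iters)
            rounds += 1

        deformed = warp_image(matched, total)
        cc_final = cross_correlation(deformed, target)
        if cc_final >= cc_stop or n_updates >= config.max_template_updates:
            break
        n_updates += 1
        current_template = warp_image(matched, total)

    nj_final = negative_jacobian_fraction(jacobian_determinants(total))
    trace = SimilarityTrace()
    for log in per_scale:
        for s, c in zip(log.ssd_values, log.cc_values):
            trace.append(s, c)
    if len(trace) == 0:  # zero-iteration edge case: record the final state
        trace.append(ssd(deformed, target), cc_final)
    return RegistrationReport(
        final_field=total,
        deformed_template=deformed,
        trace=trace,
        per_scale=per_scale,
        nj_final=nj_final,
        n_template_updates=n_updates,
        scales_used=len(pyr_target),
        cc_initial=cc0,
        cc_final=cc_final,
        cc_stop_threshold=cc_stop,
        converged=bool(cc_final >= cc_stop),
    )
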