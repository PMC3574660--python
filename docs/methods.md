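# Methods

## Model

Registration seeks the displacement field `u` minimising

    E(u) = Σ_p (B(p) − A(p + u(p)))²  +  Σ_p | Σ_{j∈n_v} k_ij (u_j − u_i) |

where `A` is the template, `B` the target, and the second term is the
spring-mesh regularization energy: the magnitude of the net Hooke force at
every mesh vertex. The two terms are minimised alternately rather than
jointly — a similarity half-step followed by a regularization half-step —
because each partial minimisation is cheap and the alternation converges in
practice.

**Similarity half-step.** The intensity-conservation (optical-flow)
velocity, in its renormalized form

    v(p) = d(p) ∇B(p) / (‖∇B(p)‖² + d(p)²),    d = A∘T − B,

is subtracted from the field (`u ← u − v`). By the AM–GM inequality
`‖v‖ ≤ ½` everywhere, so a single step never moves a point by more than
half a pixel — the small-motion regime the velocity derivation assumes.
Where both `∇B` and `d` vanish the velocity is set to 0, the unique
continuous extension. Gradients are central differences in the interior and
one-sided at the boundary.

**Regularization half-step.** One vertex per pixel; 2-D cells are split
into two triangles along the fixed `(i,j)→(i+1,j+1)` diagonal (interior
degree 6); in 3-D the edge set is the 6-connected axis graph plus three
fixed-orientation face diagonals per cell. Edge stiffness is the Batina
rule `k_ij = 1/|x_j − x_i|`: shrinking edges stiffen sharply, which is what
suppresses vertex collision and with it folds, crossings and tears. Each
Jacobi sweep simultaneously replaces every vertex displacement with the
stiffness-weighted neighbour average; by default the stiffness is
recomputed before each sweep from the moved positions `x⁰ + uⁿ` (the
spring lengths the deformed mesh actually has). A frozen-stiffness mode
exists, under which the sweep is the exact Jacobi iteration for the linear
equilibrium system — that mode is what the direct-solve oracle tests use,
and each frozen sweep is a per-vertex convex combination, so component
min/max bounds can never expand (discrete maximum principle).

**Driver.** Images enter spatially pre-aligned (rigid/affine normalisation
is upstream of this tool). The template is histogram-matched to the target
once, up front (quantile mapping, 256 quantiles). Both images are
decomposed into a factor-2 Gaussian pyramid (anti-aliasing σ = 0.5·factor)
down to a 32-px floor; registration runs coarse→fine, multiplying field
vectors by the resampling factor and interpolating linearly between levels.
Within a scale, up to 10 iterations run; a relative SSD decrease below 1e−4
stops the scale, and an SSD increase reverts the step and stops — this step
acceptance makes per-scale SSD traces non-increasing by construction. After
the finest scale, if any Jacobian determinant of the accumulated field is
negative, 3 extra relaxation sweeps are applied (up to 3 rounds). If the
cross-correlation of the deformed template still falls short of the
stopping threshold and updates remain (max 3), the template is re-warped
through the current transform and the whole pass repeats; passes are
combined by true composition `u_total(p) = u_new(p) + u_old(p + u_new(p))`,
not addition — naive addition would break exactly the topology guarantee
the mesh exists to provide.

**Stopping threshold.** The rule `CC_t = (1 − CC_0)·α + CC_0` with the
reference α = 1.2 exceeds 1 for any `CC_0 < 1`, so taken literally the
criterion is unreachable; the default clamps it at 0.999 (in effect:
"register until essentially perfect or until updates are exhausted"). A
`fractional_gap` variant `CC_0 + (1 − CC_0)/α` — closing a 1/α fraction of
the remaining similarity gap — is provided as the likely intended reading.
Neither is asserted as canonical; both are config options.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `resample_factor` | 2 | pyramid down/upsampling factor |
| `min_coarse_dim` | 32 px | smallest admissible coarse-level dimension |
| `iters_per_scale` | 10 | force/relax iterations per pyramid level |
| `relax_iters` | 3 | Jacobi sweeps per iteration (reference range 3–5) |
| `alpha` | 1.2 | stopping-threshold parameter |
| `max_template_updates` | 3 | re-registration passes with re-warped template |
| `cc_rule` | `literal_clamped` | threshold rule (see above) |
| `renormalized_force` | on | use the bounded-denominator velocity |
| `posthoc_relax_iters` / `posthoc_max_rounds` | 3 / 3 | fold-correction sweeps after the finest scale |
| `n_quantiles` | 256 | histogram-matching resolution |

Displacements are in grid units throughout; physical voxel spacing only
rescales intensity gradients. The Jacobian is computed in pixel units
(central differences interior, one-sided at boundaries), so identity and
pure translations give determinant exactly 1.

## Synthetic data

The generator emulates the geometry that makes intersubject brain
registration hard at desk scale, not MRI physics. Phantoms are nested
smooth blobs — concentric ellipses whose shared boundary is perturbed by
low-frequency radial harmonics — with distinct piecewise-constant
intensity levels plus additive Gaussian noise (default levels 0.4/0.7/1.0
on background 0, noise σ 0.02, 64×64, three structures: comparable
relative contrasts and structure scales to subcortical anatomy on a small
grid). Ground-truth warps are Gaussian-smoothed white-noise vector fields
rescaled to a peak amplitude (default 3 px at smoothness σ 8 px); the spec
constraint amplitude ≤ σ keeps generated warps fold-free, verified per
seed. A registration pair is built by pulling the target back through a
generated warp `w`; the returned truth field is the numerical inverse of
`w` (fixed-point iteration), which is exactly the field registration
should recover under the pull-back convention, making "recovered ≈ truth"
well-defined.

Not emulated: bias fields, Rician noise, partial-volume blur, real
anatomical variability, skull/background clutter, anisotropic voxels.
Passing the synthetic suite therefore shows the algorithm is implemented
correctly and behaves as designed on well-posed smooth-warp problems; it
does not certify accuracy on clinical data.

## Numerical choices and degenerate inputs

- Out-of-domain samples clamp to the border (replicate), avoiding spurious
  zero-intensity forces at edges.
- Spring edges shorter than 1e−6 grid units are clamped (with a warning)
  before inverting the length.
- Cross-correlation of constant images, and Dice of a structure absent
  from both masks, raise `DegenerateInputError` rather than returning NaN.
- A constant source image is histogram-matched to the reference median
  (with a warning).
- Label propagation is nearest-neighbour only; interpolating label values
  is meaningless.
- Nothing in the pipeline draws random numbers at registration time, so
  runs are bit-reproducible given inputs and config; the seed in the
  config exists for manifest provenance and for the synthetic generators.

## Problem sizes

The test suite and the acceptance script use 20 seeded 64×64 registration
problems (two pyramid levels each) plus small grids (≤ 8×8) for the
direct-solve oracles; the full suite completes in seconds on one CPU.
These sizes were chosen as the smallest at which every mechanism of the
method — multiresolution transfer, template updating, fold correction — is
actually exercised.

## Known limitations

- The mesh is never remeshed; extreme deformations that would benefit from
  adaptive refinement are out of scope, as are torsional spring variants.
- 3-D operators are implemented and tested at the container level, but the
  evaluated reference path is 2-D.
- The alternating scheme optimises the two energy terms separately; no
  claim is made about convergence to a joint minimiser.
- With dynamic stiffness the L1 spring energy is not strictly monotone
  across sweeps (it is under frozen stiffness with a fixed boundary, which
  is the tested property).
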