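# meshreg

Topology-preserving nonrigid (deformable) image registration for
single-channel 2-D and 3-D images, with a synthetic evaluation suite.

Intersubject registration of medical images — e.g. mapping one brain MRI
onto another to transfer an atlas segmentation — needs a spatially varying
transformation `T(p) = p + u(p)` that makes the deformed template match the
target while keeping anatomy intact: no folding, crossing, or tearing of
structures, i.e. an everywhere-positive Jacobian determinant of `T`.

`meshreg` estimates `u` by alternating two cheap half-steps:

1. **Similarity force.** Minimising the sum of squared differences
   `E_sim = Σ_p (B(p) − A∘T(p))²` via the renormalized optical-flow
   (demons-style) velocity

       v(p) = (A∘T(p) − B(p)) ∇B(p) / (‖∇B(p)‖² + (A∘T(p) − B(p))²),

   applied as the displacement increment `−v(p)`. The renormalized
   denominator bounds each step by ½ px.

2. **Spring-mesh regularization.** The template grid carries a triangular
   mesh (one vertex per pixel); each edge is a linear spring with Batina
   stiffness `k_ij = 1/|x_j − x_i|` (inverse edge length), which resists
   vertex collision. A few Jacobi sweeps of the spring-equilibrium update

       u_i ← (Σ_j k_ij u_j) / (Σ_j k_ij)

   pull each vertex toward the stiffness-weighted average of its
   neighbours, keeping the mesh — and hence the image topology — valid.

A coarse-to-fine pyramid (factor-2 resampling) supplies large displacements;
any residual negative-Jacobian points after the finest scale are removed by
extra relaxation sweeps; and while the cross-correlation stays below the
stopping threshold `CC_t`, the template is re-warped through the current
transform and registration repeats (template updating), composing fields.

Evaluation utilities cover the cross-correlation factor CC, the
negative-Jacobian fraction `N_J`, endpoint error against a known field, and
atlas-style label propagation scored with the Dice/kappa similarity index
`KI = 2·TP / (2·TP + FN + FP)`.

## Worked example

`examples/02_register_synthetic_pair.py` builds a 64×64 phantom of nested
structures, deforms it with a smooth random field (3 px amplitude, 8 px
smoothness), registers template onto target, and scores the result:

```
cross-correlation: 0.9579 -> 0.9921
negative-Jacobian fraction (N_J): 0.0000
median endpoint error (gradient region): 0.588 px
template updates used: 3, scales: 2, iterations logged: 61
```

The cross-correlation rises toward 1 (deformed template ≈ target), `N_J = 0`
certifies a fold-free deformation, and the recovered field lands within a
fraction of a pixel of the known truth wherever the image carries gradient
information. `examples/04_label_transfer.py` continues to segmentation: the
template's structure labels pushed through the recovered field overlap the
target's true labels at KI ≈ 0.96–0.99, up from 0.85–0.98 before
registration.

The same pipeline from the shell:

```sh
meshreg synth --shape 64 64 --amplitude 3 --sigma 8 --seed 0 --out pair/
meshreg register --template pair/template.nii.gz --target pair/target.nii.gz --out reg/
meshreg evaluate --truth-field pair/truth_field.nii.gz \
    --est-field reg/displacement_field.nii.gz --labels pair/template_labels.nii.gz
```

Each command writes a `manifest.json` (config snapshot, input digests,
metrics) so runs are auditable and reproducible.

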