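"""Spring-analogy relaxation repairing a folded displacement field.

Builds a displacement field with a deliberate fold (negative Jacobian
determinants), then applies Jacobi spring-relaxation sweeps and watches the
folded-point fraction fall to zero.  The spring regularization energy is
printed alongside; with dynamic (inverse-edge-length) stiffness it is not
strictly monotone, but the topology defects it penalises disappear.
"""

import numpy as np

from meshreg import (
    DisplacementField,
    build_mesh,
    jacobian_determinants,
    negative_jacobian_fraction,
    regularization_energy,
    spring_relax,
)

shape = (32, 32)
x = np.arange(shape[0], dtype=float)
u = np.zeros(shape + (2,))
u[..., 0] = -2.5 * np.sin(2 * np.pi * x[:, None] / 10.0)  # self-crossing warp

mesh = build_mesh(shape)
fld = DisplacementField(u)
print("sweep  N_J      E_reg")
for sweep in range(6):
    nj = negative_jacobian_fraction(jacobian_determinants(fld))
    energy = regularization_energy(fld, mesh)
    print(f"{sweep:>5}  {nj:.4f}  {energy:10.3f}")
    fld = spring_relax(fld, mesh, n_iter=1)
# Each sweep replaces every vertex displacement by the stiffness-weighted
# average of its neighbours; inverse-edge-length (Batina) stiffness pushes
# colliding vertices apart, so folds disappear within a few sweeps.
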