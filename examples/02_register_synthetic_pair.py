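"""Register a synthetic pair with a known ground-truth deformation.

Creates a phantom target, warps it with a smooth random field to get the
template, runs the full multiresolution registration, and scores the
recovered displacement field against the known truth.
"""

import numpy as np

from meshreg import (
    PhantomSpec,
    RegistrationConfig,
    WarpSpec,
    endpoint_error,
    gradient_mask,
    make_registration_pair,
    register,
)

pair = make_registration_pair(
    PhantomSpec(shape=(64, 64), seed=1),
    WarpSpec(shape=(64, 64), amplitude_px=3.0, smoothness_sigma_px=8.0, seed=2),
)
report = register(pair.template, pair.target, RegistrationConfig())

epe = endpoint_error(report.final_field, pair.truth_field)
mask = gradient_mask(pair.target)
print(f"cross-correlation: {report.cc_initial:.4f} -> {report.cc_final:.4f}")
print(f"negative-Jacobian fraction (N_J): {report.nj_final:.4f}")
print(f"median endpoint error (gradient region): {np.median(epe[mask]):.3f} px")
print(f"template updates used: {report.n_template_updates}, "
      f"scales: {report.scales_used}, iterations logged: {len(report.trace)}")
# CC rising toward 1 means the deformed template matches the target;
# N_J = 0 means the deformation has no folds, crossings or tears; the
# endpoint error measures how close the recovered field is to the truth
# where the image actually carries information.
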