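"""Recover a known state-space model from its simulated output.

Simulates an order-2 innovation-form model (poles 0.9 and 0.5) and
re-estimates it with the subspace algorithm; the eigenvalues of the
estimated dynamics matrix are the similarity-invariant quantity to compare.
"""

import numpy as np

import imbef

# observer canonical form for poles {0.9, 0.5}, zeros 0.45 +/- 0.77i
poles = [0.9, 0.5]
zeros = [0.45 + 0.77j, 0.45 - 0.77j]
a, c = np.poly(poles), np.poly(zeros)
gen = imbef.SSModel(
    A=[[-a[1], 1.0], [-a[2], 0.0]],
    B=[[1.0, 0.0]],
    K=(c[1:] - a[1:]).reshape(2, 1),
    order=2,
)

y = imbef.simulate_ssm(gen, T=2000, noise_sd=1.0, seed=0)
fit = imbef.estimate_ssm(y, order=2)

est = np.sort(fit.eigenvalues().real)
print(f"true eigenvalues      : {sorted(poles)}")
print(f"estimated eigenvalues : {est.round(4).tolist()}")
print(f"max abs error         : {np.max(np.abs(est - np.sort(poles))):.4f}")
print(f"innovation variance   : {fit.residual_variance:.3f} (true 1.0)")
print(f"spectral radius       : {fit.spectral_radius:.3f} (stable < 1)")
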