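"""Infer species-metabolite coupling and check posterior stability.

Simulates a panel of 2 taxa and 2 metabolites where metabolite levels
respond to lagged changes in abundances (matrix B), infers A and B jointly
with Normal priors plus an LKJ residual-correlation prior, and classifies
the stability of the taxa matrix across all posterior draws.
"""

import numpy as np

from microdyn import (
    MCMCSettings,
    generate_fixture,
    infer_mvar_bayes,
    posterior_stability,
)

params, series = generate_fixture(
    "mvar", n_vars=2, n_steps=300, seed=3, noise_sd=0.2, n_metabolites=2
)
print("true B (abundance changes -> metabolites):\n", np.round(params.B, 3))

post = infer_mvar_bayes(series, seed=4,
                        mcmc=MCMCSettings(tune=1000, draws=1000, thin=1))
print("\nposterior median B:\n", np.round(post.median("B"), 3))
print("posterior median A:\n", np.round(post.median("A"), 3))

report = posterior_stability(post, matrix_name="A")
print(f"\n{report.fraction_stable:.2f}% of sampled A matrices are stable "
      f"(all eigenvalue moduli < 1)")
print("median A matrix stable:", report.median_matrix_stable,
      f"(spectral radius {report.median_matrix_spectral_radius:.3f})")
print("A stable median alongside a fraction below 100% would mean some "
      "posterior mass sits on unstable interaction structures — the two "
      "classifications are computed independently.")
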