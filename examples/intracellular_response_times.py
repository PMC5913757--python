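"""First-passage (response-time) distributions of intracellular multi-step models.

Solves a 10-step irreversible reaction chain, confirms the gamma closed
form, and shows how log-normal cell-to-cell rate heterogeneity flattens
the fitted shape parameter.
"""

import numpy as np

import rtnet as rt
from rtnet.intracellular import ChainModel, HeterogeneitySpec, heterogeneous_rt, solve_model_rt
from rtnet.distributions import fit_gamma_to_samples

law = rt.GammaRT(10.0, 10.0)  # 10 steps, unit mean
grid = law.default_grid()
emp = solve_model_rt(ChainModel(n_steps=10, base_rate=1.0), grid)
print(f"sup-norm ODE flux vs gamma(10,10): "
      f"{np.max(np.abs(emp.density - law.pdf(grid))):.2e}")

for cv in (0.0, 0.5, 1.0):
    samples = heterogeneous_rt(ChainModel(10, 1.0),
                               HeterogeneitySpec(cv=cv, n_cells=20000, seed=1))
    fit = fit_gamma_to_samples(samples)
    print(f"rate heterogeneity CV={cv}: best-fit shape alpha = {fit.fitted.shape:.2f}")

# The first line shows the chain's first-passage density is exactly the
# gamma distribution. The fitted alpha starts at the step number (10) and
# drops as cell-to-cell variability broadens the tails: heterogeneity makes
# the population response less, not more, predictable.
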