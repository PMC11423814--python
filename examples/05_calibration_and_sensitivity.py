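"""Desk-scale Bayesian calibration and Sobol' sensitivity.

Generates synthetic luminescence references at known parameters, runs a
short ensemble-MCMC chain over three clock parameters, and prints the
recovered posterior intervals next to the truth; then computes total-order
Sobol' indices on an analytic benchmark to show the estimator at work.
"""
import numpy as np

from mechanoclock import (CircadianParams, FitSpace, MechanoParams,
                          TreatmentCondition, generate_synthetic_calibration,
                          run_mcmc, sobol_total_order)
from mechanoclock.calibration import batched_objective

mech, circ = MechanoParams(), CircadianParams()
names = ["circ.tau_P", "circ.K_dP"]
truth = np.array([circ.tau_P, circ.K_dP])
fit = FitSpace(names=names, lower=[7.0, 0.2], upper=[11.0, 0.45])
datasets = generate_synthetic_calibration(
    mech, circ, [TreatmentCondition()], T_sd=0.5, A_sd_frac=0.15,
    n_samples=20000, horizon_h=48.0, seed=3)
logp = batched_objective(fit, datasets, mech, circ, duration=96.0, dt=0.2)
sampler = run_mcmc(logp, fit, n_walkers=10, n_steps=150, seed=5,
                   start=truth * 1.05, vectorized=True)
chain = sampler.get_chain(discard=75, flat=True)
for i, name in enumerate(names):
    lo, hi = np.percentile(chain[:, i], [2.5, 97.5])
    print(f"{name}: truth {truth[i]:.3f}, posterior 95% CI [{lo:.3f}, {hi:.3f}]")

ST = sobol_total_order(lambda X: np.sin(X[:, 0]) + 0.2 * X[:, 1] ** 2,
                       lower=[-np.pi, -np.pi], upper=[np.pi, np.pi],
                       n_base=4096, seed=0)
print(f"Sobol' total-order indices (analytic benchmark): {np.round(ST, 3)}")
print("\nEven this short demonstration chain concentrates near the "
      "generating values; the Sobol' indices apportion output variance "
      "between the two inputs.")
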