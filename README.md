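# mechanoclock

Modeling how a cell's mechanical environment tunes — and can break — its
circadian clock.

Fibroblast-like cells keep ~24 h rhythms in clock proteins (BMAL1, PER/CRY,
REV-ERBα) even in culture, but the strength of those rhythms depends on
substrate stiffness, cell spreading and cytoskeletal drugs.  `mechanoclock`
couples two models to explain that dependence:

1. **A YAP/TAZ–MRTF mechanotransduction network.**  Substrate stiffness
   activates FAK → RhoA → ROCK/mDia, driving actin polymerization, stress
   fiber assembly, lamin-A-dependent stretching of nuclear pore complexes,
   and finally nuclear import of the transcriptional co-regulators YAP/TAZ
   (released from cytosolic phosphorylation) and MRTF (released from G-actin
   sequestration).  Because these events are fast compared to the clock, the
   network is solved at steady state: a condition (stiffness in kPa, contact
   area, cell density, inhibitor concentrations, mutations) maps to
   steady-state nuclear concentrations [Y]<sub>nuc</sub> and
   [M]<sub>nuc</sub>.  Drug mechanisms get closed-form actin balances:
   cytochalasin D (filament capping + G-actin dimerization), latrunculin
   (G-actin sequestration) and jasplakinolide (enhanced assembly).

2. **A three-species delay-differential clock.**  Nuclear concentrations
   *B* (BMAL1), *P* (PER/CRY) and *R* (REV-ERBα) obey

   ```
   dB/dt = K_eB0 / (1 + (R(t−τ_B)/K_IR)²)          + K_eB2(Y,M) − K_dB·B
   dP/dt = g(B(t−τ_P), P(t−τ_P))                   + K_eP2(Y,M) − K_dP·P
   dR/dt = ζ·g(B(t−τ_R), P(t−τ_R))                 + K_eR2(Y,M) − K_dR·R
   g(B,P) = K_eP0 · (B/K_aB)²/(1+(B/K_aB)²) · 1/(1+(P/K_IP)²)
   ```

   with delays τ representing transcription-to-nuclear-protein lags, and
   mechano-coupling terms K<sub>eX2</sub> that are sums of activating Hill
   functions (exponent 2) of [Y]<sub>nuc</sub> and [M]<sub>nuc</sub>.  A
   luciferase reporter (dL/dt = K<sub>eL</sub>·expr<sub>P</sub> −
   K<sub>dL</sub>·L) mimics PER2::Luc luminescence recordings.  Raising the
   mechano inputs pushes the system through a supercritical Hopf
   bifurcation: oscillations that are sustained on soft substrates decay
   when nuclear YAP/TAZ and MRTF accumulate (stiff substrates,
   jasplakinolide, YAP-5SA or lamin A mutations).

On top of the core model the package provides

- **population simulation**: cohorts of model cells with log-normally varied
  kinetic parameters (σ = 0.2), solved in one vectorized DDE integration,
  with reporter noise at SNR 5;
- **oscillation metrics**: period/amplitude extraction and the **circadian
  power fraction** — the fraction of a cell's power spectrum within
  ±0.1 day⁻¹ of the population circadian frequency after 15-min sampling, a
  zero-phase 4-tap FIR filter and standardization (0 = arrhythmic,
  1 = perfect sinusoid);
- **statistics**: one-way ANOVA + Tukey HSD with compact letter displays,
  and log-scale Pearson correlations of power fraction vs N/C ratios;
- **Bayesian calibration**: reconstructed luminescence references from
  period/amplitude summaries, a period-penalized Gaussian likelihood,
  affine-invariant ensemble MCMC (emcee) with IACT convergence checks;
- **sensitivity**: total-order Sobol' indices (Saltelli sampling, Jansen
  estimator);
- **stability analysis**: analytic linearization of the DDEs,
  rightmost characteristic roots, and the Hopf locus over the
  (YAP/TAZ, MRTF) plane.

## A worked example

```python
from mechanoclock import (MechanoParams, CircadianParams, TreatmentCondition,
                          steady_state_network, coupling_rates,
                          simulate_clock, period_amplitude)

mech, circ = MechanoParams(), CircadianParams()
state = steady_state_network(mech, TreatmentCondition())   # glass, untreated
print(state.yap_nc, state.mrtf_nc)      # 0.274 0.635  (N/C ratios)

coup = coupling_rates(*state.nuclear_inputs(), circ)
traj = simulate_clock(circ, coup, duration=24 * 10)
print(period_amplitude(traj, species="P"))  # (23.53, 1.32): ~24 h rhythm
```

The N/C ratios say how strongly the stiff glass substrate concentrates
YAP/TAZ and MRTF in the nucleus; the period confirms the representative
cell keeps a circadian (~24 h) rhythm under that condition.  Swapping the
condition for `TreatmentCondition(jasplakinolide=1.0)` raises both nuclear
inputs past the Hopf point and the same call shows decaying oscillations
(see `examples/02_single_cell_clock.py`, which prints the peak-decay ratio
0.58 → 0.05).

The `examples/` directory walks through each capability: the stiffness
sweep of the mechano network, single-cell dynamics, population power
fractions, the Hopf locus, and desk-scale calibration/sensitivity runs.
A thin CLI mirrors the pipeline (`mechanoclock simulate | population |
calibrate | sensitivity | stability | powerfraction`).

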