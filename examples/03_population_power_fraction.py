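"""Population cohorts and the circadian power fraction.

Simulates 100-cell cohorts with log-normal parameter variability on a soft
substrate and on glass, adds reporter noise (SNR 5), and prints the median
oscillation period and circadian power fraction of nuclear REV-ERBalpha.
"""
import numpy as np

from mechanoclock import (CircadianParams, MechanoParams, TreatmentCondition,
                          sample_parameters, simulate_population)

mech, circ = MechanoParams(), CircadianParams()
for label, cond in [("0.1 kPa", TreatmentCondition(substrate_stiffness=0.1)),
                    ("glass", TreatmentCondition())]:
    sets = sample_parameters(mech, circ, 100, seed=7)
    res = simulate_population(sets, cond, seed=8)
    m = res.metrics
    print(f"{label}: median period {np.nanmedian(m.period_h):.2f} h, "
          f"median power fraction {m.power_fraction.median():.3f}")
print("\nSofter substrates give longer periods and power fractions closer "
      "to 1 (clean rhythms); on glass more cells sit near or past the Hopf "
      "point and the spectrum spreads, lowering the fraction.")
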