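"""Hopf bifurcation locus in the nuclear YAP/TAZ - MRTF plane.

For each nuclear MRTF level, finds the critical nuclear YAP/TAZ
concentration where the clock's fixed point changes stability.  Conditions
below the curve sustain circadian oscillations; above it they decay.
"""
import numpy as np

from mechanoclock import CircadianParams, hopf_locus

circ = CircadianParams()
res = hopf_locus(circ, np.linspace(0.05, 4.0, 9), np.linspace(0.1, 2.4, 5))
print(f"{'MRTF_nuc':>9} {'critical YAP/TAZ_nuc':>21}")
for m, yc in zip(res["mrtf"], res["yap_critical"]):
    print(f"{m:9.2f} {yc:21.3f}" if np.isfinite(yc) else f"{m:9.2f} {'none':>21}")
print("\nThe critical YAP/TAZ falls as MRTF rises: both inputs push the "
      "clock toward the bifurcation, so less of one is needed when the "
      "other is high.")
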