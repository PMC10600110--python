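"""15N tracer incubations: total reduction, assimilation and the fate
partition.

Simulates one winter batch of T0/Tf incubation vials (control, 15N2 and
15N2O treatments at 6-25 degC), then computes per-vial rates from the
isotopologue concentrations (15N2O = 45 + 2*46), the D29/D30 excesses
(censored at the 0.14 uM detection limit), and biomass 15N enrichment
(PON x excess atom fraction), closing the budget
    fixation = reduction - N2 production = assimilation + DIN production.
"""

import json

from n2ofix import SimulationConfig, simulate_incubation_batch, run_tracer

config = SimulationConfig()
vials = simulate_incubation_batch(config, seed=11, season="winter")
rates, cohorts, discrimination = run_tracer(vials)

n2 = cohorts["tracer_N2"]["assimilation"]
n2o = cohorts["tracer_N2O"]
print(f"15N2  assimilation: {n2['trimmed_mean']:.1f} +/- {n2['trimmed_se']:.1f} "
      f"nmol N/g/d (trimmed mean +/- se, n={n2['n']})")
a = n2o["assimilation"]
print(f"15N2O assimilation: {a['trimmed_mean']:.1f} +/- {a['trimmed_se']:.1f} "
      f"nmol N/g/d (n={a['n']})")
r = n2o["reduction"]
print(f"total 15N2O reduction (winter): {r['trimmed_mean']:.0f} +/- "
      f"{r['trimmed_se']:.0f} nmol N/g/d")
print(f"median NOx share of total reduction: "
      f"{n2o['nox_fraction_median']:.3f}")
censored = (rates["delta15n2_below_lod"] == "True").mean()
print(f"fraction of vials with D15N2 below the 0.14 uM LOD: {censored:.2f}")
print()
print("discrimination report:")
print(json.dumps({k: round(v, 3) if isinstance(v, float) else v
                  for k, v in discrimination.items()}, indent=2))
print()
print("Reduction far exceeds assimilation (much fixed N leaks to the water")
print("as DIN), and the measured 15N2O assimilation sits well above the")
print("indirect upper threshold: fixation is direct.")
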