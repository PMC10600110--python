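"""Temperature sensitivity of the two fixation pathways.

Simulates a tracer batch across 6-25 degC and fits median (quantile)
regressions of assimilation rate on temperature for each pathway --
rates normalised to dry biomass are heavily skewed, so medians resist the
outliers.  Q10 (rate multiplication per 10 degC warming) is estimated from
per-temperature trimmed cell means; the median-fit variants are shown for
comparison.
"""

from n2ofix import (
    SimulationConfig,
    simulate_incubation_batch,
    run_tracer,
    run_temperature,
)
from n2ofix.temperature import q10_trimmed_mean

config = SimulationConfig()
vials = simulate_incubation_batch(config, seed=21, season="winter")
rates, _, _ = run_tracer(vials)
fits = run_temperature(rates, seed=21, n_boot=200)

for pathway, fit in fits.items():
    g = rates[rates["treatment"] == f"tracer_{pathway}"]
    q10_tm = q10_trimmed_mean(g["assimilation_nmolN_per_g_d"].to_numpy(),
                              g["temperature_C"].to_numpy())
    print(f"{pathway}-pathway (n={fit.n}):")
    print(f"  linear median slope = {fit.slope:.2f} nmol/g/d per degC "
          f"(95% CI {fit.slope_ci[0]:.2f} to {fit.slope_ci[1]:.2f})")
    print(f"  Q10 (trimmed cell means) = {q10_tm:.2f}")
    print(f"  Q10 (exp median fit)     = {fit.q10:.2f} "
          f"(95% CI {fit.q10_ci[0]:.2f} to {fit.q10_ci[1]:.2f})")
print()
print("N2 fixation speeds up with warming (underlying Q10 ~ 1.4; a single")
print("batch estimates it with the wide CI shown) while N2O assimilation")
print("stays flat (Q10 ~ 1): in the cold, a larger share of total N")
print("fixation runs on N2O.")
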