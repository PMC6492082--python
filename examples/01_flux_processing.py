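"""Flux processing: concentration -> flux, baselines, cumulative emissions.

Builds a two-day CO2 pulse riding the constant respiration baseline,
subtracts the baseline and integrates, then shows the unit conversion from
a detector mole fraction to an area flux.
"""
import numpy as np

import n2opools as n

vessel = n.VesselConfig.from_treatment("demo-3c", "3c")

# 1 ppm N2O leaving the vessel at 30 mL/min at 20 degC
flux = n.concentration_to_flux(1.0, 30.0, vessel, "N2O")
print(f"1 ppm N2O at 30 mL/min -> {flux:.4f} kg N ha-1 d-1")

# a CO2 pulse on the 0.67 kg C ha-1 h-1 respiration baseline
t = np.arange(0, 10 + 1e-9, 2 / 24)  # bi-hourly sampling, days
pulse = 60.0 * np.exp(-0.5 * ((t - 3.0) / 1.2) ** 2)
co2 = n.GasFluxSeries("CO2", t, pulse + 24 * n.CO2_BASELINE_KG_HA_H, vessel)

adjusted = n.subtract_baseline(co2, n.CO2_BASELINE_KG_HA_H)
total = n.cumulative_emission(adjusted, 0, 10).total
print(f"amendment-attributable CO2 over days 0-10: {total:.1f} kg C ha-1")
print("(the baseline-inclusive integral would add "
      f"{24 * n.CO2_BASELINE_KG_HA_H * 10:.1f} kg C ha-1 of respiration)")

# product ratio: the share of denitrified N escaping as N2O
n2o = n.GasFluxSeries("N2O", t, 5.0 * np.exp(-0.5 * ((t - 3.5) / 1.5) ** 2))
n2 = n.GasFluxSeries("N2", t, 2.0 * np.exp(-0.5 * ((t - 5.0) / 1.5) ** 2))
ratio = n.product_ratio(n2o, n2)
print(f"product ratio N2O/(N2O+N2) at day 3: "
      f"{np.interp(3.0, ratio.times, ratio.r_n2o):.2f} "
      "(close to 1 = little N2O is reduced on to N2)")
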