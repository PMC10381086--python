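# Simplified DEB (DEBkiss) model: assimilation scales with volumetric
# length^2, maintenance with volumetric length^3, which reduces to a
# von-Bertalanffy equation in physical length with asymptote 60 mm at f=1.
# Original publication assumed unlimited food; this suite scales food with
# the Holling type II response of the photoperiod-DEB parameterization
# (unlimited_food flag restores the original assumption).
model: jager2015
stage: all krill
source: "Jager & Ravagnan (2015) Ecol. Modell. 301:29-39"
calibration:
  region: "laboratory/literature compilation"
  season: "full year"
  food_proxy: "unlimited food assumed in the original; chl range undetermined"
  chl_range: "undetermined"
  temperature_range_degC: [-2.0, 5.0]
coefficients:
  length_inf:
    {value: 60.0, units: "mm", citation: "Jager & Ravagnan (2015), asymptotic physical length under unlimited food"}
  von_bert_rate:
    {value: 0.0035, units: "d-1", citation: "Jager & Ravagnan (2015), von-Bertalanffy growth rate at 0 degC"}
  arrhenius_temp:
    {value: 7421.0, units: "K", citation: "Jager & Ravagnan (2015), Arrhenius temperature"}
  temp_ref:
    {value: 273.15, units: "K", citation: "Jager & Ravagnan (2015), reference temperature (0 degC)"}
  shape_factor:
    {value: 0.2, units: "-", citation: "Jager & Ravagnan (2015), shape conversion factor (volumetric/physical length)"}
  food_half_sat:
    {value: 1.35, units: "mg chl m-3", citation: "Bahlburg et al. (2021), Holling type II half-saturation (borrowed parameterization)"}
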