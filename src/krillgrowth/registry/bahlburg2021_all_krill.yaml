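# Photoperiod-DEB model: DEBkiss budget with an explicit day-length scaling
# of ingestion and respiration derived from experimental photoperiod work
# (Piccolin et al. 2018): bounded, monotone increasing in day length.
model: bahlburg2021
stage: all krill
source: "Bahlburg et al. (2021) J. Plankton Res."
calibration:
  region: "Western Antarctic Peninsula (in-situ forcing)"
  season: "full year"
  food_proxy: "in-situ chlorophyll a"
  chl_range: "4 months with daily chl >2 mg m-3"
  temperature_range_degC: [-2.0, 5.0]
coefficients:
  length_inf:
    {value: 60.0, units: "mm", citation: "Bahlburg et al. (2021), asymptotic physical length under unlimited food"}
  von_bert_rate:
    {value: 0.0035, units: "d-1", citation: "Bahlburg et al. (2021), von-Bertalanffy growth rate at 0 degC"}
  arrhenius_temp:
    {value: 7421.0, units: "K", citation: "Bahlburg et al. (2021), Arrhenius temperature"}
  temp_ref:
    {value: 273.15, units: "K", citation: "Bahlburg et al. (2021), reference temperature (0 degC)"}
  shape_factor:
    {value: 0.2, units: "-", citation: "Bahlburg et al. (2021), shape conversion factor"}
  food_half_sat:
    {value: 1.35, units: "mg chl m-3", citation: "Bahlburg et al. (2021), Holling type II half-saturation"}
  photo_floor:
    {value: 0.45, units: "-", citation: "Piccolin et al. (2018) via Bahlburg et al. (2021), metabolic activity at 0 h day length"}
  photo_slope:
    {value: 0.55, units: "-", citation: "Piccolin et al. (2018) via Bahlburg et al. (2021), day-length scaling range (activity 1.0 at 24 h)"}
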