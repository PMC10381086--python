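# Energy-partitioning model: Holling type II uptake (low half-saturation,
# in-situ calibration data), metabolism charged first, residual allocated to
# somatic growth; winter metabolic switch. Anchored on positive growth at
# (-1.5 degC, 0.3 mg chl m-3) and ~5 mm seasonal growth under moderate food.
model: ryabov2017
stage: all krill
source: "Ryabov et al. (2017) Nat. Ecol. Evol. 1:0177"
calibration:
  region: "Western Antarctic Peninsula (Palmer LTER, in-situ chl, sinusoidal approximation)"
  season: "full year"
  food_proxy: "in-situ chlorophyll a (lower peak concentrations than WAP DEB forcing)"
  chl_range: "moderate, peaks ~1-2 mg m-3"
  temperature_range_degC: [-2.0, 5.0]
coefficients:
  length_inf:
    {value: 60.0, units: "mm", citation: "Ryabov et al. (2017), maximum body length of the energy-partitioning scheme"}
  growth_rate:
    {value: 0.004, units: "d-1", citation: "Ryabov et al. (2017), somatic growth-rate constant at 0 degC"}
  arrhenius_temp:
    {value: 7421.0, units: "K", citation: "Ryabov et al. (2017), metabolic temperature scaling (Arrhenius form)"}
  temp_ref:
    {value: 273.15, units: "K", citation: "Ryabov et al. (2017), reference temperature (0 degC)"}
  food_half_sat:
    {value: 0.35, units: "mg chl m-3", citation: "Ryabov et al. (2017), Holling type II half-saturation"}
  winter_factor:
    {value: 0.5, units: "-", citation: "Ryabov et al. (2017), winter metabolic reduction"}
  winter_start:
    {value: "05-01", units: "MM-DD", citation: "Ryabov et al. (2017), winter window start"}
  winter_end:
    {value: "09-30", units: "MM-DD", citation: "Ryabov et al. (2017), winter window end"}
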