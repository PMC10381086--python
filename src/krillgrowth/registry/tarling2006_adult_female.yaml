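# Length/stage/temperature intermoult-period model, adult-female fit:
# hyperbolic in temperature (moult rate is a downward parabola peaking at
# 0.5 degC, so IMP lengthens above 0.5 degC), linear in body length.
# 10 d at (0 degC, 35 mm).
model: tarling2006
stage: adult female
source: "Tarling et al. (2006) Limnol. Oceanogr. 51:959-972"
calibration:
  region: "Scotia Sea, South Georgia, northern Antarctic Peninsula"
  season: "austral summer"
  food_proxy: "none (IMP model)"
  chl_range: "n/a"
  temperature_range_degC: [-1.0, 4.0]
coefficients:
  imp_scale:
    {value: 10.0, units: "d", citation: "Tarling et al. (2006), adult-female IMP model, scale at 35 mm and 0 degC"}
  length_ref_mm:
    {value: 35.0, units: "mm", citation: "Tarling et al. (2006), adult-female IMP model, reference length"}
  rate_temp_lin:
    {value: 0.03, units: "degC-1", citation: "Tarling et al. (2006), adult-female IMP model, moult-rate temperature term"}
  rate_temp_sq:
    {value: -0.03, units: "degC-2", citation: "Tarling et al. (2006), adult-female IMP model, moult-rate temperature curvature"}
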