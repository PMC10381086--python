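# Length/stage/temperature intermoult-period model, juvenile fit: IMP is
# nearly length-independent for juveniles and has an interior maximum at
# 3 degC.
model: tarling2006
stage: juvenile
source: "Tarling et al. (2006) Limnol. Oceanogr. 51:959-972"
calibration:
  region: "Scotia Sea, South Georgia, northern Antarctic Peninsula"
  season: "austral summer"
  food_proxy: "none (IMP model)"
  chl_range: "n/a"
  temperature_range_degC: [-1.0, 4.0]
coefficients:
  imp_scale:
    {value: 9.0, units: "d", citation: "Tarling et al. (2006), juvenile IMP model, scale"}
  temp_curvature:
    {value: 0.01, units: "degC-2", citation: "Tarling et al. (2006), juvenile IMP model, temperature curvature"}
  temp_optimum:
    {value: 3.0, units: "degC", citation: "Tarling et al. (2006), juvenile IMP model, temperature of maximum IMP"}
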