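# Adult-female DGR parameterization, used by the Tarling composite above the
# 35 mm stage switch.
model: atkinson2006
stage: adult female
source: "Atkinson et al. (2006) Limnol. Oceanogr. 51:973-987"
calibration:
  region: "Scotia Sea, South Georgia, northern Antarctic Peninsula"
  season: "austral summer (incl. spring-like southern stations)"
  food_proxy: "satellite-derived chlorophyll a"
  chl_range: "right-skewed, mostly <1.5 mg m-3"
  temperature_range_degC: [-1.0, 4.0]
coefficients:
  dgr_intercept:
    {value: -0.081, units: "mm d-1", citation: "Atkinson et al. (2006), adult-female growth model"}
  dgr_length:
    {value: 0.00225, units: "mm d-1 mm-1", citation: "Atkinson et al. (2006), adult-female growth model"}
  dgr_length_sq:
    {value: -0.000061, units: "mm d-1 mm-2", citation: "Atkinson et al. (2006), adult-female growth model"}
  dgr_food_max:
    {value: 0.385, units: "mm d-1", citation: "Atkinson et al. (2006), adult-female growth model"}
  dgr_food_half_sat:
    {value: 0.328, units: "mg chl m-3", citation: "Atkinson et al. (2006), adult-female growth model"}
  dgr_temp:
    {value: 0.0078, units: "mm d-1 degC-1", citation: "Atkinson et al. (2006), adult-female growth model"}
  dgr_temp_sq:
    {value: -0.0101, units: "mm d-1 degC-2", citation: "Atkinson et al. (2006), adult-female growth model"}
  imp_ref_days:
    {value: 10.5, units: "d", citation: "Atkinson et al. (2006), mean observed intermoult period, adult females"}
  length_ref_mm:
    {value: 40.0, units: "mm", citation: "Atkinson et al. (2006), reference body length of the adult-female increment model"}
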