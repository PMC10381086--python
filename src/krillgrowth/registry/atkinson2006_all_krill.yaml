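# "All krill" DGR parameterization - the standard choice of downstream
# applications; equation transcribed as published.
model: atkinson2006
stage: all krill
source: "Atkinson et al. (2006) Limnol. Oceanogr. 51:973-987"
calibration:
  region: "Scotia Sea, South Georgia, northern Antarctic Peninsula"
  season: "austral summer (incl. spring-like southern stations)"
  food_proxy: "satellite-derived chlorophyll a"
  chl_range: "right-skewed, mostly <1.5 mg m-3"
  temperature_range_degC: [-1.0, 4.0]
coefficients:
  dgr_intercept:
    {value: -0.066, units: "mm d-1", citation: "Atkinson et al. (2006), all-krill growth model (Eq. 4)"}
  dgr_length:
    {value: 0.002, units: "mm d-1 mm-1", citation: "Atkinson et al. (2006), all-krill growth model (Eq. 4)"}
  dgr_length_sq:
    {value: -0.000061, units: "mm d-1 mm-2", citation: "Atkinson et al. (2006), all-krill growth model (Eq. 4)"}
  dgr_food_max:
    {value: 0.385, units: "mm d-1", citation: "Atkinson et al. (2006), all-krill growth model (Eq. 4)"}
  dgr_food_half_sat:
    {value: 0.328, units: "mg chl m-3", citation: "Atkinson et al. (2006), all-krill growth model (Eq. 4)"}
  dgr_temp:
    {value: 0.0078, units: "mm d-1 degC-1", citation: "Atkinson et al. (2006), all-krill growth model (Eq. 4)"}
  dgr_temp_sq:
    {value: -0.0101, units: "mm d-1 degC-2", citation: "Atkinson et al. (2006), all-krill growth model (Eq. 4)"}
  imp_ref_days:
    {value: 10.5, units: "d", citation: "Atkinson et al. (2006), mean observed intermoult period, all krill"}
  length_ref_mm:
    {value: 40.0, units: "mm", citation: "Atkinson et al. (2006), reference body length of the all-krill increment model"}
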