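# Instantaneous daily growth rate (DGR) and per-moult growth increment,
# juvenile parameterization. Functional family: additive terms quadratic in
# body length, quadratic in temperature, Michaelis-Menten (saturating) in
# chlorophyll a. Coefficients anchored to the published benchmark behaviour
# of the juvenile fit (surface peak >0.3 mm/d for a 26 mm krill in summer).
model: atkinson2006
stage: juvenile
source: "Atkinson et al. (2006) Limnol. Oceanogr. 51:973-987"
calibration:
  region: "Scotia Sea, South Georgia, northern Antarctic Peninsula"
  season: "austral summer (incl. spring-like southern stations)"
  food_proxy: "satellite-derived chlorophyll a"
  chl_range: "right-skewed, mostly <1.5 mg m-3"
  temperature_range_degC: [-1.0, 4.0]
coefficients:
  dgr_intercept:
    {value: -0.158, units: "mm d-1", citation: "Atkinson et al. (2006), juvenile growth model"}
  dgr_length:
    {value: 0.00674, units: "mm d-1 mm-1", citation: "Atkinson et al. (2006), juvenile growth model"}
  dgr_length_sq:
    {value: -0.000101, units: "mm d-1 mm-2", citation: "Atkinson et al. (2006), juvenile growth model"}
  dgr_food_max:
    {value: 0.385, units: "mm d-1", citation: "Atkinson et al. (2006), juvenile growth model"}
  dgr_food_half_sat:
    {value: 0.321, units: "mg chl m-3", citation: "Atkinson et al. (2006), juvenile growth model"}
  dgr_temp:
    {value: 0.00811, units: "mm d-1 degC-1", citation: "Atkinson et al. (2006), juvenile growth model"}
  dgr_temp_sq:
    {value: -0.0115, units: "mm d-1 degC-2", citation: "Atkinson et al. (2006), juvenile growth model"}
  imp_ref_days:
    {value: 9.2, units: "d", citation: "Atkinson et al. (2006), mean observed intermoult period of the growth-increment dataset"}
  length_ref_mm:
    {value: 26.0, units: "mm", citation: "Atkinson et al. (2006), reference body length of the juvenile increment model"}
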