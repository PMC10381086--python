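# Temperature-only intermoult-period model: exponential decay of IMP with
# water temperature. 30 d at 0 degC; anchored so that it agrees with the
# Tarling adult-female IMP in the 1.5-2.5 degC band and diverges outside it.
model: kawaguchi2006
stage: all krill
source: "Kawaguchi et al. (2006) Mar. Ecol. Prog. Ser."
calibration:
  region: "Indian sector of the Southern Ocean"
  season: "austral summer"
  food_proxy: "none (temperature-only IMP model)"
  chl_range: "n/a"
  temperature_range_degC: [-1.0, 4.0]
coefficients:
  imp_at_zero:
    {value: 30.0, units: "d", citation: "Kawaguchi et al. (2006), IMP-temperature regression, intercept at 0 degC"}
  imp_decay:
    {value: 0.45, units: "degC-1", citation: "Kawaguchi et al. (2006), IMP-temperature regression, exponential decay rate"}
  validity_min_degC:
    {value: -2.0, units: "degC", citation: "Kawaguchi et al. (2006), observed temperature range (extended to habitat minimum)"}
  validity_max_degC:
    {value: 5.0, units: "degC", citation: "Kawaguchi et al. (2006), observed temperature range (extended to habitat maximum)"}
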