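# Variant of the Hofmann/Lascara-type budget with a comparatively small
# temperature dependence of metabolism (lower respiration Q10); ice-algal
# food input fixed to zero in this suite. Same cap and anchors.
model: fach2002
stage: all krill
source: "Fach et al. (2002) Mar. Ecol. Prog. Ser. 231:187-203"
calibration:
  region: "Western Antarctic Peninsula"
  season: "full year (model-derived forcing)"
  food_proxy: "POC from regional biogeochemical model output"
  chl_range: ">3 months with >1 mg chl m-3"
  temperature_range_degC: [-2.0, 4.0]
coefficients:
  mass_coeff:
    {value: 0.002, units: "mg C mm-3", citation: "Fach et al. (2002), carbon mass-length relation"}
  mass_exp:
    {value: 3.0, units: "-", citation: "Fach et al. (2002), carbon mass-length relation"}
  assimilation_eff:
    {value: 0.8, units: "-", citation: "Fach et al. (2002), assimilation efficiency"}
  ingest_max:
    {value: 0.569, units: "mg C (mg C)^(-2/3) d-1", citation: "Fach et al. (2002), maximum mass-specific ingestion"}
  ingest_half_sat_poc:
    {value: 150.0, units: "mg C m-3", citation: "Fach et al. (2002), ingestion food saturation constant (Ivlev)"}
  resp_coeff:
    {value: 0.0437, units: "mg C (mg C)^(-0.85) d-1", citation: "Fach et al. (2002), basal respiration"}
  resp_exp:
    {value: 0.85, units: "-", citation: "Fach et al. (2002), respiration mass exponent"}
  resp_q10:
    {value: 1.5, units: "-", citation: "Fach et al. (2002), respiration Q10 (weaker temperature dependence of metabolism)"}
  growth_cap:
    {value: 0.25, units: "mm d-1", citation: "Fach et al. (2002), imposed maximum daily length change"}
  winter_factor:
    {value: 0.5, units: "-", citation: "Fach et al. (2002), winter metabolic reduction"}
  winter_start:
    {value: "05-01", units: "MM-DD", citation: "Fach et al. (2002), winter window start (late fall)"}
  winter_end:
    {value: "09-30", units: "MM-DD", citation: "Fach et al. (2002), winter window end (early spring)"}
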