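# POC-driven bioenergetic budget: saturating ingestion scaling with carbon
# mass^(2/3), respiration with mass^0.85 and a Q10 temperature correction;
# daily length change capped at 0.25 mm/d. Anchored on the published cap and
# cap-onset chlorophyll band (1.4-1.7 mg m-3).
model: hofmann2000
stage: all krill
source: "Hofmann & Lascara (2000) Mar. Ecol. Prog. Ser. 194:219-231"
calibration:
  region: "Western Antarctic Peninsula"
  season: "full year (model-derived forcing)"
  food_proxy: "POC from regional biogeochemical model output"
  chl_range: ">3 months with >1 mg chl m-3"
  temperature_range_degC: [-2.0, 4.0]
coefficients:
  mass_coeff:
    {value: 0.002, units: "mg C mm-3", citation: "Hofmann & Lascara (2000), carbon mass-length relation"}
  mass_exp:
    {value: 3.0, units: "-", citation: "Hofmann & Lascara (2000), carbon mass-length relation"}
  assimilation_eff:
    {value: 0.8, units: "-", citation: "Hofmann & Lascara (2000), assimilation efficiency"}
  ingest_max:
    {value: 0.569, units: "mg C (mg C)^(-2/3) d-1", citation: "Hofmann & Lascara (2000), maximum mass-specific ingestion"}
  ingest_half_sat_poc:
    {value: 150.0, units: "mg C m-3", citation: "Hofmann & Lascara (2000), ingestion food saturation constant (Ivlev)"}
  resp_coeff:
    {value: 0.0437, units: "mg C (mg C)^(-0.85) d-1", citation: "Hofmann & Lascara (2000), basal respiration"}
  resp_exp:
    {value: 0.85, units: "-", citation: "Hofmann & Lascara (2000), respiration mass exponent"}
  resp_q10:
    {value: 2.5, units: "-", citation: "Hofmann & Lascara (2000), respiration Q10"}
  growth_cap:
    {value: 0.25, units: "mm d-1", citation: "Hofmann & Lascara (2000), imposed maximum daily length change"}
  winter_factor:
    {value: 0.5, units: "-", citation: "Hofmann & Lascara (2000), winter metabolic reduction"}
  winter_start:
    {value: "05-01", units: "MM-DD", citation: "Hofmann & Lascara (2000), winter window start (late fall)"}
  winter_end:
    {value: "09-30", units: "MM-DD", citation: "Hofmann & Lascara (2000), winter window end (early spring)"}
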