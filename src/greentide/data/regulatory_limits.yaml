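# International legislative / recommended maximum limits of toxic elements in
# foods, feeds and seaweeds (mg kg-1 dry weight unless basis says otherwise).
# Ranged limits in the source material are split into explicit entries where a
# commodity split is known (e.g. Canadian feed Cd: equine vs other livestock);
# otherwise the strictest (lowest) bound is encoded and noted in `reference`.
version: 1
limits:
  - {jurisdiction: Australia/New Zealand, commodity: fish, metal: As, limit: 2, inorganic_only: true, basis: dw, reference: FSANZ}
  - {jurisdiction: Australia/New Zealand, commodity: fish, metal: Sn, limit: 250, inorganic_only: false, basis: dw, reference: FSANZ}
  - {jurisdiction: Australia/New Zealand, commodity: fish, metal: Pb, limit: 0.5, inorganic_only: false, basis: dw, reference: FSANZ}
  - {jurisdiction: Australia/New Zealand, commodity: seaweed, metal: As, limit: 1, inorganic_only: true, basis: dw, reference: FSANZ}
  - {jurisdiction: Australia/New Zealand, commodity: seaweed, metal: Sn, limit: 250, inorganic_only: false, basis: dw, reference: FSANZ}
  - {jurisdiction: Australia/New Zealand, commodity: vegetables, metal: Cd, limit: 0.1, inorganic_only: false, basis: dw, reference: "FSANZ; range 0.1-0.5, strictest bound"}
  - {jurisdiction: Australia/New Zealand, commodity: vegetables, metal: Pb, limit: 0.1, inorganic_only: false, basis: dw, reference: "FSANZ; range 0.1-0.3, strictest bound"}
  - {jurisdiction: Canada, commodity: equine feed, metal: Cd, limit: 0.2, inorganic_only: false, basis: dw, reference: "CFIA RG-8; low end of 0.2-0.4 feed range"}
  - {jurisdiction: Canada, commodity: livestock feed, metal: Cd, limit: 0.4, inorganic_only: false, basis: dw, reference: "CFIA RG-8; high end of 0.2-0.4 feed range"}
  - {jurisdiction: Canada, commodity: animal feed, metal: As, limit: 8, inorganic_only: false, basis: dw, reference: CFIA RG-8}
  - {jurisdiction: Canada, commodity: animal feed, metal: Pb, limit: 8, inorganic_only: false, basis: dw, reference: CFIA RG-8}
  - {jurisdiction: Canada, commodity: fish protein, metal: As, limit: 3.5, inorganic_only: false, basis: dw, reference: CFIA}
  - {jurisdiction: Canada, commodity: fish protein, metal: Pb, limit: 0.5, inorganic_only: false, basis: dw, reference: CFIA}
  - {jurisdiction: EU, commodity: seaweed, metal: Cd, limit: 3.0, inorganic_only: false, basis: dw, reference: EC}
  - {jurisdiction: EU, commodity: seaweed, metal: As, limit: 40, inorganic_only: false, basis: dw, reference: EC}
  - {jurisdiction: EU, commodity: seaweed, metal: As, limit: 0.2, inorganic_only: true, basis: dw, reference: "EC; inorganic As"}
  - {jurisdiction: EU, commodity: seaweed, metal: Pb, limit: 10, inorganic_only: false, basis: dw, reference: EC}
  - {jurisdiction: EU, commodity: calcareous algae, metal: As, limit: 10, inorganic_only: false, basis: dw, reference: EC}
  - {jurisdiction: EU, commodity: animal feed, metal: Cd, limit: 1, inorganic_only: false, basis: dw, reference: "2002/32/EC; range 1-10, strictest bound"}
  - {jurisdiction: EU, commodity: animal feed, metal: As, limit: 4, inorganic_only: false, basis: dw, reference: "2002/32/EC; range 4-10, strictest bound"}
  - {jurisdiction: EU, commodity: animal feed, metal: Pb, limit: 5, inorganic_only: false, basis: dw, reference: "2002/32/EC; range 5-40, strictest bound"}
  - {jurisdiction: FAO, commodity: fish and meats, metal: Sn, limit: 50, inorganic_only: false, basis: dw, reference: "FAO; range 50-250, strictest bound"}
  - {jurisdiction: FAO, commodity: fish and meats, metal: Pb, limit: 0.1, inorganic_only: false, basis: dw, reference: FAO}
  - {jurisdiction: FAO, commodity: plants and vegetables, metal: Cd, limit: 0.05, inorganic_only: false, basis: dw, reference: "FAO; range 0.05-0.4, strictest bound"}
  - {jurisdiction: FAO, commodity: plants and vegetables, metal: As, limit: 0.1, inorganic_only: false, basis: dw, reference: FAO}
  - {jurisdiction: FAO, commodity: plants and vegetables, metal: Sn, limit: 250, inorganic_only: false, basis: dw, reference: FAO}
  - {jurisdiction: FAO, commodity: plants and vegetables, metal: Pb, limit: 0.1, inorganic_only: false, basis: dw, reference: "FAO; range 0.1-1.5, strictest bound"}
  - {jurisdiction: Hong Kong/China, commodity: fish and shellfish, metal: Cd, limit: 2, inorganic_only: false, basis: dw, reference: HK/CN}
  - {jurisdiction: Hong Kong/China, commodity: fish and shellfish, metal: Pb, limit: 6, inorganic_only: false, basis: dw, reference: HK/CN}
  - {jurisdiction: Hong Kong/China, commodity: general foods, metal: Cd, limit: 0.2, inorganic_only: false, basis: ww, reference: HK/CN wet-weight basis}
  - {jurisdiction: Hong Kong/China, commodity: general foods, metal: Pb, limit: 0.3, inorganic_only: false, basis: ww, reference: HK/CN wet-weight basis}
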