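# Default reference tables: regulatory maximum limits (mg/kg edible tissue),
# oral reference doses (mg/kg-bw/day), consumption scenarios and consumer
# profiles.  Override any block by passing your own file with the same layout.
limits:
  - {element: As, authority: Brazil, ml: 1.0}
  - {element: As, authority: MERCOSUL, ml: 1.0}
  - {element: As, authority: Chile, ml: 1.0}
  - {element: As, authority: WHO/FAO (CODEX), ml: 0.5}
  - {element: Cd, authority: Brazil, ml: 1.0}
  - {element: Cd, authority: MERCOSUL, ml: 0.05}
  - {element: Cd, authority: Chile, ml: 0.05}
  - {element: Cd, authority: WHO/FAO (CODEX), ml: 0.5}
  - {element: Cu, authority: Chile, ml: 10.0}
  - {element: Se, authority: Chile, ml: 0.3}
  - {element: Pb, authority: Brazil, ml: 2.0}
  - {element: Pb, authority: MERCOSUL, ml: 0.3}
  - {element: Pb, authority: Chile, ml: 2.0}
  - {element: Pb, authority: FAO, ml: 0.2}
  - {element: Pb, authority: WHO/FAO (CODEX), ml: 0.3}
  - {element: Zn, authority: Chile, ml: 100.0}
rfds:
  - {element: Al, rfd: 0.286, source: ANVISA, status: active}
  - {element: As, rfd: 0.003, source: FAO/WHO, status: revoked}
  - {element: Cr, rfd: 0.045, source: ANVISA, status: active}
  - {element: Ni, rfd: 1.0, source: ANVISA, status: active}
  - {element: Fe, rfd: 3.47, source: ANVISA, status: active}
  - {element: Mn, rfd: 2.3, source: ANVISA, status: active}
  - {element: Cu, rfd: 6.935, source: ANVISA, status: active}
  - {element: Zn, rfd: 23.5, source: ANVISA, status: active}
scenarios:
  - {name: general, ingestion_rate: 63.0, population: general population}
  - {name: amazon, ingestion_rate: 416.39, population: high fish-intake region}
profiles:
  - {label: adult, body_weight: 70.0}
  - {label: child, body_weight: 15.0}
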