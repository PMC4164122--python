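# Acute isocapnic hypoxia at rest: 10 min of 9% O2 with alveolar CO2 held
# at its pre-step value by inspired CO2, then return to room air.
schema_version: 1
species: human
duration_s: 1080
environment:
  - {t: 0, fio2: 0.2094, fico2: 0.0, pb: 760}
  - {t: 180, fio2: 0.09, fico2: 0.0, pb: 760, isocapnic: true}
  - {t: 780, fio2: 0.2094, fico2: 0.0, pb: 760}
workload:
  - {t: 0, watts: 0}
solver:
  max_breaths: 6000
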