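schema_version: 1
species: human
duration_s: 180
environment:
  - {t: 0, fio2: 0.2094, fico2: 0.0, pb: 760}
workload:
  - {t: 0, watts: 0}
solver:
  max_breaths: 2000
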