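# Step to 360 W with uniform lung damage: 20% weight gain in every segment.
schema_version: 1
species: human
duration_s: 720
environment:
  - {t: 0, fio2: 0.2094, fico2: 0.0, pb: 760}
workload:
  - {t: 0, watts: 360}
damage:
  uniform: 0.20
solver:
  max_breaths: 6000
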