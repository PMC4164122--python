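# Step to 360 W with the volume-matched regional pattern: 38.1% weight gain
# confined to the right lung (52.5% of total volume), equivalent in
# volume-weighted mean to 20% uniform.
schema_version: 1
species: human
duration_s: 720
environment:
  - {t: 0, fio2: 0.2094, fico2: 0.0, pb: 760}
workload:
  - {t: 0, watts: 360}
damage:
  region: right
  dw: 0.381
solver:
  max_breaths: 6000
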