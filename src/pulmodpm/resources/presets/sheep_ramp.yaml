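# Incremental treadmill fatigue run in sheep: 9% grade, start 0.67 m/s,
# +0.22 m/s every 90 s, speed capped at 2.22 m/s.
schema_version: 1
species: sheep
duration_s: 1800
treadmill_ramp:
  start_m_s: 0.67
  increment_m_s: 0.22
  every_s: 90
  cap_m_s: 2.22
  grade_pct: 9
solver:
  max_breaths: 8000
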