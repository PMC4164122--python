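# Steady-state exercise at simulated altitude (hypoxia, 11.85% O2),
# workload steps 0-240 W.
schema_version: 1
species: human
duration_s: 1200
environment:
  - {t: 0, fio2: 0.1185, fico2: 0.0, pb: 760}
workload:
  - {t: 0, watts: 0}
  - {t: 300, watts: 60}
  - {t: 600, watts: 120}
  - {t: 900, watts: 240}
solver:
  max_breaths: 8000
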