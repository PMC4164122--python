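# pulmodpm

A breath-by-breath, anatomically structured pulmonary gas-exchange and
exercise physiology simulator, built to study how regional lung damage
(edema from blast, blunt trauma or chemical injury) degrades oxygen
transport and physical performance.

It is aimed at computational physiologists and injury-modelling groups who
need a whole-body closed-loop model — not a CT-derived subject-specific
mesh, and not a homogeneous two-compartment lung — with enough regional
structure that damage can be confined to one lung or to individual
segments.

## The model

**Anatomy.** The human lung is an asymmetric upper airway tree of 18
rigid, well-mixed compartments (trachea to segmental bronchi, Horsfield-
style morphometry) feeding 19 lung segments. Each segment has a conducting
dead-space compartment in series with a variable-volume alveolar
compartment and a serial capillary train (default n = 10 divisions). The
sheep model has 6 lobar compartments; the goat reuses sheep anatomy scaled
by body mass. Volumes scale linearly with body mass, membrane areas (and
hence diffusing capacities) with mass^(2/3).

**Gas transport.** Every airway compartment obeys an advective mass
balance `V dC/dt = V̇ (C_in − C)`, solved implicitly (backward Euler) root
to leaf on inhalation and leaf to root on exhalation. Alveolar
compartments exchange with capillary blood through Fick's law,
`ṁ = f_i D_L (P_Alv − P_c)`, with the segment's membrane-area fraction
f_i; capillary divisions advance by an implicit serial sweep with blood
gas contents tied to pressures through a Hill O2 dissociation curve
(P50 = 26.8 mmHg, n = 2.7) and a linearized CO2 curve. The O2 diffusing
capacity is workload- and PO2-dependent,

    D_L,O2 = −0.0078 P² + (0.3 + W/833) P + 76 + W/6   [ml/(mmHg·min)]

**Heterogeneity.** Regional ventilation and perfusion follow the classic
gravity gradients: per-percent-volume weights `−0.00031 h + 0.064`
(ventilation) and `−0.0009 h + 0.1` (perfusion) of segment height h (%
from lung base), renormalized over segments to partition total flow.

**Damage.** Injury is quantified as fractional lung weight gain ΔW per
segment. It maps to the two exchange impairments via the calibrated
coupling `shunt ≈ 0.15 · D_L-reduction`: a global venous-admixture shunt
proportional to the volume-weighted mean ΔW, and a per-segment D_L
reduction. Uniform and regional damage with equal mean ΔW share the same
shunt but differ in regional diffusion impairment — which is why regional
damage desaturates more during heavy exercise.

**Control and fatigue.** Minute ventilation follows a chemoreflex drive
(CO2 and SaO2 terms with a circulatory sensing delay and slow hypoxic
ventilatory decline), split into tidal volume and frequency with a fixed
35% inspiratory time fraction. Cardiac output and metabolism are linear in
VO2 and workload. An oxygen-deficit accumulator declares fatigue when
demand exceeds circulatory delivery capacity for long enough; its first
crossing is the time-to-fatigue endpoint.

## Worked example

```python
import pulmodpm as pm
from pulmodpm.simulate import steady_state

model = pm.build_human_lung(70)
summary, _ = steady_state(model, {"work_w": 0.0})
for k in ("ve_l_min", "q_tot_l_min", "p_a_o2_mmhg", "p_a_co2_mmhg", "sao2"):
    print(f"{k:>14s}: {summary[k]:.2f}")

damaged = pm.DamageState.uniform(19, shunt=0.095, dl_reduction=0.5)
summary_d, _ = steady_state(model, {"work_w": 100.0}, damage=damaged)
print("damaged PaO2 at 100 W: %.1f mmHg (SaO2 %.3f)"
      % (summary_d["p_a_o2_mmhg"], summary_d["sao2"]))
```

prints

```
      ve_l_min: 7.38
   q_tot_l_min: 6.50
   p_a_o2_mmhg: 93.61
  p_a_co2_mmhg: 40.05
          sao2: 0.97
damaged PaO2 at 100 W: 45.8 mmHg (SaO2 0.809)
```

A healthy resting adult settles at a minute ventilation of ~7.4 L/min,
arterial PO2 ~94 mmHg and PCO2 ~40 mmHg — inside the normal physiologic
envelope. The same lung carrying a 9.5% shunt and a 50% diffusing-capacity
reduction (moderate uniform edema) becomes markedly hypoxemic during
100 W exercise.

Scenarios can also be run from the shell:

```bash
pulmodpm presets                      # list shipped protocols
pulmodpm run --preset hypoxia_rest --out hypoxia.csv
pulmodpm run --config my_scenario.yaml --out run.csv --tidy
pulmodpm validate-config my_scenario.yaml
```

Shipped presets include isocapnic hypoxia at rest (`hypoxia_rest`),
exercise at simulated altitude (`altitude_exercise`), the incremental
treadmill fatigue run in sheep (`sheep_ramp`), and the uniform vs regional
damage comparison at 360 W (`damage_uniform`, `damage_regional`).

## Layout

| Module | Contents |
| --- | --- |
| `pulmodpm.anatomy` | species lung builders, allometric scaling, morphometric tables |
| `pulmodpm.distribution` | gravity-dependent ventilation/perfusion fractions |
| `pulmodpm.gas_transport` | airway/alveolar/capillary exchange steps, D_L relation, mixing |
| `pulmodpm.blood` | O2/CO2 dissociation curves and inversions |
| `pulmodpm.damage` | weight-gain → (D_L reduction, shunt) mapping, calibration fits |
| `pulmodpm.control` | ventilatory drive, breathing pattern, metabolism, fatigue |
| `pulmodpm.simulate` | the breath engine, steady-state and scenario drivers |
| `pulmodpm.config` / `pulmodpm.cli` | scenario schema, presets, command line |
| `pulmodpm.fixtures` | toy lungs and synthetic calibration data |

See `docs/methods.md` for the governing equations, parameter tables,
numerical scheme and known limitations.
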