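# Methods

This note documents the governing equations, parameter choices, numerical
scheme and known limitations of `pulmodpm`. Units throughout: pressures in
mmHg, volumes in ml (BTPS for gas spaces), gas amounts in ml STPD, flows in
ml/s inside the solver and L/min at API boundaries, diffusing capacities in
ml/(mmHg·min).

## Anatomic structure

The human lung is represented by an 18-compartment asymmetric upper airway
tree (trachea → segmental bronchi) and 19 lung segments. Airway compartment
dimensions are shipped as a TSV table (`resources/human_airways.tsv`);
compartment volumes are cylinder volumes π d² l / 4. The source morphometry
prints lengths/diameters in a table headed "cm", but the values (trachea
100 × 16) are physiologic only in millimetres; both species tables are read
as mm.

Tree connectivity and the assignment of segments to terminal bronchi are
not part of the printed tables; the shipped adjacency map
(`human_airway_tree.tsv`, `human_segment_map.tsv`) is an adopted
reconstruction with the following properties: one root (trachea, id 1), an
acyclic binary-ish tree, separable left/right subtrees under the two main
bronchi, and exactly one feeding terminal per segment. In the combined tree
the per-segment conducting dead-space compartment is the true leaf and
feeds exactly one segment; upper-tree terminals may parent several of them
(with 18 upper compartments and 19 segments a one-to-one mapping is
impossible).

The left/right partition places segments {19–26, 29, 34} in the right lung,
giving a right-lung volume fraction of 0.525. This reproduces the
regional-damage conversion used in the damage scenarios: a 20% uniform
weight gain concentrated in the right lung alone becomes 20%/0.525 = 38.1%
per right-lung segment.

Per-segment conducting dead space (the generations between the upper tree
and the alveoli) has no printed dimensions; each segment carries a single
series compartment, sized so the total anatomic dead space is 150 ml at the
70 kg human reference (the upper tree supplies ≈35 ml, the remainder is
distributed in proportion to segment volume). The target is a config
parameter.

The sheep lung has 6 lobar alveolar compartments (ids 19–24, two left and
four right) fed through a 6-compartment airway tree; lobar volume
percentages are renormalized from a printed column that sums to 100.1%.
Lobar heights (% from base) are not printed anywhere; the shipped values
(`sheep_lobe_heights` column in `sheep_lobe_map.tsv`) are plausible
standing-posture estimates and are exposed for editing. The goat uses sheep
anatomy scaled by body mass.

Reference body masses: human 70 kg, sheep 40 kg, goat 30 kg. Allometric
scaling multiplies volumes by the mass ratio and area-like quantities
(D_L) by the mass ratio to the 2/3 power; the scale factor is always taken
against the model's reference mass, so repeated scaling compounds.

Quantities without a printed value, chosen once as physiologic defaults and
config-exposed: total pulmonary capillary volume 75 ml (human reference,
scaled linearly), end-expiratory alveolar volume 3000 ml, baseline
(healthy) shunt 0.02.

## Gas transport

Airway compartments are rigid and well-mixed:
`V dC/dt = V̇ (C_in − C)`, with the airway-wall uptake term neglected for
the respiratory gases. The inlet is the parent on inhalation and the mixed
daughters on exhalation. Flow through a compartment equals the sum of the
alveolar flows of its subtended segments, so flow is conserved by
construction.

Alveolar compartments are variable-volume:
`d(VC)/dt = V̇ C_in − f_i D_L (RT·C − P_c)` on inhalation (outflow term on
exhalation), where RT = 863 mmHg per (ml STPD/ml BTPS) converts alveolar
concentration to partial pressure and f_i is the segment's membrane-area
fraction (taken equal to its volume fraction). `P_c` is the mean capillary
pressure over the segment's train, which makes the alveolar-side flux the
exact sum of the per-division fluxes.

Capillary trains discretize each segment's capillary bed into n = 10 serial
well-mixed divisions (config). Division i obeys
`dC_i/dt = (n Q_c / V_cap f_k)(C_{i−1} − C_i) + (D_L/V_cap)(P_Alv − P_c,i)`
with `P_c,i` recovered from content through the dissociation curve. A
convergence check (doubling n) is part of the test suite's oracle
comparisons; at default conditions the outlet pressure is insensitive to n
because end-capillary blood is close to diffusion equilibrium.

The O2 diffusing capacity follows the empirical workload/PO2 relation
`D_L,O2 = −0.0078 P² + (0.3 + W/833) P + 76 + W/6`. Two guards make the
relation usable inside a closed loop: the evaluation pressure is clamped at
110 mmHg and the result floored at 1 ml/(mmHg·min). The downward-opening
quadratic becomes negative above P ≈ 128 mmHg when extrapolated; without
the clamp, hypoxic hyperventilation raises alveolar PO2, collapses D_L to
the floor, and locks the loop in an artificial hypoxemic state. The clamp
treats the quadratic as valid only on the physiologic alveolar range; both
guards are arguments of `dl_oxygen`. D_L for CO2 is constant at
800 ml/(mmHg·min). Per-segment D_L is the whole-lung value scaled by the
(mass/70)^(2/3) area factor and by (1 − D_L-reduction) of that segment;
damage reduction is applied to both gases (the edema fluid is a barrier to
both; CO2's 20-fold larger D_L keeps CO2 retention minimal, as observed).

Blood chemistry is a Hill O2 curve (P50 26.8 mmHg, exponent 2.7, capacity
1.34 ml/g, Hb 15 g/dl, dissolved β 3.0e−5 ml/(ml·mmHg)) and a linearized
CO2 curve C = 0.252 + 0.0057 P, both strictly increasing and inverted by
safeguarded Newton iteration (bisection fallback, brackets [0, 1500] mmHg).
A `linear_o2_beta` mode replaces the O2 curve by C = βP for analytic
oracles.

Arterial blood is the flow-weighted mean of end-capillary contents mixed
with a venous-admixture shunt:
`C_a = (1 − s) Σ f_Q,k C_end,k + s C_v`. Recombination order (capillary →
lobar → systemic) does not matter for conserved contents, so a single
weighted mean is used.

## Ventilation/perfusion distribution

Fractional flows derive from segment height h (% from lung base):
ventilation weight `−0.00031 h + 0.064` and perfusion weight
`−0.0009 h + 0.1` per percent lung volume. A segment's fraction is its
weight times volume fraction, renormalized — the raw weighted volumes do
not sum to unity (5.290 and 6.78 on the human table), because the height
relations are regressions of normalized regional rates, not a partition.
Fractions are computed once per anatomy and are not altered by damage,
which acts only through D_L and shunt.

## Damage model

Injury is a per-segment fractional lung weight gain ΔW, static during a
simulation (injury at steady state, simulated time shorter than recovery).
Two coupled impairments follow:

* global shunt  `s = s_baseline + k_w · mean_vol(ΔW)` (clipped at 1, with a
  warning on saturation);
* per-segment D_L reduction `r_k = clip(k_w ΔW_k / 0.15, 0, 1)`, inverting
  the calibrated coupling `shunt ≈ 0.15 · D_L-reduction` regionally.

By construction, uniform damage reproduces the 0.15 coupling exactly, and
regional damage with the same volume-weighted mean ΔW produces the same
global shunt while concentrating the diffusion impairment. The
weight-gain-to-shunt slope k_w is never printed in the source calibration;
the default 0.375 is a synthetic reconstruction chosen so that a 20%
uniform weight gain yields a 7.5% damage shunt and a 50% D_L reduction —
plausible mid-range values — and is deliberately config-exposed.
Quantitative work should set k_w explicitly.

`fit_shunt_dl` reproduces the calibration procedure: for each experimental
condition it minimizes the squared error between modelled and observed
steady-state arterial PO2 over (shunt, D_L-reduction) ∈ [0,1]², using
`scipy.optimize.least_squares` with a steady-state predictor that caches
converged engine states per workload as warm starts. Identifiability
requires at least one low workload in the observation set: at rest the
shunt dominates arterial PO2 while diffusion limitation is negligible; at
heavy exercise with severe damage the arterial PO2 saturates toward a
delivery-limited plateau that carries little gradient information.
`fit_damage_line` is ordinary least squares (optionally through a pinned
intercept).

## Control, metabolism and fatigue

The prior whole-body control laws are re-created as simple documented
forms; every gain is config-exposed and scales linearly with body mass
except per-watt coefficients (workload is absolute):

* Ventilatory drive
  `VE* = VE_rest + G_CO2 [P_aCO2 − B]₊ + G_hyp [S_ref − SaO2]₊ (1 − a) + k_ex W`
  with VE_rest 6 L/min, G_CO2 1.5 L/min/mmHg, B 39 mmHg, G_hyp 120 L/min
  per unit saturation, S_ref 0.92, k_ex 0.25 L/min/W. VE follows the target
  through first-order dynamics (τ_up 20 s, τ_down 90 s). The controller
  senses arterial values delayed by 15 s (lung-to-chemoreceptor transit).
  `a` is the hypoxic-ventilatory-decline adaptation: a slow first-order
  state (τ 180 s) rising toward 0.4 of the hypoxic term, graded over the
  first 5% of desaturation. The delay and the decline together produce the
  observed hypoxic-step shape: an early ventilation peak followed by a
  monotone decay to a plateau above baseline.
* Breathing pattern: inspiratory fraction fixed at 0.35;
  V_T = 250 + (125/3)·VE ml up to a cap of 60% of a 4600 ml vital
  capacity, frequency carrying further increases — monotone, continuous,
  and giving the canonical (500 ml, 12/min) split at VE = 6 L/min.
* Metabolism: VO2 = 0.3 + 0.0116·W L/min, VCO2 = 0.85·VO2.
* Cardiac output: Q = 5 + 5·VO2 L/min.
* Isocapnic clamping is a per-breath PI controller on the inspired CO2
  fraction holding arterial PCO2 at its pre-step value.
* Fatigue: delivery capacity is `eff · Q · (C_aO2 − C(P_v,min))` with
  P_v,min 15 mmHg (maximal extraction); the deficit accumulator integrates
  max(0, demand − delivery) and fatigue is declared above D_max
  (1000 ml O2 at 70 kg). After fatigue the effective workload drops to the
  sustainable power. Treadmill work converts speed and grade as
  `W = m v (c + g·grade/100)` with level-cost c = 2 W/(kg·m/s); the
  incremental sheep protocol (0.67 m/s start, +0.22 m/s per 90 s, cap
  2.22 m/s, 9% grade) ships as a preset.

The tissue/venous store is one well-mixed pool of 70 ml/kg for both gases.
This is adequate for O2 but understates the body's CO2 stores, so CO2
transients settle unrealistically fast; steady states are unaffected.

## Numerical scheme

Fixed step dt = 10 ms (config). Within a step the splitting order is fixed:
airway transport sweep (implicit, level-by-level along the tree), alveolar
update (implicit in concentration, conservative in the stored amount V·C),
capillary serial sweep (implicit per division, Newton in pressure with
closed-form path for affine curves), then arterial mixing and the tissue
pool (explicit; its time constant is minutes). Capillary trains advance on
a 5× substep of dt by default. Backward Euler makes every transport update
unconditionally stable and bounded between the old and inlet values; the
suite stress-tests dt up to one inspiration time. The conservative alveolar
form makes per-breath gas accounting telescope to machine precision.

Steady-state detection requires the per-breath relative change of arterial
PO2 and PCO2 to stay below 0.1% (config) for 5 consecutive breaths. The
steady-state driver optionally accelerates convergence by relaxing the
mixed-venous pool toward its Fick value during the first 25 breaths only —
sustained acceleration can excite a spurious limit cycle through the
sensing delay, while the bounded version leaves the fixed point unchanged
and lets the natural dynamics settle the remainder.

Scenario runs are breath-resolved and fully deterministic: identical
configurations produce bit-identical time series. The only randomness in
the package is the synthetic calibration-data generator, driven by one
explicit seed.

Problem sizes used by the test suite and reference scripts: steady states
run tens of breaths; scenario protocols minutes to tens of minutes of
simulated time; heavy comparisons (fatigue ramps, calibration recovery) use
dt = 20–25 ms, which changes steady-state arterial PO2 by well under
0.1 mmHg relative to the 10 ms default.

## Synthetic data

`fixtures.make_fixture_lung` builds miniature lungs (one tracheal
compartment, equal-volume segments at chosen heights, small dead space) for
symmetry tests and analytic oracles. `fixtures.generate_calibration_data`
draws shunt-vs-damage points on a chosen line with Gaussian noise — it
stands in for figure-read experimental calibration sets, and its role in
tests is parameter-recovery of the fitters, not emulation of animal
variability. What passing tests show: internal consistency (conservation,
oracle agreement, monotone damage response, recovery of planted
parameters) and qualitative reproduction of the experimental shapes
(hypoxic ventilation transient, damage-ordered arterial O2, fatigue-time
ordering, regional vs uniform contrast). They do not validate the model
against real subject data.

## Known limitations

* The original whole-body controller and fatigue equations are published
  elsewhere; the forms here are re-creations tuned to physiologic
  envelopes, so only qualitative behaviors are comparable.
* No Bohr/Haldane interaction, temperature/pH shifts, nitrogen exchange, or
  hypoxic pulmonary vasoconstriction; perfusion fractions are static.
* Airway mechanics (resistance, compliance) and generation-by-generation
  structure of the conducting region are not modelled.
* The upper-airway connectivity, sheep lobar heights and the k_w slope are
  adopted reconstructions, documented above and exposed in configuration.
* Extreme damage (D_L reduction near 1) at exercise produces profound,
  delivery-limited hypoxemia; the model is not meant to be predictive in
  that regime.
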