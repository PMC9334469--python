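# Methods

## The virtual lung

The lung is a population of N = 500 identical-size alveolar units with
quasi-static threshold behavior: a unit opens during inspiration when
peak inspiratory pressure (PIP) reaches its opening pressure and
collapses at end-expiration when PEEP is below its closing pressure.
Closing sits below opening (healthy gap 1–3 cmH2O, opening ~Normal(3, 2)
cmH2O clipped at 0.5), so a pressure sweep traces a hysteresis loop.
Units can be open, closed, or consolidated; consolidation is absorbing
(no healing within the six-hour protocol). There is no intra-breath
flow dynamics: all endpoints of interest are per-breath summaries, so
each breath is resolved as open → measure → close → injure. The I:E
ratio is carried as metadata only.

Dynamic respiratory-system compliance is

    Crs = C_stiff + C_scale · f_open · d(PEEP)

with `C_stiff` = 4 mL/cmH2O (tissue/chest-wall floor), `C_scale`
proportional to body weight (0.52 ± 0.02 mL/cmH2O per kg, clipped), and
`f_open` the end-inspiratory open fraction. The factor
`d(PEEP) = clip(1 − 0.075·(PEEP − 12), 0.3, 1)` de-rates the tidal slope
when the lung is held at high end-expiratory volume: overdistension acts
on the operating point (end-expiratory distension), which is why a lung
ventilated at PEEP 2 with a huge tidal volume can show the same dynamic
compliance as one at PEEP 15 with a small one. Delivered tidal volume is
`Crs · ΔP`.

Ventilation modes follow two contracts. Fixed driving pressure applies
the commanded ΔP directly. Volume guarantee recomputes
`ΔP = V_T,target / Crs` once per breath from a compliance estimate
smoothed over recent breaths (exponential average, weight 0.3), slews it
by at most 2 cmH2O per breath, and caps PIP at 60 cmH2O — mimicking how
clinical volume-guarantee servos avoid breath-to-breath oscillation.

## Injury processes

**Lavage (surfactant depletion).** Each saline cycle adds a
truncated-normal increment (mean 1.5, SD 0.6 cmH2O) to every
non-consolidated unit's opening pressure, and a fraction of that
increment to its closing pressure, preserving closing < opening.
Depletion is heterogeneous: a susceptible quarter of the units (the
dependent regions) amplifies the opening increment by 1.5–2.1× and
receives a larger closing fraction (0.42 vs 0.15), so lavage widens the
opening/closing hysteresis overall while building a subpopulation whose
closing pressures reach the low teens — these units are what a
decremental PEEP trial titrates against. Both critical pressures
saturate toward structural asymptotes (44 cmH2O opening, 20 cmH2O
closing; increments taper linearly over the upper half of the range),
which keeps the post-lavage lung recruitable at the maneuver pressures
regardless of how many cycles a given animal needed. Each cycle also
removes 1.5 % of `C_scale` and adds a persistent 0.04 of alveolar
dead-space fraction (edema and surfactant loss cause high-V/Q regions
that do not recruit away). Cycles repeat, each followed by a 10-min
qualification window at V_T 6 mL/kg / PEEP 6 / FiO2 1.0, until every
breath of a window reads PaO2 < 100 mmHg; the cycle count is emergent
(typically 12–16) and the qualifying PaO2 lands near 80–95 mmHg.

**Ventilator-induced injury.** Two per-breath channels, both inactive
under protective settings by construction of their thresholds:

* *Atelectrauma*: units that opened and re-closed within the same breath
  ("cyclic") consolidate with probability 1×10⁻⁴ per unit-breath, and the
  survivors' closing pressures creep upward by 4.8×10⁻³ cmH2O per cyclic
  unit-breath (opening pressures by 40 % of that), with the same
  structural saturation as lavage. Destabilization-dominant drift is
  deliberate: ongoing shear injures the collapse side of the hysteresis
  more than the reopening side, and it is what raises the injured arm's
  best-compliance PEEP from 12 to 16 cmH2O without making the lung
  unrecruitable at maneuver pressures.
* *Volutrauma*: open units whose share of the tidal volume exceeds 2.5×
  the nominal per-unit tidal volume (defined at full aeration and the
  reference ΔP of 14 cmH2O) consolidate with probability 8×10⁻⁵ per
  unit-breath. At 17 mL/kg with a partially closed lung the per-unit
  strain is ≈3–4× nominal; at 6 mL/kg it stays near 1×.

Three hours of 17 mL/kg / PEEP 2 / RR 12 ventilation yields a
consolidated fraction of ≈0.27–0.34, while the protective arm stays
below 0.02 over its entire course.

## Gas exchange

Quasi-steady, recomputed every breath. Shunt is a fixed venous
admixture (0.06, matching baseline PaO2 ≈ 550–580 mmHg at FiO2 1.0) plus
perfusion to non-aerated units attenuated by hypoxic vasoconstriction
(factor 0.7); consolidated units are additionally down-weighted to 0.35
of their perfusion share, since chronic consolidation diverts flow far
more effectively than acute cyclic collapse. Aeration for gas exchange
is the end-inspiratory open fraction (oxygen uptake happens while units
are open). Alveolar ventilation is
`RR · max(V_T − V_D,airway, 0) · (1 − f_ds)` with airway dead space
2.2 mL/kg and an alveolar dead-space fraction
`f_ds = min(0.58, 1.0·((1 − f_open) + f_consolidated) + ds_lavage)`.
PaCO2 follows `863·VCO2/VA` capped to [10, 200] mmHg; pH follows
Henderson–Hasselbalch at a fixed bicarbonate of 24 mmol/L (no metabolic
compensation over six hours, making the controller's acidosis pathway a
deterministic function of PaCO2). Arterial PO2 solves the Berggren
mixing relation with mixed-venous content from the Fick principle at
fixed VO2 (3.5 mL/kg/min); substituting Fick reduces the fixed point to
a closed form in O2 content, which is then inverted through the
Severinghaus curve by bisection (tolerance ≪ 0.1 mmHg). The
Severinghaus form was chosen over a Hill fit for its accuracy near both
asymptotes; no temperature or Bohr correction is applied. Cardiac
output is `CO_base · max(0.3, 1 − 0.015·(PEEP − 5))` — venous return
falls with intrathoracic pressure — which makes oxygen delivery peak at
a lower PEEP than PaO2. A pig dies when PaO2 stays below 30 mmHg for
10 consecutive minutes; this rule is a placeholder, as the source
experiments report deaths without stating a criterion.

## Controller and protocol

Controller constants are the protocol's published rules (SpO2 band
88–95 %, VT ladder 6/5/4 mL/kg on PIP > 30 strictly, RR ±5/min within
[10, 35] on a 30-min pH schedule against [7.30, 7.45]). Where timing was
unspecified, the oxygenation input is evaluated every 30 s with a 5-min
dwell between table moves (prevents oscillation), single-step moves
only, and no automatic VT re-escalation (conservative: the rule set
describes only reductions). The minimum RR of 10/min mirrors the stated
maximum. The "higher PEEP / lower FiO2" table ships as an editable
14-row config rather than being hard-coded. At each protocol hand-over
to closed-loop ventilation the controller starts at the most invasive
table row and walks down — the safe direction after an injury phase.

Protocol constants follow the study design: recruitment ladder
PEEP 12→16→20→24 at ΔP 20 (the stated 2–4 cmH2O rungs, taken as 4),
5 breaths per rung, then 5 cycles at PIP 50 / PEEP 24, then 5 min at
PEEP 15 / V_T 6 mL/kg ending in the standardized assessment; volume
history 10 breaths at 10 mL/kg / PEEP 0 / RR 10 followed by a 5-s
disconnection that collapses every unit with positive closing pressure;
decremental trial at constant ΔP 14 / RR 20 / FiO2 1.0, ascent
12→24 by 4 (5 cycles each), descent 24→6 by 2 with 10 min per step
(simulated as 200 breaths), measurement at the end of each descent step,
stop at PEEP 6 or P/F < 80. Only descent steps count as measurements,
and trial FiO2 is taken as 1.0 (implied by the P/F stopping rule in the
post-lavage context). Group-level best PEEP is the argmax of the
across-animal mean curve over PEEP levels measured in every animal; ties
break toward the lower PEEP (less exposure for equal benefit).

## Statistics

The relative treatment effect of a subgroup is
`(mean pooled mid-rank − 1/2)/N`; its size-weighted mean across
subgroups is exactly 1/2, and it equals the pairwise-counting definition
(probability that a pooled draw is smaller than a subgroup draw, ties
counted half), which the tests verify by enumeration. The Mann–Whitney
comparison uses the exact permutation distribution of U for combined
n ≤ 12 (valid under ties) and the tie-corrected normal approximation
with continuity correction above that. The longitudinal ANOVA-type
testing used alongside these statistics in the source study is out of
scope; only the descriptive RTE and the two-sample comparison are
provided.

## Calibration and what the synthetic cohort does and does not show

Free parameters (unit-population shape, injury rates, dead-space gain,
hemodynamic slope) were calibrated once so that the default six-pig
cohort reproduces the study-level pattern: baseline compliance in the
22–36 mL/cmH2O band, lavage qualifying near PaO2 80–95 mmHg after
12–16 cycles, trial-1 best-compliance PEEP of 12 cmH2O with
best-oxygenation PEEP 4 cmH2O higher, protective-arm trials reaching the
PEEP 6 floor with post-maneuver P/F above 300 mmHg, and the injurious
arm showing best-compliance PEEP 16 cmH2O, hypoxemic trial termination,
post-maneuver P/F below 300 mmHg and roughly triple the phase-1
mechanical power. These group-level locations are stable across cohort
seeds because the lavage stopping criterion pins severity and the
structural saturation bounds the tails.

Known mismatches, accepted as calibration compromises: simulated
hypercapnia overshoots the animal data at the severe end (the PaCO2 cap
of 200 mmHg is reached during qualification and at the highest trial
steps, where real animals ran 80–130 mmHg), trial compliance magnitudes
run ~20–30 % below the animal values in the injured arm, and the
automated arm settles at a somewhat higher equilibrium PEEP and lower
FiO2 than the animals did. The cohort also omits known features of real
animals: no pig-to-pig variation in hemoglobin or metabolic rate beyond
body-weight scaling, no pulmonary-artery pressure or vascular-resistance
model (only the cardiac-output–PEEP response), no edema or inflammation
dynamics, and no spontaneous breathing. Passing tests therefore
demonstrate that the mechanisms and protocol logic reproduce the
qualitative physiology and the group-level titration landmarks — not
that the simulator predicts individual-animal trajectories.

## Numerical choices and problem sizes

500 units per lung keeps unit-sampling noise in group curves well below
the decision margins (SD of an open-fraction estimate ≈ 0.02). The
default study size is six pigs per arm, run breath-by-breath
(~20,000 breaths per pig); a full two-arm cohort simulates in roughly
ten seconds. Scaled-down phases used in some tests and examples shorten
phases, never alter rules. All randomness flows from
`numpy.random.default_rng` seeds spawned per pig, so reruns are
byte-identical; the content–PO2 inversion is deterministic bisection;
degenerate inputs (zero VCO2, fully consolidated lungs, dead animals)
are exercised in the test suite.
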