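# ventsim

Closed-loop mechanical-ventilation simulation of a two-hit porcine lung
injury model: saline-lavage surfactant depletion followed by either
protective (automated, ARDSNet-style) or injurious (high tidal volume,
low PEEP) ventilation.

Lavage-only animal models of hypoxemic lung failure recover too easily —
one recruitment maneuver restores oxygenation — which limits their value
for testing ventilation strategies. Adding a period of injurious
ventilation after lavage produces a persistently low-recruitability
injury whose titrated "best PEEP" sits higher. `ventsim` reproduces this
whole experimental workflow in silico so that protocol logic, closed-loop
controllers and titration analyses can be exercised end-to-end on
synthetic animals.

## What is inside

* **`ventsim.pig`** — a virtual pig whose lung is a population of
  threshold-behaved alveolar units. A unit opens during inspiration once
  peak pressure reaches its opening pressure and collapses at
  end-expiration when PEEP is below its closing pressure; the spread
  between the two produces hysteresis and recruitment-maneuver
  responsiveness. Saline lavage raises critical pressures
  (heterogeneously — a susceptible subpopulation responds more);
  injurious ventilation consolidates units through cyclic
  opening/closing (atelectrauma) and tidal overdistension (volutrauma)
  and destabilizes the survivors. Dynamic compliance is
  `Crs = C_stiff + C_scale · f_open · d(PEEP)` with an overdistension
  de-rating `d` at high end-expiratory pressure.
* **`ventsim.gas`** — closed-form gas exchange: alveolar gas equation,
  Severinghaus oxyhemoglobin dissociation curve, Berggren venous-admixture
  mixing solved for arterial PO2, `PaCO2 = 863·VCO2/VA`,
  Henderson–Hasselbalch pH, oxygen delivery.
* **`ventsim.controller`** — the automated protective-ventilation
  algorithm: SpO2 (target 88–95 %) moves one step along the
  "higher PEEP / lower FiO2" table; tidal volume steps 6 → 5 → 4 mL/kg
  when PIP exceeds 30 cmH2O; a 30-min arterial pH sample moves the
  respiratory rate ±5/min within [10, 35] when pH leaves [7.30, 7.45].
* **`ventsim.protocol`** — the experiment engine: 60-min baseline with a
  PaCO2 servo, lavage repeated until PaO2 stays below 100 mmHg for
  10 min, stepwise recruitment maneuvers to PIP 50 cmH2O, volume-history
  standardization, decremental PEEP trials (24 → 6 cmH2O by 2, constant
  driving pressure 14, 10 min per step, stop at PEEP 6 or P/F < 80), and
  the full two-arm study (3 h protective or injurious, then 3 h
  protective in both arms, with recruitment + trial after lavage and
  after each phase).
* **`ventsim.power`** — mechanical power of pressure-controlled
  ventilation, `M_P = 0.098 · RR · V_T · (ΔP + PEEP)` (V_T in liters).
* **`ventsim.analysis`** — best-PEEP identification (argmax of dynamic
  compliance, PaO2 or oxygen delivery over a trial; group version on the
  across-animal mean curve), recovery-from-lavage percentages, relative
  treatment effects from pooled mid-ranks, exact-permutation
  Mann–Whitney comparisons, and cohort summary tables.
* **`ventsim.io`** — plain-text readers/writers (per-breath CSV, trials
  CSV, summary JSON, YAML calibration configs; defaults shipped in
  `ventsim/data/defaults.yaml`).

The package is a library: the importable API plus the short narrative
scripts in `examples/` are the interface.

## Worked example

`python examples/04_peep_trial_best_peep.py` lavages a 46-kg pig to the
injury criterion, recruits it, and runs a decremental PEEP trial:

```
PEEP  Crs[mL/cmH2O]  PaO2[mmHg]  CO[L/min]  DO2[mL/min]
  24            9.3         278       3.09          439
  20           11.1         292       3.35          477
  16           16.3         414       3.60          528
  14           17.4         313       3.73          535
  12           17.9         184       3.86          537
   8           17.2         159       4.12          569
   6           15.4          88       4.25          562
terminated: min_peep
best PEEP by max_crs  :   12 cmH2O (value 17.9)
best PEEP by max_pao2 :   16 cmH2O (value 414.0)
best PEEP by max_do2  :    8 cmH2O (value 568.9)
```

Reading the columns: compliance peaks at PEEP 12 cmH2O — above that,
overdistension flattens the tidal pressure–volume slope; below it,
unstable units collapse. Arterial PO2 peaks one ladder level higher
(16 cmH2O) because shunt keeps falling after the compliance optimum,
while oxygen delivery peaks lower still because cardiac output rises as
PEEP falls. This compliance-versus-oxygenation split, and its widening
after injurious ventilation (best compliance PEEP 12 vs 16 cmH2O between
arms), is the model's central behavior; `examples/05_two_arm_study.py`
shows the two-arm contrast with rank-based statistics.

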