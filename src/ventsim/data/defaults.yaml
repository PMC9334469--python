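# Default calibration shipped with ventsim.
#
# injury: lavage and ventilator-induced injury mechanism parameters
# (see ventsim.pig.InjuryParams for field-by-field documentation).
# peep_fio2_table: the "higher PEEP / lower FiO2" escalation ladder used
# by the closed-loop controller, ordered by invasiveness.

injury:
  lavage_shift_mean: 1.5        # cmH2O added to opening pressures per cycle
  lavage_shift_sd: 0.6
  lavage_closing_frac: 0.15     # closing shift as fraction of opening shift
  lavage_closing_frac_het: 0.42 # same, susceptible subpopulation
  lavage_compliance_loss: 0.015 # fractional compliance loss per cycle
  lavage_deadspace_per_cycle: 0.04
  lavage_closing_cap: 20.0      # cmH2O structural asymptote, closing
  lavage_opening_cap: 44.0      # cmH2O structural asymptote, opening
  lavage_het_frac: 0.25         # susceptible fraction of units
  lavage_het_mult: [1.5, 2.1]   # susceptibility multiplier range
  cyclic_consolidation_prob: 1.0e-4
  cyclic_pressure_shift: 4.8e-3 # cmH2O destabilization per cyclic unit-breath
  cyclic_shift_opening_frac: 0.4
  overdistension_strain_threshold: 2.5
  overdistension_consolidation_prob: 8.0e-5
  shunt_hpv_factor: 0.7
  consolidated_perfusion_factor: 0.35

peep_fio2_table:
  - [0.3, 5]
  - [0.3, 8]
  - [0.3, 10]
  - [0.3, 12]
  - [0.3, 14]
  - [0.4, 14]
  - [0.4, 16]
  - [0.5, 16]
  - [0.5, 18]
  - [0.5, 20]
  - [0.8, 20]
  - [0.9, 22]
  - [1.0, 22]
  - [1.0, 24]
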