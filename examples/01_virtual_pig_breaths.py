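"""Ventilate one healthy virtual pig and watch per-breath mechanics.

Builds a 46-kg pig, delivers two minutes of volume-guaranteed pressure
control (VT 6 mL/kg, PEEP 7), and prints the realized mechanics and the
quasi-steady blood gas of the final breath.
"""

import ventsim as v

pig = v.make_pig(bw=46.0, seed=1)
settings = v.VentSettings(mode="PCV_VG", fio2=1.0, peep=7.0, rr=16.0, vt_target=6.0)

t = 0.0
for _ in range(32):  # two minutes at 16/min
    _, rec = v.step_breath(pig, settings, t)
    t += 60.0 / settings.rr

print(f"PIP {rec.pip:5.1f} cmH2O   dP {rec.dp:4.1f} cmH2O   VT {rec.vt_ml:5.0f} mL")
print(f"Crs {rec.crs_dyn:5.1f} mL/cmH2O   MP {rec.mp:4.1f} J/min")
print(f"PaO2 {rec.pao2:5.0f} mmHg   PaCO2 {rec.paco2:4.0f} mmHg   pH {rec.ph:4.2f}")
print(f"end-expiratory aeration {v.aeration_fraction(pig):.2f}")

# A healthy lung is almost fully aerated, so compliance sits near its
# full-aeration value (~25-30 mL/cmH2O at this size), arterial PO2 at
# FiO2 1.0 runs 500-600 mmHg, and CO2 is normal for a 16/min rate.
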