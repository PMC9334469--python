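"""Mechanical power of pressure-controlled ventilation.

Uses the simplified pressure-controlled-ventilation estimate

    M_P [J/min] = 0.098 * RR * VT * (dP + PEEP)

with VT in liters and pressures in cmH2O.  The 0.098 factor converts
cmH2O * L to joules.  This form assumes decelerating-flow pressure
control; the volume-controlled (constant-flow) formulation is a different
equation and is out of scope here.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["MP_FACTOR", "mechanical_power", "phase_mp_summary"]

MP_FACTOR = 0.098


def mechanical_power(rr: float, vt_l: float, dp: float, peep: float) -> float:
    """Per-breath mechanical power in J/min.

    ``vt_l`` must be in liters.  Linear in each argument; depends on the
    pressures only through their sum dP + PEEP.
    """
    if min(rr, vt_l, dp, peep) < 0:
        raise ValueError("mechanical power inputs must be non-negative")
    return MP_FACTOR * rr * vt_l * (dp + peep)


def phase_mp_summary(mp_values: Iterable[float]) -> tuple[float, float]:
    """Mean and (population) SD of per-breath mechanical power over a window."""
    arr = np.asarray(list(mp_values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty mechanical-power window")
    return float(arr.mean()), float(arr.std())
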