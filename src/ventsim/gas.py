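"""Closed-form pulmonary gas-exchange calculations.

Converts a lung's aeration state and the current ventilator settings into
arterial blood gases, oxygen saturation and oxygen delivery.  The chain is
the classical one:

* alveolar gas equation  ->  alveolar PO2,
* Severinghaus dissociation curve  ->  SO2 from PO2,
* Berggren venous-admixture mixing with a Fick mixed-venous content
  ->  arterial PO2 at a given shunt fraction,
* ``PaCO2 = 863 * VCO2 / VA``  ->  arterial CO2 from alveolar ventilation,
* Henderson-Hasselbalch  ->  pH from PaCO2 at a fixed bicarbonate.

All functions are pure and operate on scalars, in conventional clinical
units (pressures mmHg, contents mL O2 / dL, ventilation mL/min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BloodGas",
    "GasExchangeEnv",
    "alveolar_po2",
    "severinghaus_so2",
    "o2_content",
    "po2_from_content",
    "shunt_pao2",
    "paco2_from_ventilation",
    "ph_from_paco2",
    "oxygen_delivery",
]

#: O2 carrying capacity of hemoglobin, mL O2 per gram Hb.
HB_O2_CAPACITY = 1.34
#: Solubility of O2 in plasma, mL O2 / dL / mmHg.
O2_SOLUBILITY = 0.003
#: Default bicarbonate concentration, mmol/L (no metabolic compensation).
DEFAULT_HCO3 = 24.0

PACO2_MIN = 10.0
PACO2_MAX = 200.0


@dataclass(frozen=True)
class BloodGas:
    """Arterial blood-gas snapshot at one point in time."""

    pao2: float  # mmHg
    paco2: float  # mmHg
    ph: float
    sao2: float  # fraction
    spo2: float  # fraction; equals sao2 unless monitor noise is modelled
    pf_ratio: float  # mmHg, pao2 / fio2
    fio2: float = 1.0


@dataclass(frozen=True)
class GasExchangeEnv:
    """Inputs needed to compute a blood gas for one quasi-steady state."""

    fio2: float
    shunt: float
    alveolar_ventilation: float  # mL/min
    barometric_pressure: float = 760.0  # mmHg
    water_vapor: float = 47.0  # mmHg
    rq: float = 0.8

    def __post_init__(self) -> None:
        if not 0.21 <= self.fio2 <= 1.0:
            raise ValueError(f"fio2 must be in [0.21, 1.0], got {self.fio2}")
        if not 0.0 <= self.shunt <= 1.0:
            raise ValueError(f"shunt must be in [0, 1], got {self.shunt}")


def alveolar_po2(env: GasExchangeEnv, paco2: float) -> float:
    """Alveolar PO2 from the alveolar gas equation, floored at 1 mmHg.

    PAO2 = FiO2 * (Pb - PH2O) - PaCO2 / RQ
    """
    if paco2 <= 0:
        raise ValueError("paco2 must be positive")
    pao2_alv = env.fio2 * (env.barometric_pressure - env.water_vapor) - paco2 / env.rq
    return max(pao2_alv, 1.0)


def severinghaus_so2(po2: float) -> float:
    """Hemoglobin O2 saturation (fraction) from the Severinghaus curve.

    SO2 = 1 / (23400 / (PO2^3 + 150 PO2) + 1); strictly increasing,
    asymptoting to 1.
    """
    if po2 <= 0:
        raise ValueError("po2 must be positive")
    return 1.0 / (23400.0 / (po2 ** 3 + 150.0 * po2) + 1.0)


def o2_content(po2: float, hb: float) -> float:
    """Blood O2 content (mL O2 / dL) at a given PO2 and hemoglobin (g/dL)."""
    return HB_O2_CAPACITY * hb * severinghaus_so2(po2) + O2_SOLUBILITY * po2


def po2_from_content(content: float, hb: float, tol: float = 1e-6) -> float:
    """Invert the content curve: PO2 at which blood carries ``content``.

    Monotone bisection on [1e-3, 700].  Contents above the curve's value at
    700 mmHg (or at/below zero) are clamped to the interval ends.
    """
    lo, hi = 1e-3, 700.0
    if content <= o2_content(lo, hb):
        return lo
    if content >= o2_content(hi, hb):
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if o2_content(mid, hb) < content:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def shunt_pao2(
    shunt: float,
    pao2_alveolar: float,
    hb: float,
    co: float,
    vo2: float,
) -> float:
    """Arterial PO2 (mmHg) for a given shunt fraction.

    Solves the Berggren mixing relation
    ``CaO2 = shunt * CvO2 + (1 - shunt) * CcO2`` with end-capillary blood
    equilibrated at the alveolar PO2 and mixed-venous content from the Fick
    principle, ``CvO2 = CaO2 - VO2 / (10 CO)``.  Substituting the Fick
    relation reduces the fixed point to closed form in content,

        CaO2 = CcO2 - shunt / (1 - shunt) * VO2 / (10 CO),

    after which the content curve is inverted numerically for PaO2.

    Parameters are shunt fraction in [0, 1), alveolar PO2 (mmHg), hemoglobin
    (g/dL), cardiac output (L/min) and O2 consumption (mL/min).
    """
    if not 0.0 <= shunt < 1.0:
        raise ValueError("shunt must be in [0, 1)")
    if co <= 0:
        raise ValueError("cardiac output must be positive")
    cc = o2_content(pao2_alveolar, hb)
    if shunt == 0.0:
        return pao2_alveolar
    ca = cc - shunt / (1.0 - shunt) * vo2 / (10.0 * co)
    return po2_from_content(ca, hb)


def paco2_from_ventilation(vco2: float, alveolar_ventilation: float) -> float:
    """PaCO2 (mmHg) = 863 * VCO2 / VA, capped to [10, 200].

    ``vco2`` in mL/min (STPD), ``alveolar_ventilation`` in mL/min (BTPS).
    """
    if alveolar_ventilation <= 0:
        raise ValueError("alveolar ventilation must be positive")
    return min(max(863.0 * vco2 / alveolar_ventilation, PACO2_MIN), PACO2_MAX)


def ph_from_paco2(paco2: float, hco3: float = DEFAULT_HCO3) -> float:
    """Arterial pH from Henderson-Hasselbalch at fixed bicarbonate."""
    if paco2 <= 0 or hco3 <= 0:
        raise ValueError("paco2 and hco3 must be positive")
    return 6.1 + math.log10(hco3 / (0.03 * paco2))


def oxygen_delivery(pao2: float, hb: float, co: float) -> float:
    """Systemic O2 delivery DO2 (mL O2/min) = CaO2 * CO * 10."""
    if pao2 <= 0 or hb < 0 or co < 0:
        raise ValueError("inputs must be positive")
    return o2_content(pao2, hb) * co * 10.0
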