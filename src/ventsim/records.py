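"""Shared record types: commanded ventilator settings and per-breath results."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["VentSettings", "BreathRecord", "PCV_VG", "PCV_FIXED_DP"]

PCV_VG = "PCV_VG"  # pressure control with volume guarantee (VT target in mL/kg)
PCV_FIXED_DP = "PCV_FIXED_DP"  # pressure control at a fixed driving pressure


@dataclass(frozen=True)
class VentSettings:
    """Commanded ventilator settings for one or more breaths.

    Exactly one of ``vt_target`` (mL/kg, volume-guarantee mode) or ``dp``
    (cmH2O, fixed driving-pressure mode) governs, selected by ``mode``.
    """

    mode: str
    fio2: float
    peep: float
    rr: float
    vt_target: float | None = None  # mL/kg body weight
    dp: float | None = None  # cmH2O
    ie_ratio: str = "1:2"
    pip_limit: float = 60.0

    def __post_init__(self) -> None:
        if self.mode not in (PCV_VG, PCV_FIXED_DP):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.21 <= self.fio2 <= 1.0:
            raise ValueError(f"fio2 out of range: {self.fio2}")
        if self.peep < 0:
            raise ValueError("peep must be >= 0")
        if self.rr < 1:
            raise ValueError("rr must be >= 1")
        if self.mode == PCV_VG and self.vt_target is None:
            raise ValueError("PCV_VG requires vt_target")
        if self.mode == PCV_FIXED_DP and self.dp is None:
            raise ValueError("PCV_FIXED_DP requires dp")

    @property
    def insp_time_fraction(self) -> float:
        """Inspiratory fraction of the breath cycle parsed from ``ie_ratio``."""
        i, e = (float(x) for x in self.ie_ratio.split(":"))
        return i / (i + e)

    def with_(self, **kw) -> "VentSettings":
        return replace(self, **kw)


@dataclass(frozen=True)
class BreathRecord:
    """Realized mechanics and quasi-steady gas exchange for one breath.

    ``crs_dyn`` is delivered tidal volume over driving pressure; ``mp`` is
    the pressure-controlled mechanical power in J/min.
    """

    time_s: float
    pip: float  # cmH2O
    peep: float  # cmH2O
    dp: float  # cmH2O (= pip - peep)
    vt_ml: float
    rr: float
    fio2: float
    crs_dyn: float  # mL/cmH2O
    mp: float  # J/min
    aeration: float  # end-expiratory open fraction
    consolidated_fraction: float
    pao2: float
    paco2: float
    ph: float
    spo2: float
    co: float  # L/min
    cyclic_events: int = 0  # units that opened and re-closed this breath
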