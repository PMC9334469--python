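"""Automated closed-loop protective-ventilation controller.

Implements an ARDSNet-style rule set for pressure-controlled ventilation
with volume guarantee:

* oxygenation: SpO2 below 88 % moves one step up the "higher PEEP / lower
  FiO2" table, above 95 % one step down, with a dwell time between moves;
* lung protection: the tidal-volume setpoint steps down 6 -> 5 -> 4 mL/kg
  whenever observed peak inspiratory pressure exceeds 30 cmH2O (no
  automatic re-escalation);
* acid-base: an arterial pH sample provided every 30 simulated minutes
  moves the respiratory rate in steps of +/-5/min when pH leaves
  [7.30, 7.45], capped at 35/min.

The controller is deterministic given its input sequence and always emits
an exact row of the configured table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .records import PCV_VG, VentSettings

__all__ = [
    "PeepFio2Table",
    "ControllerState",
    "ARDSNET_HIGHER_PEEP_TABLE",
    "tick_oxygenation",
    "tick_tidal_volume",
    "tick_acid_base",
    "controller_step",
]

#: Published ARDSNet "higher PEEP / lower FiO2" escalation table as
#: (FiO2, PEEP) pairs ordered by invasiveness.  Shipped as an editable
#: default; any table with both coordinates non-decreasing is accepted.
ARDSNET_HIGHER_PEEP_TABLE: tuple[tuple[float, float], ...] = (
    (0.3, 5),
    (0.3, 8),
    (0.3, 10),
    (0.3, 12),
    (0.3, 14),
    (0.4, 14),
    (0.4, 16),
    (0.5, 16),
    (0.5, 18),
    (0.5, 20),
    (0.8, 20),
    (0.9, 22),
    (1.0, 22),
    (1.0, 24),
)

VT_STEPS = (6.0, 5.0, 4.0)  # mL/kg, descending protection ladder
PIP_REDUCE_THRESHOLD = 30.0  # cmH2O, strict inequality


@dataclass
class PeepFio2Table:
    """Ordered (FiO2, PEEP) escalation ladder with a current position."""

    rows: tuple[tuple[float, float], ...] = ARDSNET_HIGHER_PEEP_TABLE
    current_index: int = 0

    def __post_init__(self) -> None:
        fio2s = [r[0] for r in self.rows]
        peeps = [r[1] for r in self.rows]
        if sorted(fio2s) != list(fio2s) or sorted(peeps) != list(peeps):
            raise ValueError("table rows must be non-decreasing in FiO2 and PEEP")
        if not 0 <= self.current_index < len(self.rows):
            raise ValueError("current_index out of bounds")

    @property
    def current(self) -> tuple[float, float]:
        return self.rows[self.current_index]

    def move(self, delta: int) -> None:
        self.current_index = min(max(self.current_index + delta, 0), len(self.rows) - 1)

    @classmethod
    def from_yaml(cls, path) -> "PeepFio2Table":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(rows=tuple((float(r[0]), float(r[1])) for r in data["peep_fio2_table"]))


@dataclass
class ControllerEvent:
    time_s: float
    rule: str
    old: float
    new: float


@dataclass
class ControllerState:
    """Mutable controller memory between evaluation ticks."""

    table: PeepFio2Table = field(default_factory=PeepFio2Table)
    vt_step: float = 6.0  # mL/kg
    rr: float = 20.0
    spo2_low: float = 0.88
    spo2_high: float = 0.95
    ph_low: float = 7.30
    ph_high: float = 7.45
    rr_step: float = 5.0
    rr_max: float = 35.0
    rr_min: float = 10.0
    dwell_s: float = 300.0  # minimum time between table moves
    eval_interval_s: float = 30.0  # oxygenation evaluation cadence
    ph_interval_s: float = 1800.0  # pH sampling cadence
    last_move_time: float = -1e9
    last_eval_time: float = -1e9
    last_ph_time: float = -1e9
    events: list[ControllerEvent] = field(default_factory=list)

    def settings(self) -> VentSettings:
        fio2, peep = self.table.current
        return VentSettings(
            mode=PCV_VG,
            fio2=fio2,
            peep=peep,
            rr=self.rr,
            vt_target=self.vt_step,
            ie_ratio="1:2",
        )


def tick_oxygenation(state: ControllerState, spo2: float, now: float) -> ControllerState:
    """One SpO2 evaluation: move one table step if out of the 88-95 % band.

    Moves are rate-limited by the dwell time and clamped to the table ends;
    a single evaluation never moves more than one row.
    """
    if now - state.last_move_time < state.dwell_s:
        return state
    old = state.table.current_index
    if spo2 < state.spo2_low:
        state.table.move(+1)
    elif spo2 > state.spo2_high:
        state.table.move(-1)
    if state.table.current_index != old:
        state.last_move_time = now
        state.events.append(ControllerEvent(now, "peep_fio2_table", old, state.table.current_index))
    return state


def tick_tidal_volume(state: ControllerState, observed_pip: float, now: float = 0.0) -> ControllerState:
    """Step the VT target down one level when PIP strictly exceeds 30 cmH2O."""
    if observed_pip > PIP_REDUCE_THRESHOLD:
        i = VT_STEPS.index(state.vt_step)
        if i + 1 < len(VT_STEPS):
            state.events.append(ControllerEvent(now, "vt_step", state.vt_step, VT_STEPS[i + 1]))
            state.vt_step = VT_STEPS[i + 1]
    return state


def tick_acid_base(state: ControllerState, ph: float, now: float = 0.0) -> ControllerState:
    """Adjust RR by +/-5/min on a 30-min pH sample, clamped to [rr_min, 35]."""
    old = state.rr
    if ph < state.ph_low:
        state.rr = min(state.rr + state.rr_step, state.rr_max)
    elif ph > state.ph_high:
        state.rr = max(state.rr - state.rr_step, state.rr_min)
    if state.rr != old:
        state.events.append(ControllerEvent(now, "rr", old, state.rr))
    return state


def controller_step(
    state: ControllerState, spo2: float, ph: float, observed_pip: float, now: float
) -> tuple[ControllerState, VentSettings]:
    """Composite per-breath controller evaluation.

    Applies the oxygenation rule on its 30-s cadence, the tidal-volume rule
    on every breath summary, and the acid-base rule on the 30-min pH
    schedule, then emits the resulting settings (always an exact table row,
    PCV with volume guarantee, I:E 1:2).
    """
    if now - state.last_eval_time >= state.eval_interval_s:
        state.last_eval_time = now
        tick_oxygenation(state, spo2, now)
    tick_tidal_volume(state, observed_pip, now)
    if now - state.last_ph_time >= state.ph_interval_s:
        state.last_ph_time = now
        tick_acid_base(state, ph, now)
    return state, state.settings()
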