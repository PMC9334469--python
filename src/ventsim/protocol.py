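"""Experiment protocol engine.

Drives a virtual pig through the full two-arm study timeline:

    baseline (60 min, PaCO2-servo)  ->  saline lavage to hypoxemia
    ->  RM1 + PEEP trial 1
    ->  ventilation phase 1 (3 h protective closed-loop OR injurious
        high-VT / low-PEEP)
    ->  RM2 + PEEP trial 2
    ->  ventilation phase 2 (3 h protective closed-loop, both arms)
    ->  RM3 + PEEP trial 3

A recruitment maneuver steps PEEP 12 -> 24 at a driving pressure of 20,
holds 5 cycles at PIP 50 / PEEP 24, then assesses gas exchange and
mechanics after 5 min at PEEP 15 / VT 6 mL/kg.  Each decremental PEEP
trial first standardizes volume history (10 breaths at VT 10 mL/kg /
PEEP 0, then a 5-s circuit disconnection), ascends 12 -> 24 by 4, and
descends 24 -> 6 by 2 cmH2O every 10 simulated minutes at a constant
driving pressure of 14 and RR 20, recording one measurement at the end of
each descent step until PEEP 6 or a P/F ratio below 80 mmHg is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .controller import ControllerState, controller_step
from .pig import InjuryParams, PigDead, PigState, apply_lavage_cycle, step_breath
from .records import PCV_FIXED_DP, PCV_VG, BreathRecord, VentSettings
from . import gas

__all__ = [
    "PeepTrialStep",
    "PeepTrialResult",
    "Snapshot",
    "ExperimentLog",
    "CalibrationError",
    "run_baseline",
    "run_lavage",
    "run_recruitment_maneuver",
    "run_volume_history",
    "run_peep_trial",
    "run_full_experiment",
    "PROTECTIVE",
    "INJURIOUS",
]

PROTECTIVE = "protective"
INJURIOUS = "injurious"

#: Recruitment-maneuver ladder (PEEP rungs at driving pressure 20).
RM_LADDER_PEEP = (12.0, 16.0, 20.0, 24.0)
RM_PLATEAU_PIP = 50.0
RM_ASSESS_PEEP = 15.0
#: Decremental-trial grids.
TRIAL_ASCENT_PEEP = (12.0, 16.0, 20.0, 24.0)
TRIAL_DESCENT_PEEP = tuple(float(p) for p in range(24, 4, -2))
TRIAL_DP = 14.0
TRIAL_RR = 20.0
TRIAL_STEP_MINUTES = 10.0
PF_STOP = 80.0


class CalibrationError(RuntimeError):
    """Raised when an injury process fails to reach its protocol criterion."""


@dataclass(frozen=True)
class PeepTrialStep:
    """End-of-step measurement on the decremental PEEP ladder."""

    peep: float
    pao2: float
    paco2: float
    crs: float
    co: float
    do2: float
    pf_ratio: float


@dataclass
class PeepTrialResult:
    steps: list[PeepTrialStep] = field(default_factory=list)
    terminated_reason: str = ""  # min_peep | hypoxemia | death


@dataclass
class Snapshot:
    """Standardized assessment at a protocol instant (e.g. post-RM)."""

    label: str
    time_s: float
    bg: gas.BloodGas
    crs: float
    mp: float
    co: float
    peep: float
    dp: float


@dataclass
class ExperimentLog:
    arm: str
    pig_id: int = 0
    breaths: list[BreathRecord] = field(default_factory=list)
    snapshots: list[Snapshot] = field(default_factory=list)
    trials: list[PeepTrialResult] = field(default_factory=list)
    lavage_cycles: int = 0
    died_at_s: float | None = None
    phase_labels: list[tuple[str, float, float]] = field(default_factory=list)

    def phase_breaths(self, label: str) -> list[BreathRecord]:
        spans = [(t0, t1) for lab, t0, t1 in self.phase_labels if lab == label]
        return [b for b in self.breaths if any(t0 <= b.time_s < t1 for t0, t1 in spans)]


def _ventilate(
    pig: PigState,
    settings: VentSettings,
    n_breaths: int,
    t0: float,
    log: ExperimentLog | None = None,
) -> tuple[float, BreathRecord | None]:
    """Run ``n_breaths`` at fixed settings; returns (end time, last record)."""
    t = t0
    rec = None
    for _ in range(n_breaths):
        _, rec = step_breath(pig, settings, t)
        if log is not None:
            log.breaths.append(rec)
        t += 60.0 / settings.rr
        if not pig.alive:
            if log is not None:
                log.died_at_s = t
            raise PigDead(f"pig died at t={t:.0f}s")
    return t, rec


def _snapshot(label: str, t: float, pig: PigState, rec: BreathRecord) -> Snapshot:
    bg = gas.BloodGas(
        pao2=rec.pao2,
        paco2=rec.paco2,
        ph=rec.ph,
        sao2=rec.spo2,
        spo2=rec.spo2,
        pf_ratio=rec.pao2 / rec.fio2,
        fio2=rec.fio2,
    )
    return Snapshot(label, t, bg, rec.crs_dyn, rec.mp, rec.co, rec.peep, rec.dp)


# -- protocol stages ------------------------------------------------------


def run_baseline(
    pig: PigState,
    minutes: float = 60.0,
    log: ExperimentLog | None = None,
    t0: float = 0.0,
    rr_start: float = 16.0,
    rr_min: float = 6.0,
    rr_max: float = 40.0,
) -> tuple[float, float]:
    """Baseline ventilation: VT 6 mL/kg, PEEP 7, FiO2 1.0, I:E 1:2.

    The respiratory rate is servo-adjusted every 30 s (one step of 1/min)
    to hold PaCO2 in [37, 45] mmHg.  Returns (end time, final RR).  If the
    band cannot be reached within the RR limits the run simply continues
    at the limit.
    """
    t = t0
    rr = rr_start
    t_end = t0 + minutes * 60.0
    last_adj = -1e9
    while t < t_end:
        settings = VentSettings(
            mode=PCV_VG, fio2=1.0, peep=7.0, rr=rr, vt_target=6.0, ie_ratio="1:2"
        )
        _, rec = step_breath(pig, settings, t)
        if log is not None:
            log.breaths.append(rec)
        t += 60.0 / rr
        if not pig.alive:
            if log is not None:
                log.died_at_s = t
            raise PigDead(f"pig died at t={t:.0f}s")
        if t - last_adj >= 30.0:
            last_adj = t
            if rec.paco2 > 45.0 and rr < rr_max:
                rr += 1.0
            elif rec.paco2 < 37.0 and rr > rr_min:
                rr -= 1.0
    if log is not None and rec is not None:
        log.snapshots.append(_snapshot("baseline", t, pig, rec))
    return t, rr


def run_lavage(
    pig: PigState,
    params: InjuryParams | None = None,
    rr: float = 16.0,
    max_cycles: int = 20,
    log: ExperimentLog | None = None,
    t0: float = 0.0,
) -> tuple[float, gas.BloodGas]:
    """Repeat lavage cycles until PaO2 stays below 100 mmHg for 10 min.

    After each cycle the pig is ventilated for 10 simulated minutes at
    VT 6 mL/kg, PEEP 6, FiO2 1.0; the procedure ends when every breath of
    a full window reads PaO2 < 100 mmHg, and the qualifying blood gas is
    returned.  More than ``max_cycles`` cycles raises CalibrationError.
    """
    params = params if params is not None else pig.injury
    settings = VentSettings(mode=PCV_VG, fio2=1.0, peep=6.0, rr=rr, vt_target=6.0)
    t = t0
    for cycle in range(1, max_cycles + 1):
        apply_lavage_cycle(pig, params)
        if log is not None:
            log.lavage_cycles = cycle
        qualifies = True
        rec = None
        n = int(round(10.0 * rr))  # 10 minutes of breaths
        for _ in range(n):
            _, rec = step_breath(pig, settings, t)
            if log is not None:
                log.breaths.append(rec)
            t += 60.0 / rr
            if not pig.alive:
                if log is not None:
                    log.died_at_s = t
                raise PigDead(f"pig died during lavage at t={t:.0f}s")
            if rec.pao2 >= 100.0:
                qualifies = False
        if qualifies:
            bg = gas.BloodGas(
                pao2=rec.pao2,
                paco2=rec.paco2,
                ph=rec.ph,
                sao2=rec.spo2,
                spo2=rec.spo2,
                pf_ratio=rec.pao2 / rec.fio2,
                fio2=rec.fio2,
            )
            if log is not None:
                log.snapshots.append(_snapshot("post_lavage", t, pig, rec))
            return t, bg
    raise CalibrationError(
        f"lavage did not reach PaO2 < 100 mmHg within {max_cycles} cycles"
    )


def run_recruitment_maneuver(
    pig: PigState,
    label: str = "post_rm",
    log: ExperimentLog | None = None,
    t0: float = 0.0,
) -> tuple[float, Snapshot]:
    """Stepwise recruitment maneuver with standardized assessment.

    PEEP ladder 12 -> 24 cmH2O (driving pressure 20, RR 20, 5 breaths per
    rung), 5 cycles at PIP 50 / PEEP 24, then 5 min at PEEP 15 / VT
    6 mL/kg during which the post-RM assessment is taken at minute 5.
    """
    t = t0
    for peep in RM_LADDER_PEEP:
        s = VentSettings(mode=PCV_FIXED_DP, fio2=1.0, peep=peep, rr=20.0, dp=20.0)
        t, _ = _ventilate(pig, s, 5, t, log)
    s = VentSettings(
        mode=PCV_FIXED_DP, fio2=1.0, peep=24.0, rr=20.0, dp=RM_PLATEAU_PIP - 24.0
    )
    t, _ = _ventilate(pig, s, 5, t, log)
    s = VentSettings(mode=PCV_VG, fio2=1.0, peep=RM_ASSESS_PEEP, rr=20.0, vt_target=6.0)
    t, rec = _ventilate(pig, s, int(5 * 20), t, log)
    snap = _snapshot(label, t, pig, rec)
    if log is not None:
        log.snapshots.append(snap)
    return t, snap


def run_volume_history(
    pig: PigState, log: ExperimentLog | None = None, t0: float = 0.0
) -> float:
    """Standardize volume history: 10 breaths at VT 10 mL/kg / PEEP 0 /
    RR 10 / I:E 1:1, then 5 s of circuit disconnection at zero airway
    pressure (every open unit with a positive closing pressure collapses).
    """
    s = VentSettings(mode=PCV_VG, fio2=1.0, peep=0.0, rr=10.0, vt_target=10.0, ie_ratio="1:1")
    t, _ = _ventilate(pig, s, 10, t0, log)
    from .pig import CLOSED, OPEN  # local to avoid polluting module namespace

    disconnect = (pig.state == OPEN) & (pig.closing > 0.0)
    pig.state[disconnect] = CLOSED
    return t + 5.0


def run_peep_trial(
    pig: PigState, log: ExperimentLog | None = None, t0: float = 0.0
) -> tuple[float, PeepTrialResult]:
    """Decremental PEEP trial at constant driving pressure 14 and RR 20.

    Ascent 12 -> 24 by 4 (5 cycles per step), then descent 24 -> 6 by 2
    with 10 simulated minutes per step at FiO2 1.0.  One measurement is
    recorded at the end of each descent step; the trial stops at PEEP 6 or
    as soon as a recorded P/F ratio falls below 80 mmHg.
    """
    t = t0
    result = PeepTrialResult()
    try:
        for peep in TRIAL_ASCENT_PEEP:
            s = VentSettings(mode=PCV_FIXED_DP, fio2=1.0, peep=peep, rr=TRIAL_RR, dp=TRIAL_DP)
            t, _ = _ventilate(pig, s, 5, t, log)
        n_step = int(round(TRIAL_STEP_MINUTES * TRIAL_RR))
        for peep in TRIAL_DESCENT_PEEP:
            s = VentSettings(mode=PCV_FIXED_DP, fio2=1.0, peep=peep, rr=TRIAL_RR, dp=TRIAL_DP)
            t, rec = _ventilate(pig, s, n_step, t, log)
            do2 = gas.oxygen_delivery(rec.pao2, pig.hb, rec.co)
            result.steps.append(
                PeepTrialStep(
                    peep=peep,
                    pao2=rec.pao2,
                    paco2=rec.paco2,
                    crs=rec.crs_dyn,
                    co=rec.co,
                    do2=do2,
                    pf_ratio=rec.pao2 / rec.fio2,
                )
            )
            if rec.pao2 / rec.fio2 < PF_STOP:
                result.terminated_reason = "hypoxemia"
                break
        else:
            result.terminated_reason = "min_peep"
    except PigDead:
        result.terminated_reason = "death"
        if log is not None:
            log.trials.append(result)
        raise
    if log is not None:
        log.trials.append(result)
    return t, result


def _run_protective_phase(
    pig: PigState,
    ctrl: ControllerState,
    hours: float,
    t0: float,
    log: ExperimentLog,
) -> float:
    """Closed-loop protective ventilation for ``hours`` simulated hours."""
    t = t0
    t_end = t0 + hours * 3600.0
    rec = None
    while t < t_end:
        spo2 = rec.spo2 if rec is not None else 0.95
        ph = rec.ph if rec is not None else 7.40
        pip = rec.pip if rec is not None else 0.0
        ctrl, settings = controller_step(ctrl, spo2, ph, pip, t)
        _, rec = step_breath(pig, settings, t)
        log.breaths.append(rec)
        t += 60.0 / settings.rr
        if not pig.alive:
            log.died_at_s = t
            raise PigDead(f"pig died at t={t:.0f}s")
    return t


def _run_injurious_phase(
    pig: PigState, hours: float, t0: float, log: ExperimentLog
) -> float:
    """Non-automated injurious ventilation: VT 17 mL/kg, PEEP 2, RR 12."""
    s = VentSettings(mode=PCV_VG, fio2=1.0, peep=2.0, rr=12.0, vt_target=17.0)
    n = int(round(hours * 3600.0 / (60.0 / s.rr)))
    t, _ = _ventilate(pig, s, n, t0, log)
    return t


def run_full_experiment(
    arm: str,
    pig: PigState,
    seed: int | None = None,
    phase_hours: float = 3.0,
    baseline_minutes: float = 60.0,
    pig_id: int = 0,
) -> ExperimentLog:
    """Run one pig through the complete protocol for the given arm.

    ``arm`` is "protective" (closed-loop throughout) or "injurious"
    (high-VT / low-PEEP phase 1, then closed-loop protective phase 2).
    A death truncates the log; completed stages are preserved.
    """
    if arm not in (PROTECTIVE, INJURIOUS):
        raise ValueError(f"unknown arm {arm!r}")
    if seed is not None:
        pig.rng = np.random.default_rng(seed)
        pig.rng_seed = seed
    log = ExperimentLog(arm=arm, pig_id=pig_id)
    try:
        t, base_rr = run_baseline(pig, baseline_minutes, log)
        t, _ = run_lavage(pig, rr=base_rr, log=log, t0=t)
        t, _ = run_recruitment_maneuver(pig, "post_rm1", log, t)
        t = run_volume_history(pig, log, t)
        t, _ = run_peep_trial(pig, log, t)

        t0_phase = t
        ctrl = ControllerState()
        ctrl.table.current_index = len(ctrl.table.rows) - 1  # start fully escalated
        if arm == PROTECTIVE:
            t = _run_protective_phase(pig, ctrl, phase_hours, t, log)
        else:
            t = _run_injurious_phase(pig, phase_hours, t, log)
        log.phase_labels.append(("phase1", t0_phase, t))

        t, _ = run_recruitment_maneuver(pig, "post_rm2", log, t)
        t = run_volume_history(pig, log, t)
        t, _ = run_peep_trial(pig, log, t)

        t0_phase = t
        if arm == INJURIOUS:
            ctrl = ControllerState()
            ctrl.table.current_index = len(ctrl.table.rows) - 1
        t = _run_protective_phase(pig, ctrl, phase_hours, t, log)
        log.phase_labels.append(("phase2", t0_phase, t))

        t, _ = run_recruitment_maneuver(pig, "post_rm3", log, t)
        t = run_volume_history(pig, log, t)
        t, _ = run_peep_trial(pig, log, t)
    except PigDead:
        pass
    return log
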