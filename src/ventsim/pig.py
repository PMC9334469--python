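"""Virtual porcine lung and its breath-by-breath evolution.

The lung is a population of threshold-behaved alveolar units.  Each unit
has a critical opening pressure (it opens during inspiration once peak
pressure reaches it) and a lower closing pressure (it collapses at
end-expiration if PEEP falls below it); the spread between the two produces
pressure-volume hysteresis, recruitment-maneuver responsiveness and a
"best PEEP".  Saline lavage (surfactant depletion) raises opening pressures
steeply and closing pressures more modestly, widening the hysteresis;
injurious ventilation consolidates units through two channels -- cyclic
opening/closing (atelectrauma) and tidal overdistension (volutrauma) -- and
progressively destabilizes surviving units by nudging their critical
pressures upward.  Consolidated units never re-aerate.

Dynamic respiratory-system compliance is a stiff (chest wall / tissue)
floor plus a term proportional to the end-inspiratory open fraction,
de-rated at high end-expiratory distension (overdistension flattens the
tidal slope of the pressure-volume curve).  Gas exchange is quasi-steady
and recomputed every breath from the aerated fraction (see
:mod:`ventsim.gas`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from . import gas
from .power import mechanical_power
from .records import PCV_FIXED_DP, PCV_VG, BreathRecord, VentSettings

__all__ = [
    "AlveolarUnit",
    "InjuryParams",
    "PigState",
    "PigDead",
    "make_cohort",
    "make_pig",
    "make_pig_from_units",
    "aeration_fraction",
    "step_breath",
    "apply_lavage_cycle",
    "cardiac_output",
    "blood_gas",
]

OPEN, CLOSED, CONSOLIDATED = 0, 1, 2

#: Reference driving pressure (cmH2O) used to define the nominal per-unit
#: tidal volume against which overdistension strain is measured.
STRAIN_REF_DP = 14.0

#: Death rule: arterial PO2 below this (mmHg) sustained for this long (s).
DEATH_PAO2 = 30.0
DEATH_SUSTAIN_S = 600.0


class PigDead(RuntimeError):
    """Protocol-halt signal raised when a dead pig is ventilated."""


class AlveolarUnit(NamedTuple):
    """One recruitable lung compartment."""

    opening_pressure: float  # cmH2O
    closing_pressure: float  # cmH2O
    state: int = OPEN  # OPEN / CLOSED / CONSOLIDATED
    perfusion_weight: float = 1.0


@dataclass
class InjuryParams:
    """Lavage and ventilator-induced injury mechanism parameters.

    Lavage shifts critical pressures upward each cycle (truncated-normal
    draws); opening pressures shift by the full draw and closing pressures
    by ``lavage_closing_frac`` of it, so surfactant depletion widens the
    opening/closing hysteresis.  VILI acts per breath: units that opened
    and re-closed within the breath ("cyclic") consolidate with
    ``cyclic_consolidation_prob`` and have their critical pressures nudged
    up by ``cyclic_pressure_shift``; open units whose tidal strain exceeds
    ``overdistension_strain_threshold`` consolidate with
    ``overdistension_consolidation_prob``.
    """

    lavage_shift_mean: float = 1.5  # cmH2O per cycle, opening pressures
    lavage_shift_sd: float = 0.6
    lavage_closing_frac: float = 0.15  # closing shift as fraction of opening shift
    lavage_closing_frac_het: float = 0.42  # same, for the susceptible subpopulation
    lavage_compliance_loss: float = 0.015  # fractional loss per cycle
    lavage_deadspace_per_cycle: float = 0.04  # persistent alveolar dead-space add
    lavage_closing_cap: float = 20.0  # cmH2O asymptote for lavage-driven closing rise
    lavage_opening_cap: float = 44.0  # cmH2O asymptote for lavage-driven opening rise
    lavage_het_frac: float = 0.25  # fraction of units with amplified lavage response
    lavage_het_mult: tuple[float, float] = (1.5, 2.1)  # multiplier range for those units
    cyclic_consolidation_prob: float = 1.0e-4  # per cyclic unit-breath
    cyclic_pressure_shift: float = 4.8e-3  # cmH2O per cyclic unit-breath
    cyclic_shift_opening_frac: float = 0.4  # opening shift as fraction of closing shift
    overdistension_strain_threshold: float = 2.5  # x nominal unit tidal volume
    overdistension_consolidation_prob: float = 8.0e-5  # per overdistended unit-breath
    shunt_hpv_factor: float = 0.7  # hypoxic-vasoconstriction attenuation of shunt
    consolidated_perfusion_factor: float = 0.35  # residual perfusion of consolidated units

    def __post_init__(self) -> None:
        for name in (
            "cyclic_consolidation_prob",
            "overdistension_consolidation_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.overdistension_strain_threshold <= 0:
            raise ValueError("overdistension_strain_threshold must be > 0")
        if not 0.0 < self.shunt_hpv_factor <= 1.0:
            raise ValueError("shunt_hpv_factor must be in (0, 1]")


@dataclass
class PigState:
    """Full virtual-animal state.

    Units are stored as parallel arrays (``opening``, ``closing``,
    ``state`` with codes OPEN/CLOSED/CONSOLIDATED, ``perfusion``); the
    ``units`` property materializes them as :class:`AlveolarUnit` tuples.
    """

    body_weight: float  # kg
    opening: np.ndarray
    closing: np.ndarray
    state: np.ndarray
    perfusion: np.ndarray
    compliance_scale: float  # mL/cmH2O gained at full aeration
    stiff_compliance: float  # mL/cmH2O floor when fully derecruited
    injury: InjuryParams
    hb: float = 10.0  # g/dL
    vo2: float = 160.0  # mL O2/min
    vco2: float = 128.0  # mL CO2/min
    hco3: float = gas.DEFAULT_HCO3  # mmol/L
    airway_dead_space: float = 100.0  # mL
    alveolar_deadspace_gain: float = 1.0  # per unit of (1 - aeration) + consolidated
    alveolar_deadspace_cap: float = 0.58
    lavage_deadspace: float = 0.0  # persistent alveolar dead-space fraction
    base_shunt: float = 0.06  # venous admixture of the healthy lung
    co_base: float = 4.2  # L/min at PEEP <= 5
    co_peep_slope: float = 0.015  # fractional CO loss per cmH2O PEEP above 5
    od_onset_peep: float = 12.0  # cmH2O end-expiratory overdistension onset
    od_slope: float = 0.075  # compliance de-rating per cmH2O PEEP above onset
    od_floor: float = 0.30
    lavage_mult: np.ndarray | None = None  # per-unit lavage susceptibility
    alive: bool = True
    rng_seed: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    cumulative_cyclic_events: int = 0
    last_dp: float = 10.0  # driving pressure of the previous breath (cmH2O)
    last_crs_dyn: float = 25.0  # dynamic compliance of the previous breath
    crs_ema: float = 25.0  # compliance averaged over recent breaths (VG servo input)
    hypoxemia_s: float = 0.0  # accumulated time with PaO2 < DEATH_PAO2

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if not self.compliance_scale > 0 or not self.stiff_compliance > 0:
            raise ValueError("compliances must be positive")
        if self.compliance_scale <= self.stiff_compliance:
            raise ValueError("compliance_scale must exceed stiff_compliance")
        if np.any(self.closing >= self.opening):
            raise ValueError("closing pressure must be below opening pressure")
        total = float(self.perfusion.sum())
        if total <= 0:
            raise ValueError("perfusion weights must be positive")
        self.perfusion = self.perfusion / total
        if self.lavage_mult is None:
            self.lavage_mult = np.ones(self.opening.size)

    # -- unit bookkeeping -------------------------------------------------

    @property
    def n_units(self) -> int:
        return self.opening.size

    @property
    def units(self) -> list[AlveolarUnit]:
        return [
            AlveolarUnit(float(o), float(c), int(s), float(w))
            for o, c, s, w in zip(self.opening, self.closing, self.state, self.perfusion)
        ]

    @property
    def consolidated_fraction(self) -> float:
        return float(np.count_nonzero(self.state == CONSOLIDATED)) / self.n_units

    def open_fraction(self) -> float:
        return float(np.count_nonzero(self.state == OPEN)) / self.n_units

    def copy(self) -> "PigState":
        return copy.deepcopy(self)

    def unit_nominal_tv(self) -> float:
        """Nominal per-unit tidal volume (mL) at the reference driving pressure."""
        return self.compliance_scale * STRAIN_REF_DP / self.n_units


# -- construction ---------------------------------------------------------


def make_pig(
    bw: float,
    seed: int,
    n_units: int = 500,
    injury: InjuryParams | None = None,
) -> PigState:
    """One healthy pig with randomized unit pressures and lung size.

    Healthy opening pressures are Normal(3, 2) cmH2O clipped at 0.5;
    closing pressures sit 1-3 cmH2O below opening.  Full-aeration dynamic
    compliance scales with body weight (about 0.52 mL/cmH2O per kg plus a
    stiff floor), metabolic rates with 3.5 mL O2/kg/min.
    """
    if bw <= 0:
        raise ValueError("body weight must be positive")
    rng = np.random.default_rng(seed)
    injury = injury if injury is not None else InjuryParams()
    opening = np.clip(rng.normal(3.0, 2.0, n_units), 0.5, None)
    closing = opening - rng.uniform(1.0, 3.0, n_units)
    # heterogeneous lavage susceptibility: a dependent-region subpopulation
    # responds to surfactant depletion with amplified pressure shifts
    mult = np.ones(n_units)
    suscept = rng.random(n_units) < injury.lavage_het_frac
    mult[suscept] = rng.uniform(*injury.lavage_het_mult, int(suscept.sum()))
    scale = float(np.clip(rng.normal(0.52, 0.02), 0.46, 0.58)) * bw
    vo2 = 3.5 * bw
    return PigState(
        body_weight=bw,
        opening=opening,
        closing=closing,
        state=np.full(n_units, OPEN, dtype=np.int8),
        perfusion=np.full(n_units, 1.0 / n_units),
        compliance_scale=scale,
        stiff_compliance=4.0,
        injury=injury,
        lavage_mult=mult,
        vo2=vo2,
        vco2=0.8 * vo2,
        airway_dead_space=2.2 * bw,
        co_base=float(np.clip(rng.normal(0.092, 0.003), 0.08, 0.104)) * bw,
        rng_seed=seed,
        rng=rng,
    )


def make_pig_from_units(
    units: Sequence[AlveolarUnit],
    bw: float = 46.0,
    compliance_scale: float = 24.0,
    stiff_compliance: float = 4.0,
    seed: int = 0,
    injury: InjuryParams | None = None,
    **kw,
) -> PigState:
    """Pig with an explicit (usually tiny) unit population, for fixtures."""
    opening = np.array([u.opening_pressure for u in units], dtype=float)
    closing = np.array([u.closing_pressure for u in units], dtype=float)
    state = np.array([u.state for u in units], dtype=np.int8)
    perfusion = np.array([u.perfusion_weight for u in units], dtype=float)
    return PigState(
        body_weight=bw,
        opening=opening,
        closing=closing,
        state=state,
        perfusion=perfusion,
        compliance_scale=compliance_scale,
        stiff_compliance=stiff_compliance,
        injury=injury if injury is not None else InjuryParams(),
        rng_seed=seed,
        rng=np.random.default_rng(seed),
        **kw,
    )


def make_cohort(
    n: int,
    bw_mean: float = 46.0,
    bw_sd: float = 3.0,
    seed: int = 0,
    n_units: int = 500,
    injury: InjuryParams | None = None,
) -> list[PigState]:
    """``n`` independent healthy pigs; identical seed reproduces the cohort."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if bw_mean <= 0:
        raise ValueError("bw_mean must be positive")
    if bw_sd < 0:
        raise ValueError("bw_sd must be >= 0")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n) % (2**31)
    bw_rng = np.random.default_rng(int(seeds[0]))
    bws = np.clip(bw_rng.normal(bw_mean, bw_sd, n), 0.25 * bw_mean, None)
    return [
        make_pig(float(bws[i]), int(seeds[n + i]), n_units=n_units, injury=injury)
        for i in range(n)
    ]


# -- observables ----------------------------------------------------------


def aeration_fraction(pig: PigState) -> float:
    """End-expiratory open fraction of all units, in [0, 1]."""
    if pig.n_units < 1:
        raise ValueError("pig has no units")
    return pig.open_fraction()


def cardiac_output(pig: PigState, peep: float) -> float:
    """Cardiac output (L/min): baseline attenuated by PEEP above 5 cmH2O.

    CO = co_base * max(0.3, 1 - co_peep_slope * max(0, PEEP - 5)); venous
    return falls with intrathoracic pressure, floored at 30 % of baseline.
    """
    if peep < 0:
        raise ValueError("peep must be >= 0")
    return pig.co_base * max(0.3, 1.0 - pig.co_peep_slope * max(0.0, peep - 5.0))


def _overdistension_factor(pig: PigState, peep: float) -> float:
    """Tidal-compliance de-rating from end-expiratory distension."""
    return float(
        np.clip(1.0 - pig.od_slope * max(0.0, peep - pig.od_onset_peep), pig.od_floor, 1.0)
    )


def blood_gas(
    pig: PigState, fio2: float, vt_ml: float, rr: float, aerated_fraction: float, peep: float
) -> tuple[gas.BloodGas, float]:
    """Quasi-steady blood gas and PEEP-aware cardiac output.

    Shunt is the fixed venous admixture plus perfusion to non-aerated
    units attenuated by hypoxic vasoconstriction; alveolar dead space
    grows with the non-aerated and consolidated fractions plus a
    persistent lavage component.
    """
    cf = pig.consolidated_fraction
    inj = pig.injury
    recruitable_closed = max(1.0 - aerated_fraction - cf, 0.0)
    shunt = min(
        0.95,
        pig.base_shunt
        + inj.shunt_hpv_factor
        * (recruitable_closed + inj.consolidated_perfusion_factor * cf),
    )
    alv_ds = min(
        pig.alveolar_deadspace_cap,
        pig.alveolar_deadspace_gain * ((1.0 - aerated_fraction) + cf) + pig.lavage_deadspace,
    )
    va = rr * max(vt_ml - pig.airway_dead_space, 1.0) * (1.0 - alv_ds)
    paco2 = gas.paco2_from_ventilation(pig.vco2, va)
    ph = gas.ph_from_paco2(paco2, pig.hco3)
    env = gas.GasExchangeEnv(fio2=fio2, shunt=shunt, alveolar_ventilation=va)
    pao2_alv = gas.alveolar_po2(env, paco2)
    co = cardiac_output(pig, peep)
    pao2 = gas.shunt_pao2(shunt, pao2_alv, pig.hb, co, pig.vo2)
    sao2 = gas.severinghaus_so2(pao2)
    bg = gas.BloodGas(
        pao2=pao2,
        paco2=paco2,
        ph=ph,
        sao2=sao2,
        spo2=sao2,
        pf_ratio=pao2 / fio2,
        fio2=fio2,
    )
    return bg, co


# -- breath dynamics ------------------------------------------------------


def _commanded_dp(pig: PigState, settings: VentSettings, max_step: float = 2.0) -> float:
    """Driving pressure for this breath under the active mode contract.

    Volume guarantee recomputes dp = VT_target / Crs(previous breath) once
    per breath, slews it by at most ``max_step`` cmH2O per breath (as real
    volume-guarantee controllers do), and caps PIP at ``pip_limit``.
    """
    if settings.mode == PCV_FIXED_DP:
        dp = float(settings.dp)
    else:
        want = settings.vt_target * pig.body_weight / max(pig.crs_ema, 1.0)
        dp = float(np.clip(want, pig.last_dp - max_step, pig.last_dp + max_step))
    return float(np.clip(dp, 2.0, settings.pip_limit - settings.peep))


def step_breath(
    pig: PigState, settings: VentSettings, t_s: float = 0.0
) -> tuple[PigState, BreathRecord]:
    """Advance the pig through one quasi-static breath (mutates ``pig``).

    Sequence: units with opening pressure <= PIP open during inspiration;
    dynamic compliance and delivered VT are realized at end-inspiration;
    at end-expiration open units with closing pressure > PEEP collapse;
    injury processes (cyclic consolidation and pressure destabilization,
    overdistension consolidation) then apply; finally the quasi-steady
    blood gas is evaluated and the death rule updated.
    """
    if not pig.alive:
        raise PigDead("pig is dead; protocol must halt")

    peep = settings.peep
    dp = _commanded_dp(pig, settings)
    pip = peep + dp

    recruitable = pig.state != CONSOLIDATED
    was_closed = pig.state == CLOSED
    opens = was_closed & (pig.opening <= pip)
    pig.state[opens] = OPEN

    is_open = pig.state == OPEN
    f_insp = float(np.count_nonzero(is_open)) / pig.n_units
    crs = pig.stiff_compliance + pig.compliance_scale * f_insp * _overdistension_factor(
        pig, peep
    )
    vt = crs * dp
    pig.last_dp = dp
    pig.last_crs_dyn = crs
    pig.crs_ema += 0.3 * (crs - pig.crs_ema)

    # expiration: collapse above-closing-pressure units
    closes = is_open & (pig.closing > peep)
    pig.state[closes] = CLOSED

    # cyclic recruitment/derecruitment: opened this breath and re-closed
    cyclic = opens & closes
    n_cyclic = int(np.count_nonzero(cyclic))
    inj = pig.injury
    if n_cyclic:
        pig.cumulative_cyclic_events += n_cyclic
        if inj.cyclic_pressure_shift > 0:
            ocap, ccap = inj.lavage_opening_cap, inj.lavage_closing_cap
            o_sat = np.clip((ocap - pig.opening[cyclic]) / (ocap / 2.0), 0.0, 1.0)
            c_sat = np.clip((ccap - pig.closing[cyclic]) / (ccap / 2.0), 0.0, 1.0)
            pig.opening[cyclic] += (
                inj.cyclic_shift_opening_frac * inj.cyclic_pressure_shift * o_sat
            )
            pig.closing[cyclic] += inj.cyclic_pressure_shift * c_sat
            np.maximum(pig.opening[cyclic], pig.closing[cyclic] + 0.5,
                       out=pig.opening[cyclic])
        if inj.cyclic_consolidation_prob > 0:
            hit = pig.rng.random(n_cyclic) < inj.cyclic_consolidation_prob
            idx = np.flatnonzero(cyclic)[hit]
            pig.state[idx] = CONSOLIDATED

    # overdistension: per-unit tidal strain relative to nominal
    n_open_insp = int(round(f_insp * pig.n_units))
    if n_open_insp and inj.overdistension_consolidation_prob > 0:
        strain = (vt / n_open_insp) / pig.unit_nominal_tv()
        if strain > inj.overdistension_strain_threshold:
            candidates = np.flatnonzero(is_open & (pig.state != CONSOLIDATED))
            hit = pig.rng.random(candidates.size) < inj.overdistension_consolidation_prob
            pig.state[candidates[hit]] = CONSOLIDATED

    bg, co = blood_gas(pig, settings.fio2, vt, settings.rr, f_insp, peep)

    dt = 60.0 / settings.rr
    if bg.pao2 < DEATH_PAO2:
        pig.hypoxemia_s += dt
        if pig.hypoxemia_s >= DEATH_SUSTAIN_S:
            pig.alive = False
    else:
        pig.hypoxemia_s = 0.0

    rec = BreathRecord(
        time_s=t_s,
        pip=pip,
        peep=peep,
        dp=dp,
        vt_ml=vt,
        rr=settings.rr,
        fio2=settings.fio2,
        crs_dyn=crs,
        mp=mechanical_power(settings.rr, vt / 1000.0, dp, peep),
        aeration=pig.open_fraction(),
        consolidated_fraction=pig.consolidated_fraction,
        pao2=bg.pao2,
        paco2=bg.paco2,
        ph=bg.ph,
        spo2=bg.spo2,
        co=co,
        cyclic_events=n_cyclic,
    )
    return pig, rec


def apply_lavage_cycle(
    pig: PigState, params: InjuryParams | None = None, rng: np.random.Generator | None = None
) -> PigState:
    """One saline-lavage cycle: shift critical pressures up, stiffen the lung.

    Opening pressures of non-consolidated units rise by a truncated-normal
    draw; closing pressures by ``lavage_closing_frac`` of the same draw
    (surfactant loss widens hysteresis), preserving closing < opening.
    Full-aeration compliance shrinks by ``lavage_compliance_loss`` and a
    persistent alveolar dead-space fraction accrues.  Aeration at any fixed
    pressure pair can only decrease.
    """
    if not pig.alive:
        raise PigDead("pig is dead; protocol must halt")
    params = params if params is not None else pig.injury
    rng = rng if rng is not None else pig.rng
    affected = pig.state != CONSOLIDATED
    n = int(np.count_nonzero(affected))
    d_open = np.clip(rng.normal(params.lavage_shift_mean, params.lavage_shift_sd, n), 0.0, None)
    d_open *= pig.lavage_mult[affected]
    ocap = params.lavage_opening_cap
    open_sat = np.clip((ocap - pig.opening[affected]) / (ocap / 2.0), 0.0, 1.0)
    d_open *= open_sat
    closing_frac = np.where(
        pig.lavage_mult[affected] > 1.0,
        params.lavage_closing_frac_het,
        params.lavage_closing_frac,
    )
    pig.opening[affected] += d_open
    # closing pressures saturate toward a structural asymptote; shifts are
    # unattenuated below half the cap and taper to zero at the cap
    cap = params.lavage_closing_cap
    saturation = np.clip((cap - pig.closing[affected]) / (cap / 2.0), 0.0, 1.0)
    pig.closing[affected] += closing_frac * d_open * saturation
    pig.compliance_scale *= 1.0 - params.lavage_compliance_loss
    pig.lavage_deadspace += params.lavage_deadspace_per_cycle
    return pig
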