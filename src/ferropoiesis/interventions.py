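"""Scenario definitions: timed interventions and chronic perturbations.

A :class:`Scenario` collects everything that distinguishes a simulated
subject from the healthy reference: iv and oral iron dosing, EPO dosing
(iv or sc), phlebotomies, a dietary-iron factor, chronic inflammation,
reduced hepcidin production (haemochromatosis) and chemotherapy.  The
module also translates these into the time-dependent inputs and
instantaneous state transforms the simulation engine consumes, and ships
the preset scenarios used throughout the documentation and tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .erythropoiesis import ChemoSchedule, epo_dose_units
from .parameters import ParameterSet
from .state import StateLayout, layout_for


class ScenarioError(ValueError):
    """Ill-formed scenario definition."""


@dataclass(frozen=True)
class IvIronDose:
    """Intravenous iron: ``dose_mg`` is the bioavailable amount infused
    over the configured infusion duration starting at ``time`` (days)."""
    time: float
    dose_mg: float


@dataclass(frozen=True)
class OralIronCourse:
    """Repeated oral iron: ``dose_mg`` taken ``times_per_day`` times per
    day, evenly spaced, on every day in ``[start, end)``."""
    start: float
    end: float
    dose_mg: float
    times_per_day: int = 1

    def dose_times(self) -> np.ndarray:
        if self.end <= self.start:
            return np.empty(0)
        step = 1.0 / self.times_per_day
        n = int(math.ceil((self.end - self.start) / step - 1e-9))
        return self.start + step * np.arange(n)


@dataclass(frozen=True)
class EpoDose:
    time: float
    dose: float
    unit: Literal["iu", "iu_per_kg"] = "iu_per_kg"
    route: Literal["iv", "sc"] = "sc"


@dataclass(frozen=True)
class Phlebotomy:
    """Instantaneous loss of ``fraction`` of the blood volume."""
    time: float
    fraction: float


@dataclass(frozen=True)
class Scenario:
    label: str
    horizon: float
    iron_iv: tuple[IvIronDose, ...] = ()
    iron_oral: tuple[OralIronCourse, ...] = ()
    epo: tuple[EpoDose, ...] = ()
    phlebotomies: tuple[Phlebotomy, ...] = ()
    diet_factor: float = 1.0
    hep_inflammation: float = 0.0
    hep_production_factor: float = 1.0
    chemo: ChemoSchedule | None = None
    oral_pulse_width: float = 1.0 / 48.0  # 30 min; the delay compartment low-passes it

    def __post_init__(self):
        errs = []
        if self.horizon <= 0:
            errs.append("horizon must be > 0")
        for d in self.iron_iv:
            if d.dose_mg < 0:
                errs.append(f"iv iron dose at t={d.time} is negative")
            if not 0 <= d.time <= self.horizon:
                errs.append(f"iv iron time {d.time} outside [0, horizon]")
        for c in self.iron_oral:
            if c.dose_mg < 0:
                errs.append(f"oral iron dose {c.dose_mg} is negative")
            if c.times_per_day < 1:
                errs.append("oral iron times_per_day must be >= 1")
            if not 0 <= c.start <= self.horizon:
                errs.append(f"oral course start {c.start} outside [0, horizon]")
        for e in self.epo:
            if e.dose < 0:
                errs.append(f"EPO dose at t={e.time} is negative")
            if not 0 <= e.time <= self.horizon:
                errs.append(f"EPO time {e.time} outside [0, horizon]")
            if e.route not in ("iv", "sc"):
                errs.append(f"unknown EPO route {e.route!r}")
            if e.unit not in ("iu", "iu_per_kg"):
                errs.append(f"unknown EPO dose unit {e.unit!r}")
        for ph in self.phlebotomies:
            if not 0.0 <= ph.fraction < 1.0:
                errs.append(f"phlebotomy fraction {ph.fraction} outside [0, 1)")
            if not 0 <= ph.time <= self.horizon:
                errs.append(f"phlebotomy time {ph.time} outside [0, horizon]")
        if self.diet_factor < 0:
            errs.append("diet_factor must be >= 0")
        if self.hep_inflammation < 0:
            errs.append("hep_inflammation must be >= 0")
        if self.hep_production_factor < 0:
            errs.append("hep_production_factor must be >= 0")
        if self.oral_pulse_width <= 0:
            errs.append("oral_pulse_width must be > 0")
        if errs:
            raise ScenarioError(f"scenario {self.label!r}: " + "; ".join(errs))


def iv_iron_input(t: float, scenario: Scenario, Fe_tinf: float) -> float:
    """Intravenous iron infusion rate (mg/day) at time ``t``.

    Each dose is a rectangular pulse of height ``dose / Fe_tinf`` over
    ``[t_i, t_i + Fe_tinf)``, so its time integral equals the dose exactly.
    """
    if Fe_tinf <= 0:
        raise ScenarioError("iv infusion duration Fe_tinf must be > 0")
    rate = 0.0
    for d in scenario.iron_iv:
        if d.time <= t < d.time + Fe_tinf:
            rate += d.dose_mg / Fe_tinf
    return rate


def oral_iron_input(t: float, scenario: Scenario, params: ParameterSet) -> float:
    """Ingested-iron rate ``C_in(t)`` (mg/day) entering the intestinal delay
    compartment: continuous diet plus scheduled medication pulses.

    Medication is divided by the minimal ferroportin efficacy, the
    normalising factor that keeps the iron actually absorbed below the
    administered dose once the ferroportin-gated enterocyte export is
    applied.
    """
    c_in = scenario.diet_factor * params.iron.FeDiet_nor
    width = scenario.oral_pulse_width
    zferro_min = params.sigmoids.zferro.v_min
    for course in scenario.iron_oral:
        if not (course.start <= t < course.end) or course.dose_mg == 0:
            continue
        step = 1.0 / course.times_per_day
        k = math.floor((t - course.start) / step)
        if 0 <= t - (course.start + k * step) < width:
            c_in += course.dose_mg / width / zferro_min
    return c_in


def apply_phlebotomy(y: np.ndarray, fraction: float,
                     lay: StateLayout) -> np.ndarray:
    """Instantaneous bleed: reticulocytes, every erythrocyte ageing
    sub-compartment and the random-ageing compartment are reduced by the
    same proportion in both cell count and iron content.  Marrow and plasma
    compartments are untouched (plasma volume assumed restored at once)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"phlebotomy fraction must lie in [0, 1), got {fraction}")
    out = y.copy()
    keep = 1.0 - fraction
    out[lay.RET] *= keep
    out[lay.ERY] *= keep
    out[lay.ERY_rand] *= keep
    out[lay.Fe_RET] *= keep
    out[lay.Fe_ERY] *= keep
    out[lay.Fe_ERY_rand] *= keep
    return out


def scenario_modifiers(params: ParameterSet, scenario: Scenario) -> ParameterSet:
    """Install the scenario's chronic perturbations on the parameter set.

    Diet factor, inflammatory hepcidin influx and the hepcidin production
    factor act from t = 0 on; the derived constants keep their healthy
    values (the subject was at the healthy steady state before the
    scenario starts)."""
    updates = {
        "iron.HEP_inflammation": scenario.hep_inflammation,
        "iron.hep_production_factor": scenario.hep_production_factor,
        "iron.diet_factor": scenario.diet_factor,
    }
    modified = params.with_updates(updates, refinalize=False)
    return dataclasses.replace(modified, derived=params.require_derived())


# ---------------------------------------------------------------------------
# compiled inputs for the engine


@dataclass
class CompiledInputs:
    """Scenario translated into engine inputs: continuous input callables,
    instantaneous state transforms, and the discontinuity times at which
    integration must restart."""

    c_in: Callable[[float], float]          # mg/day into the delay compartment
    fe_inj: Callable[[float], float]        # normalised iv plasma-iron flux
    kill: Callable[[float], float]          # chemotherapy kill rate, 1/day
    jumps: dict[float, list[Callable[[np.ndarray], np.ndarray]]]
    breakpoints: np.ndarray


def compile_scenario(scenario: Scenario, params: ParameterSet) -> CompiledInputs:
    lay = layout_for(params)
    fe_tinf = params.iron.Fe_tinf
    mg_per_unit = params.bridges.iv_iron_mg_per_unit

    def c_in(t: float) -> float:
        return oral_iron_input(t, scenario, params)

    def fe_inj(t: float) -> float:
        return iv_iron_input(t, scenario, fe_tinf) / mg_per_unit

    def kill(t: float) -> float:
        return scenario.chemo.kill(t) if scenario.chemo is not None else 0.0

    jumps: dict[float, list[Callable[[np.ndarray], np.ndarray]]] = {}

    def add_jump(time: float, fn: Callable[[np.ndarray], np.ndarray]) -> None:
        jumps.setdefault(float(time), []).append(fn)

    for ph in scenario.phlebotomies:
        add_jump(ph.time, lambda y, f=ph.fraction: apply_phlebotomy(y, f, lay))
    for e in scenario.epo:
        units = epo_dose_units(e.dose, e.unit, params.epo)

        def dose_epo(y: np.ndarray, units=units, route=e.route) -> np.ndarray:
            out = y.copy()
            if route == "iv":
                out[lay.C_EPO_cent] += units
            else:
                out[lay.D_sc] += units * params.epo.bioavailability_sc
            return out

        add_jump(e.time, dose_epo)

    edges: set[float] = set(jumps)
    for d in scenario.iron_iv:
        edges.update((d.time, d.time + fe_tinf))
    for course in scenario.iron_oral:
        for t0 in course.dose_times():
            edges.update((float(t0), float(t0) + scenario.oral_pulse_width))
    if scenario.chemo is not None:
        edges.update(scenario.chemo.edges())
    edges = {t for t in edges if 0.0 <= t <= scenario.horizon}
    edges.update((0.0, scenario.horizon))

    return CompiledInputs(c_in=c_in, fe_inj=fe_inj, kill=kill, jumps=jumps,
                          breakpoints=np.array(sorted(edges)))


# ---------------------------------------------------------------------------
# shipped presets

CHOP14_TIMES = (0.0, 14.0, 28.0, 42.0, 56.0, 70.0)


def _chop_schedule(kill_rate: float = 0.29) -> ChemoSchedule:
    """Six cycles of dose-dense CHOP: applications every 14 days, each
    producing a delayed transient kill of the proliferating marrow."""
    return ChemoSchedule(times=CHOP14_TIMES, kill_rate=kill_rate,
                         window=4.0, delay=1.0)


def presets() -> dict[str, Scenario]:
    """The shipped scenario library.

    Healthy-volunteer interventions (oral/iv iron, EPO schedules, blood
    donation, malnutrition), chronic conditions (inflammation,
    haemochromatosis) and the CHOP-14 chemotherapy regimen with optional
    iron/EPO support.
    """
    sc = {}
    sc["steady_state"] = Scenario(label="steady_state", horizon=1000.0)
    sc["oral_iron_150bid_50d"] = Scenario(
        label="oral_iron_150bid_50d", horizon=50.0,
        iron_oral=(OralIronCourse(0.0, 50.0, 150.0, 2),))
    sc["epo_iv_200iukg"] = Scenario(
        label="epo_iv_200iukg", horizon=40.0,
        epo=(EpoDose(0.0, 200.0, "iu_per_kg", "iv"),))
    sc["epo_iv_plus_oral_iron"] = Scenario(
        label="epo_iv_plus_oral_iron", horizon=40.0,
        epo=(EpoDose(0.0, 200.0, "iu_per_kg", "iv"),),
        iron_oral=(OralIronCourse(0.0, 10.0, 300.0, 2),))
    sc["iron_deficiency_50pct"] = Scenario(
        label="iron_deficiency_50pct", horizon=300.0, diet_factor=0.5)
    sc["iv_iron_100mg"] = Scenario(
        label="iv_iron_100mg", horizon=60.0, iron_iv=(IvIronDose(0.0, 100.0),))
    sc["phlebotomy_10pct"] = Scenario(
        label="phlebotomy_10pct", horizon=100.0,
        phlebotomies=(Phlebotomy(0.0, 0.1),))
    sc["inflammation"] = Scenario(
        label="inflammation", horizon=150.0, hep_inflammation=3.0)
    sc["haemochromatosis"] = Scenario(
        label="haemochromatosis", horizon=300.0, hep_production_factor=0.25)
    sc["souillard_epo"] = Scenario(
        label="souillard_epo", horizon=30.0,
        epo=tuple(EpoDose(t, 200.0, "iu_per_kg", "sc")
                  for t in (0.0, 2.0, 4.0, 7.0, 10.0)))
    sc["rutherford_g1"] = Scenario(
        label="rutherford_g1", horizon=42.0,
        epo=tuple(EpoDose(t, 300.0, "iu_per_kg", "sc") for t in (0.0, 3.0, 6.0, 9.0)),
        iron_oral=(OralIronCourse(0.0, 10.0, 300.0, 1),))
    sc["rutherford_g2"] = Scenario(
        label="rutherford_g2", horizon=42.0,
        epo=tuple(EpoDose(t, 400.0, "iu_per_kg", "sc") for t in (0.0, 4.0, 8.0)),
        iron_oral=(OralIronCourse(0.0, 10.0, 300.0, 1),))
    sc["rutherford_g3"] = Scenario(
        label="rutherford_g3", horizon=42.0,
        epo=tuple(EpoDose(t, 600.0, "iu_per_kg", "sc") for t in (0.0, 9.0)),
        iron_oral=(OralIronCourse(0.0, 10.0, 300.0, 1),))
    sc["kiss_donation"] = Scenario(
        label="kiss_donation", horizon=168.0, phlebotomies=(Phlebotomy(0.0, 0.1),))
    sc["kiss_donation_iron"] = Scenario(
        label="kiss_donation_iron", horizon=168.0,
        phlebotomies=(Phlebotomy(0.0, 0.1),),
        iron_oral=(OralIronCourse(0.0, 168.0, 325.0, 1),))
    support_days = (3.0, 17.0, 31.0)
    weekly = tuple(45.0 + 7.0 * k for k in range(8))
    sc["chop14"] = Scenario(label="chop14", horizon=120.0, chemo=_chop_schedule())
    sc["chop14_iron"] = Scenario(
        label="chop14_iron", horizon=120.0, chemo=_chop_schedule(),
        iron_iv=tuple(IvIronDose(t, 100.0) for t in support_days))
    sc["chop14_epo"] = Scenario(
        label="chop14_epo", horizon=120.0, chemo=_chop_schedule(),
        epo=tuple(EpoDose(t, 40000.0, "iu", "iv") for t in support_days))
    sc["chop14_epo_iron"] = Scenario(
        label="chop14_epo_iron", horizon=120.0, chemo=_chop_schedule(),
        iron_iv=tuple(IvIronDose(t, 100.0) for t in support_days),
        epo=tuple(EpoDose(t, 40000.0, "iu", "iv") for t in support_days))
    sc["chop14_amelioration_epo_iron"] = Scenario(
        label="chop14_amelioration_epo_iron", horizon=120.0,
        chemo=_chop_schedule(),
        iron_iv=tuple(IvIronDose(t, 100.0) for t in weekly),
        epo=tuple(EpoDose(t, 40000.0, "iu", "iv") for t in weekly))
    return sc
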