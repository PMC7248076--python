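"""Parameter containers for the coupled erythropoiesis / iron-metabolism model.

All cell and iron compartments are expressed relative to their homeostatic
values, so the reference fixed point of the healthy system is the all-ones
state.  Parameters fall into four groups:

* saturating-response (sigmoid) blocks for the phenomenological regulators,
* free rate constants of the iron subsystem,
* cell-kinetic and EPO pharmacokinetic constants of the erythropoiesis
  subsystem, and
* unit bridges that map the relative model quantities onto clinical units
  for reporting (g/dl haemoglobin, µg/l ferritin, ...).

A handful of rate constants are *not* free: they are derived in closed form
from the steady-state identities (see :mod:`ferropoiesis.steady_state`) and
stored on :class:`ParameterSet.derived`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import TYPE_CHECKING, Any, Iterator

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .steady_state import DerivedConstants


class ParameterError(ValueError):
    """Inadmissible or inconsistent model parameters."""


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the shared saturating-response family.

    ``v_nor`` is the anchor value returned at unit argument; ``v_min`` and
    ``v_max`` are the plateaus.  ``b > 0`` gives an increasing response with
    limits ``v_min`` at 0 and ``v_max`` at infinity; ``b < 0`` swaps the
    limits and yields a decreasing response.  The anchor identity
    ``response(1) = v_nor`` holds for either sign.
    """

    v_min: float
    v_max: float
    v_nor: float
    b: float

    def check(self) -> list[str]:
        errs = []
        if not self.v_min < self.v_nor < self.v_max:
            errs.append(
                f"sigmoid requires v_min < v_nor < v_max, got "
                f"({self.v_min}, {self.v_nor}, {self.v_max})"
            )
        if self.b == 0:
            errs.append("sigmoid exponent b must be nonzero")
        return errs


@dataclass(frozen=True)
class SigmoidBank:
    """All sigmoid blocks used by the model.

    ``hepcidin_production``, ``zferro`` and ``ztrf`` are the three iron
    regulators; the remaining blocks drive endogenous EPO production and the
    EPO effect on marrow amplification / maturation.  Every block except
    ``hepcidin_production`` is normalised (``v_nor = 1``) so that the
    reference state is a fixed point; ``hepcidin_production.v_nor`` is the
    homeostatic production rate in 1/day.
    """

    hepcidin_production: SigmoidParams = SigmoidParams(0.2, 8.0, 2.0, 4.0)
    zferro: SigmoidParams = SigmoidParams(0.05, 1.05, 1.0, -3.0)
    ztrf: SigmoidParams = SigmoidParams(0.5, 1.2, 1.0, -2.0)
    epo_production: SigmoidParams = SigmoidParams(0.05, 10.0, 1.0, -6.0)
    amp_ce: SigmoidParams = SigmoidParams(0.05, 1.2, 1.0, 0.6)
    amp_peb: SigmoidParams = SigmoidParams(0.05, 1.5, 1.0, 0.8)
    maturation: SigmoidParams = SigmoidParams(0.6, 1.8, 1.0, 0.8)

    #: blocks whose anchor must be 1 for the all-ones state to be stationary
    _UNIT_ANCHORED = ("zferro", "ztrf", "epo_production", "amp_ce", "amp_peb", "maturation")

    def check(self) -> list[str]:
        errs = []
        for f in fields(self):
            sig: SigmoidParams = getattr(self, f.name)
            errs.extend(f"sigmoids.{f.name}: {e}" for e in sig.check())
        for name in self._UNIT_ANCHORED:
            if getattr(self, name).v_nor != 1.0:
                errs.append(f"sigmoids.{name}: v_nor must be 1 (normalised regulator)")
        return errs


@dataclass(frozen=True)
class RegulatorWeights:
    """Weights of the hepcidin and transferrin production drives."""

    k_HEPFS: float = 0.3
    k_HEPFP: float = 1.0
    k_HEPHB: float = 0.5
    k_TRFFP: float = 1.0
    k_TRFHB: float = 1.0
    k_TRFFS: float = 1.0
    k_TRFHEP: float = 0.3

    def check(self) -> list[str]:
        errs = []
        for f in fields(self):
            if getattr(self, f.name) < 0:
                errs.append(f"weights.{f.name} must be >= 0")
        if self.k_HEPFS + self.k_HEPFP + self.k_HEPHB <= 0:
            errs.append("hepcidin drive weights must have positive sum")
        if self.k_TRFFP + self.k_TRFHB + self.k_TRFFS + self.k_TRFHEP <= 0:
            errs.append("transferrin drive weights must have positive sum")
        return errs


@dataclass(frozen=True)
class IronParams:
    """Free rate constants of the iron subsystem (units 1/day unless noted).

    ``FeDiet_nor`` and ``Fe_intest_max`` are in mg/day of elemental iron;
    ``Fe_tinf`` is the iv infusion duration in days.  ``HEP_inflammation``
    and ``hep_production_factor`` are neutral by default and are installed
    by scenario modifiers (chronic inflammation / haemochromatosis).
    """

    k_S: float = 0.02             # storage <-> plasma exchange
    k_ul: float = 9.0             # transferrin loading
    k_MM: float = 3.0             # Michaelis constant of loading (NTBI units)
    k_PEB: float = 1.0            # transferrin recycled at marrow uptake
    d_TRFl: float = 0.5           # loaded-transferrin degradation at uptake
    k_TRFu: float = 8.0           # transferrin production rate
    alpha: float = 2.0            # TRFl uptake exponent (dimensionless)
    d_Fe: float = 0.05            # non-recycled fraction of erythrocyte iron
    d_entero: float = 3.0         # enterocyte decay
    Delay_intest: float = 2.0     # intestinal delay rate
    FeDiet_nor: float = 15.0      # dietary iron reaching the gut, mg/day
    Fe_intest_max: float = 30.0   # half-saturation of intestinal absorption, mg/day
    Fe_tinf: float = 15.0 / 1440.0  # iv infusion duration, days (15 min)
    HEP_inflammation: float = 0.0
    hep_production_factor: float = 1.0
    diet_factor: float = 1.0

    _POSITIVE = (
        "k_S", "k_ul", "k_MM", "k_PEB", "k_TRFu", "d_entero",
        "Delay_intest", "FeDiet_nor", "Fe_intest_max", "Fe_tinf",
    )

    def check(self) -> list[str]:
        errs = []
        for name in self._POSITIVE:
            if getattr(self, name) <= 0:
                errs.append(f"iron.{name} must be > 0")
        for name in ("d_TRFl", "HEP_inflammation", "diet_factor", "hep_production_factor"):
            if getattr(self, name) < 0:
                errs.append(f"iron.{name} must be >= 0")
        if not 0.0 <= self.d_Fe <= 1.0:
            errs.append("iron.d_Fe must lie in [0, 1]")
        if self.alpha <= 0:
            errs.append("iron.alpha must be > 0")
        return errs


@dataclass(frozen=True)
class ReferenceValues:
    """Steady-state reference values of the iron compartments.

    With the all-ones normalisation these are 1 by construction; they are
    kept explicit because the derived-constant formulas are written in terms
    of them.  ``HB_nor`` is the homeostatic haemoglobin concentration in
    g/dl and doubles as the unit bridge for the HB observable.
    """

    NTBI_0: float = 1.0
    TRFl_0: float = 1.0
    TRFu_0: float = 1.0
    F_S0: float = 1.0
    F_HB0: float = 1.0
    HEP_0: float = 1.0
    HB_nor: float = 14.0

    def check(self) -> list[str]:
        errs = []
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                errs.append(f"references.{f.name} must be > 0")
        return errs


@dataclass(frozen=True)
class CellKineticParams:
    """Cell-kinetic constants of the erythroid chain.

    Transit times ``tau_*`` are in days.  Mature erythrocytes transit 15
    ageing sub-compartments (total ``ery_transit_days``) followed by a
    random-ageing compartment with death rate ``d_rand``; ``theta_rand`` is
    a small random loss applied along the ageing chain (haemolysis).
    ``chemo_s_*`` scale the first-order chemotherapy kill rate per
    proliferating compartment; maturing cells are not hit.
    """

    beta_S: float = 0.35
    tau_BE: float = 6.0
    tau_CE: float = 6.0
    tau_PEB: float = 4.0
    tau_MEB: float = 5.0
    tau_RET: float = 2.0
    n_ages: int = 15
    ery_transit_days: float = 110.0
    theta_rand: float = 0.001
    d_rand: float = 0.1
    chemo_s_S: float = 0.15
    chemo_s_BE: float = 1.0
    chemo_s_CE: float = 1.0
    chemo_s_PEB: float = 1.0

    def check(self) -> list[str]:
        errs = []
        for name in ("beta_S", "tau_BE", "tau_CE", "tau_PEB", "tau_MEB",
                     "tau_RET", "ery_transit_days", "d_rand"):
            if getattr(self, name) <= 0:
                errs.append(f"cells.{name} must be > 0")
        for name in ("theta_rand", "chemo_s_S", "chemo_s_BE", "chemo_s_CE", "chemo_s_PEB"):
            if getattr(self, name) < 0:
                errs.append(f"cells.{name} must be >= 0")
        if self.n_ages < 1:
            errs.append("cells.n_ages must be >= 1")
        return errs


@dataclass(frozen=True)
class EpoPkParams:
    """EPO pharmacokinetics: central/peripheral exchange, saturable receptor
    binding, internalisation, linear elimination, and a subcutaneous depot.

    Amounts are relative to the endogenous steady-state content of the
    central compartment; ``epo_amount_ss_iu`` converts dosed IU into these
    units.  ``bioavailability_sc`` bounds the absorbed fraction of a
    subcutaneous dose.
    """

    k_el: float = 3.0     # linear (renal) elimination, 1/day
    k_cp: float = 1.0     # central -> peripheral, 1/day
    k_pc: float = 1.0     # peripheral -> central, 1/day
    B_max: float = 2.0    # receptor capacity, central-compartment units
    k_int: float = 2.0    # internalisation of receptor-bound EPO, 1/day
    k_a: float = 1.0      # sc depot absorption, 1/day
    bioavailability_sc: float = 0.7
    epo_amount_ss_iu: float = 50.0
    body_weight_kg: float = 70.0

    def check(self) -> list[str]:
        errs = []
        for name in ("k_el", "k_cp", "k_pc", "k_int", "k_a",
                     "epo_amount_ss_iu", "body_weight_kg"):
            if getattr(self, name) <= 0:
                errs.append(f"epo.{name} must be > 0")
        if not 0 < self.bioavailability_sc <= 1:
            errs.append("epo.bioavailability_sc must lie in (0, 1]")
        if self.B_max <= 1:
            errs.append("epo.B_max must exceed 1 (receptor-bound pool is 1 at rest)")
        return errs


@dataclass(frozen=True)
class UnitBridges:
    """Constants mapping relative model output onto clinical units."""

    blood_volume_l: float = 5.0
    hct_nor: float = 0.42
    rbc_nor_10e6_ul: float = 4.8
    ret_nor_10e3_ul: float = 60.0
    ferritin_ref_ug_l: float = 100.0
    serum_iron_ref_ug_dl: float = 100.0
    epo_ref_miu_ml: float = 10.0
    iv_iron_mg_per_unit: float = 10.0  # mg of iron per unit of plasma-iron flux

    def check(self) -> list[str]:
        errs = []
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                errs.append(f"bridges.{f.name} must be > 0")
        return errs


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameterisation of the coupled model.

    ``derived`` holds the steady-state-derived rate constants and is filled
    by :func:`ferropoiesis.steady_state.derive_constants`; a ``ParameterSet``
    must be finalised before simulation.
    """

    sigmoids: SigmoidBank = field(default_factory=SigmoidBank)
    weights: RegulatorWeights = field(default_factory=RegulatorWeights)
    iron: IronParams = field(default_factory=IronParams)
    references: ReferenceValues = field(default_factory=ReferenceValues)
    cells: CellKineticParams = field(default_factory=CellKineticParams)
    epo: EpoPkParams = field(default_factory=EpoPkParams)
    bridges: UnitBridges = field(default_factory=UnitBridges)
    derived: "DerivedConstants | None" = None

    # -- validation ------------------------------------------------------

    def check(self) -> list[str]:
        """Collect every validation violation (empty list means valid)."""
        errs = []
        for group in ("sigmoids", "weights", "iron", "references", "cells", "epo", "bridges"):
            errs.extend(getattr(self, group).check())
        return errs

    def validate(self) -> "ParameterSet":
        errs = self.check()
        if errs:
            raise ParameterError("invalid parameters:\n  " + "\n  ".join(errs))
        return self

    def finalize(self) -> "ParameterSet":
        """Return a copy with the steady-state-derived constants installed."""
        from .steady_state import derive_constants

        self.validate()
        return dataclasses.replace(self, derived=derive_constants(self))

    @property
    def is_finalized(self) -> bool:
        return self.derived is not None

    def require_derived(self) -> "DerivedConstants":
        if self.derived is None:
            raise ParameterError("ParameterSet is not finalised; call .finalize() first")
        return self.derived

    # -- dotted-path access (used by calibration and the CLI) ------------

    _GROUPS = ("sigmoids", "weights", "iron", "references", "cells", "epo", "bridges")

    def flat_items(self) -> Iterator[tuple[str, Any]]:
        """Yield ``(dotted_name, value)`` for every scalar parameter."""
        for group in self._GROUPS:
            obj = getattr(self, group)
            for f in fields(obj):
                if f.name.startswith("_"):
                    continue
                val = getattr(obj, f.name)
                if isinstance(val, SigmoidParams):
                    for sf in fields(val):
                        yield f"{group}.{f.name}.{sf.name}", getattr(val, sf.name)
                else:
                    yield f"{group}.{f.name}", val

    def get(self, path: str) -> Any:
        obj: Any = self
        for part in path.split("."):
            if not hasattr(obj, part):
                raise KeyError(f"unknown parameter {path!r}")
            obj = getattr(obj, part)
        return obj

    def with_updates(self, updates: dict[str, float], refinalize: bool = True) -> "ParameterSet":
        """Return a copy with the dotted-path ``updates`` applied.

        Derived constants are recomputed unless ``refinalize`` is False.
        """
        ps = self
        for path, value in updates.items():
            ps = _replace_path(ps, path.split("."), value)
        ps = dataclasses.replace(ps, derived=None)
        return ps.finalize() if refinalize else ps


def _replace_path(obj: Any, parts: list[str], value: Any) -> Any:
    name = parts[0]
    if not hasattr(obj, name):
        raise KeyError(f"unknown parameter {'.'.join(parts)!r}")
    if len(parts) == 1:
        return dataclasses.replace(obj, **{name: value})
    return dataclasses.replace(obj, **{name: _replace_path(getattr(obj, name), parts[1:], value)})


def default_parameters(finalize: bool = True) -> ParameterSet:
    """The shipped default parameterisation of the healthy 70 kg adult.

    Sigmoid plateaus, cell-kinetic coefficients and the EPO PK constants are
    reconstructed values calibrated against the qualitative intervention
    scenarios (see ``docs/methods.md``); they are not literature
    measurements.
    """
    ps = ParameterSet()
    return ps.finalize() if finalize else ps
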