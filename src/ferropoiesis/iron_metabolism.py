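"""Right-hand sides of the iron compartments and the derived observables.

The iron subsystem tracks hepcidin, non-transferrin-bound plasma iron
(NTBI), liver stores, loaded/free transferrin, enterocyte iron behind an
intestinal delay compartment, the haemoglobin-recycling system, and an
erythroid iron chain running in parallel to the MEB/RET/ERY cell chain.
All compartments are relative (1 at rest) except the delay compartment,
which carries mg of ingested iron in transit.

Ferroportin efficacy (``Zferro``, a decreasing function of hepcidin) gates
the three cellular effluxes: enterocyte absorption, release from stores and
macrophage recycling.
"""

from __future__ import annotations

import numpy as np

from .erythropoiesis import ErythroidChain, observed_count
from .parameters import CellKineticParams, IronParams, ParameterSet
from .regulators import sigmoid_response
from .state import layout_for


class ObservableError(ValueError):
    """An observable is undefined for the given state."""


def plasma_iron(TRFl: float, NTBI: float, k_FeTRF: float) -> float:
    """Relative plasma iron: transferrin-bound plus non-transferrin-bound."""
    if min(TRFl, NTBI, k_FeTRF) < 0:
        raise ValueError("plasma iron inputs must be non-negative")
    return k_FeTRF * TRFl + NTBI


def hepcidin_rhs(HEP: float, A: float, params: ParameterSet) -> float:
    """dHEP/dt: saturated production driven by ``A``, linear elimination,
    plus an optional constant inflammatory influx.

    ``hep_production_factor`` scales the production sigmoid (reduced in
    haemochromatosis); chronic inflammation adds ``HEP_inflammation``.
    """
    d = params.require_derived()
    production = params.iron.hep_production_factor * sigmoid_response(
        A, params.sigmoids.hepcidin_production)
    return production - d.d_HEP * HEP + params.iron.HEP_inflammation


def intestinal_delay_rhs(C_Fe: float, C_in: float, Delay_intest: float) -> float:
    """dC_Fe/dt of the intestinal delay compartment (mg): ingested iron
    ``C_in`` (mg/day) enters, the efflux ``Delay_intest * C_Fe`` feeds the
    enterocytes."""
    return C_in - Delay_intest * C_Fe


def enterocyte_rhs(F_entero: float, Fe_oral_in: float, Zferro: float,
                   params: IronParams, k_intest: float) -> float:
    """dF_entero/dt: saturating absorption of delayed luminal iron minus
    enterocyte decay and ferroportin-gated export into plasma."""
    influx = k_intest * Fe_oral_in / (params.Fe_intest_max + Fe_oral_in)
    return influx - (params.d_entero + Zferro) * F_entero


def ntbi_rhs(NTBI: float, F_entero: float, F_S: float, F_HB: float,
             TRFl: float, TRFu: float, Zferro: float, Fe_inj: float,
             params: ParameterSet) -> float:
    """dNTBI/dt: ferroportin-gated influx from enterocytes, stores and
    recycling, iv iron, reflux from loaded transferrin; losses into stores
    and onto free transferrin (Michaelis-Menten loading)."""
    p = params.iron
    d = params.require_derived()
    loading = p.k_ul * TRFu * NTBI / (p.k_MM + NTBI)
    return ((F_entero + p.k_S * F_S + d.k_HB * F_HB) * Zferro + Fe_inj
            + d.k_lu * d.k_FeTRF * TRFl - p.k_S * NTBI - loading)


def storage_rhs(F_S: float, NTBI: float, Zferro: float, k_S: float) -> float:
    """dF_S/dt: uptake from plasma NTBI, ferroportin-gated release."""
    return -k_S * Zferro * F_S + k_S * NTBI


def trfl_rhs(TRFl: float, TRFu: float, NTBI: float, PEB_out: float,
             params: ParameterSet) -> float:
    """dTRFl/dt: loading from NTBI, unloading, and marrow uptake
    proportional to the proliferating-blast efflux."""
    p = params.iron
    d = params.require_derived()
    loading = p.k_ul * TRFu * NTBI / (p.k_MM + NTBI)
    uptake = (p.k_PEB + p.d_TRFl) * PEB_out * max(TRFl, 0.0) ** p.alpha
    return loading - d.k_lu * TRFl - uptake


def trfu_rhs(TRFu: float, TRFl: float, NTBI: float, PEB_out: float,
             Z_TRF: float, params: ParameterSet) -> float:
    """dTRFu/dt: freed by unloading and by the recycled share of marrow
    uptake, produced at rate ``k_TRFu * PEB_out * Z_TRF``, degraded
    linearly."""
    p = params.iron
    d = params.require_derived()
    loading = p.k_ul * TRFu * NTBI / (p.k_MM + NTBI)
    recycled = p.k_PEB * PEB_out * max(TRFl, 0.0) ** p.alpha
    return (-loading + d.k_lu * TRFl + recycled
            + p.k_TRFu * PEB_out * Z_TRF - d.d_TRFu * TRFu)


def erythroid_iron_rhs(fe_chain: np.ndarray, maturation_factor: float,
                       PEB_out: float, TRFl: float, alpha: float,
                       cells: CellKineticParams,
                       chain: ErythroidChain) -> np.ndarray:
    """Time derivatives of ``[Fe_MEB, Fe_RET, Fe_ERY_1..n, Fe_ERY_rand]``.

    The iron chain uses the identical transition and maturation rates as the
    corresponding cell compartments; its influx is the normalised marrow
    iron uptake ``PEB_out * TRFl**alpha``.
    """
    if fe_chain.shape[0] != chain.n_ages + 3:
        raise ValueError(
            f"iron chain length {fe_chain.shape[0]} does not match the cell "
            f"chain ({chain.n_ages} ageing stages + MEB/RET/random)")
    fe_meb, fe_ret = fe_chain[0], fe_chain[1]
    fe = fe_chain[2:2 + chain.n_ages]
    fe_rand = fe_chain[2 + chain.n_ages]
    influx = PEB_out * max(TRFl, 0.0) ** alpha
    d = np.empty_like(fe_chain)
    d[0] = (influx - maturation_factor * fe_meb) / cells.tau_MEB
    d[1] = (maturation_factor * fe_meb - fe_ret) / cells.tau_RET
    d[2] = chain.k_tot * (fe_ret - fe[0])
    d[3:2 + chain.n_ages] = chain.k_tot * (fe[:-1] - fe[1:])
    d[2 + chain.n_ages] = chain.d_rand * (fe[-1] - fe_rand)
    return d


def recycling_rhs(F_HB: float, Fe_ERY_out: float, Zferro: float,
                  params: ParameterSet) -> float:
    """dF_HB/dt: the recycled share of dying-erythrocyte iron enters the
    macrophage pool; ferroportin gates its return to plasma."""
    p = params.iron
    d = params.require_derived()
    return (1.0 - p.d_Fe) * Fe_ERY_out - d.k_HB * F_HB * Zferro


OBSERVABLE_NAMES = (
    "HB", "HCT", "RBC", "RET", "EPO", "serum_iron", "ferritin", "TSAT",
    "TRF", "HEP", "Zferro", "F_S", "F_entero", "F_HB", "NTBI", "TRFl", "TRFu",
)


def observables(y: np.ndarray, params: ParameterSet,
                chain: ErythroidChain | None = None) -> dict[str, float]:
    """Clinical observables derived from a state vector.

    Haemoglobin is computed from the erythrocyte iron content (reticulocyte
    iron neglected); haematocrit and red-cell count follow the cell
    compartments at fixed mean corpuscular volume.  Serum iron scales with
    relative plasma iron and serum ferritin with the storage compartment.
    """
    lay = layout_for(params)
    if chain is None:
        chain = ErythroidChain.from_params(params.cells)
    d = params.require_derived()
    br = params.bridges

    TRFl, TRFu = float(y[lay.TRFl]), float(y[lay.TRFu])
    total_trf = TRFl + TRFu
    if total_trf <= 0:
        raise ObservableError("TSAT undefined: TRFl + TRFu is zero")

    fe_block = np.concatenate([y[lay.Fe_ERY], [y[lay.Fe_ERY_rand]]])
    cell_block = np.concatenate([y[lay.ERY], [y[lay.ERY_rand]]])
    hb_rel = observed_count(fe_block, chain)
    rbc_rel = observed_count(cell_block, chain)
    f_p = plasma_iron(TRFl, max(float(y[lay.NTBI]), 0.0), d.k_FeTRF)

    return {
        "HB": params.references.HB_nor * hb_rel,
        "HCT": br.hct_nor * rbc_rel,
        "RBC": br.rbc_nor_10e6_ul * rbc_rel,
        "RET": br.ret_nor_10e3_ul * float(y[lay.RET]),
        "EPO": br.epo_ref_miu_ml * float(y[lay.C_EPO_cent]),
        "serum_iron": br.serum_iron_ref_ug_dl * f_p / d.F_P0,
        "ferritin": br.ferritin_ref_ug_l * float(y[lay.F_S]),
        "TSAT": TRFl / total_trf,
        "TRF": total_trf / (params.references.TRFl_0 + params.references.TRFu_0),
        "HEP": float(y[lay.HEP]),
        "Zferro": sigmoid_response(max(float(y[lay.HEP]), 0.0), params.sigmoids.zferro),
        "F_S": float(y[lay.F_S]),
        "F_entero": float(y[lay.F_entero]),
        "F_HB": float(y[lay.F_HB]),
        "NTBI": float(y[lay.NTBI]),
        "TRFl": TRFl,
        "TRFu": TRFu,
    }
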