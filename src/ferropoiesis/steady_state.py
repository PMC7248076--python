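"""Steady-state parameterisation and fixed-point verification.

Most rate constants of the iron subsystem are not free: they are fixed by
requiring that the healthy reference state (all compartments at 1, the
intestinal delay compartment at its diet-driven fixed point) is stationary.
This module derives those constants in closed form and verifies the fixed
point both analytically (all right-hand sides vanish) and by long
unperturbed simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterError, ParameterSet
from .regulators import sigmoid_response

STATIONARY_TOL = 1e-10


@dataclass(frozen=True)
class DerivedConstants:
    """Rate constants fixed by the steady-state identities.

    ``d_HEP``, ``k_FeTRF``, ``k_lu``, ``d_TRFu`` and ``k_HB`` follow the
    closed-form identities of the hepcidin, NTBI, transferrin and recycling
    balances.  ``k_intest`` closes the enterocyte balance under the normal
    diet, and ``epo_production_scale`` the EPO pharmacokinetics.  The
    remaining fields cache reference quantities used throughout the model.
    """

    d_HEP: float
    k_FeTRF: float
    k_lu: float
    d_TRFu: float
    k_HB: float
    k_intest: float
    epo_production_scale: float
    Zferro_0: float
    ZTRF_0: float
    F_P0: float


def derive_constants(params: ParameterSet) -> DerivedConstants:
    """Derive the steady-state-fixed rate constants from the free parameters.

    Raises :class:`ParameterError` naming the violated identity if any
    derived constant would be negative (inadmissible free-parameter
    combination).
    """
    from .erythropoiesis import epo_production_scale

    p = params.iron
    r = params.references
    sig = params.sigmoids

    zferro_0 = sigmoid_response(r.HEP_0, sig.zferro)
    # Eq for the storage compartment has no free constant of its own: the
    # reference state can only be stationary if release balances uptake.
    if abs(zferro_0 * r.F_S0 - r.NTBI_0) > 1e-9:
        raise ParameterError(
            "storage balance requires Zferro(HEP_0) * F_S0 == NTBI_0 "
            f"(got {zferro_0 * r.F_S0:.6g} vs {r.NTBI_0:.6g}); "
            "set sigmoids.zferro.v_nor accordingly")

    d_HEP = sig.hepcidin_production.v_nor / r.HEP_0
    k_HB = (1.0 - p.d_Fe) / (r.F_HB0 * zferro_0)

    loading_0 = p.k_ul * r.TRFu_0 * r.NTBI_0 / (p.k_MM + r.NTBI_0)
    uptake_0 = (p.k_PEB + p.d_TRFl) * r.TRFl_0 ** p.alpha
    k_lu = (loading_0 - uptake_0) / r.TRFl_0
    if k_lu <= 0:
        raise ParameterError(
            "loaded-transferrin balance gives k_lu <= 0: loading at rest "
            f"({loading_0:.4g}) must exceed marrow uptake ({uptake_0:.4g})")

    ztrf_0 = sig.ztrf.v_nor  # all drives are 1 at the reference state
    d_TRFu = (-loading_0 + k_lu * r.TRFl_0 + p.k_PEB * r.TRFl_0 ** p.alpha
              + p.k_TRFu * ztrf_0) / r.TRFu_0
    if d_TRFu < 0:
        raise ParameterError(
            "free-transferrin balance gives d_TRFu < 0: increase k_TRFu or "
            "reduce the loading rate k_ul")

    # NTBI balance at the reference state (enterocyte export at rest is
    # F_entero_0 * Zferro_0 with F_entero_0 = 1)
    f_entero_0 = 1.0
    k_FeTRF = (p.k_S * r.NTBI_0 + loading_0
               - (f_entero_0 + p.k_S * r.F_S0 + k_HB * r.F_HB0) * zferro_0
               ) / (k_lu * r.TRFl_0)
    if k_FeTRF < 0:
        raise ParameterError(
            "NTBI balance gives k_FeTRF < 0: transferrin loading plus "
            "storage uptake must exceed the ferroportin-gated influxes "
            "(increase k_ul or decrease k_ul's Michaelis constant)")

    # enterocyte balance under the normal diet closes k_intest
    k_intest = ((p.d_entero + zferro_0) * f_entero_0
                * (p.Fe_intest_max + p.FeDiet_nor) / p.FeDiet_nor)

    return DerivedConstants(
        d_HEP=d_HEP,
        k_FeTRF=k_FeTRF,
        k_lu=k_lu,
        d_TRFu=d_TRFu,
        k_HB=k_HB,
        k_intest=k_intest,
        epo_production_scale=epo_production_scale(params.epo),
        Zferro_0=zferro_0,
        ZTRF_0=ztrf_0,
        F_P0=k_FeTRF * r.TRFl_0 + r.NTBI_0,
    )


def steady_state_residuals(params: ParameterSet) -> dict[str, float]:
    """Right-hand side of every compartment at the reference state."""
    from .engine import full_rhs_named

    return full_rhs_named(params)


def verify_steady_state(params: ParameterSet, simulate_days: float = 1000.0,
                        rtol: float = 1e-8, atol: float = 1e-10) -> dict[str, float]:
    """Verify the reference fixed point analytically and by simulation.

    Returns ``max_abs_rhs`` (largest time-derivative magnitude at the
    reference state) and, if ``simulate_days > 0``, ``max_drift`` (largest
    deviation of any normalised compartment from 1 over an unperturbed
    simulation of that length).
    """
    from .engine import simulate
    from .interventions import Scenario
    from .state import reference_state

    residuals = steady_state_residuals(params)
    out = {"max_abs_rhs": max(abs(v) for v in residuals.values())}
    if simulate_days > 0:
        traj = simulate(Scenario(label="unperturbed", horizon=simulate_days),
                        params, grid=min(simulate_days / 100.0, 10.0),
                        rtol=rtol, atol=atol)
        ref = reference_state(params)
        scale = np.where(ref > 0, ref, 1.0)  # C_Fe relative to its fixed point
        out["max_drift"] = float(np.max(np.abs(traj.states - ref) / scale))
    return out


def local_stability(params: ParameterSet, perturbation: float = 0.01,
                    horizon: float = 600.0, seed: int = 0) -> float:
    """Perturb-and-relax check of local stability.

    Multiplies every compartment by ``1 + perturbation * u`` with u uniform
    in [-1, 1], simulates, and returns the largest final deviation of a
    normalised compartment from 1.  Small values (well below the initial
    perturbation) indicate that the fixed point attracts.
    """
    from .engine import simulate
    from .interventions import Scenario
    from .state import reference_state

    rng = np.random.default_rng(seed)
    y0 = reference_state(params)
    y0 = y0 * (1.0 + perturbation * rng.uniform(-1.0, 1.0, size=y0.shape))
    traj = simulate(Scenario(label="perturbed", horizon=horizon), params,
                    grid=horizon / 60.0, initial_state=y0)
    ref = reference_state(params)
    scale = np.where(ref > 0, ref, 1.0)
    return float(np.max(np.abs(traj.states[-1] - ref) / scale))
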