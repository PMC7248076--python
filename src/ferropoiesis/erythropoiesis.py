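"""Cell kinetics of erythropoiesis and EPO pharmacokinetics.

The erythroid lineage is a chain of normalised compartments

    S -> BE -> CE -> PEB -> MEB -> RET -> ERY(15 ageing stages) -> random ageing

with EPO-dependent amplification of the proliferating stages (CE, PEB) and
EPO-dependent shortening of MEB maturation.  Erythrocytes are removed
age-dependently by transit through the 15 ageing stages plus a small random
loss, followed by a random-ageing compartment; the resulting death flux
drives iron recycling.  EPO itself is modelled with a subcutaneous depot, a
central and a peripheral compartment, saturable receptor binding and
internalisation; the internalised pool is the pharmacodynamically active
signal.  Endogenous EPO production is a decreasing function of haemoglobin.

Because compartments are normalised, a uniform chain rate in normalised
coordinates is equivalent to the underlying absolute chain with a geometric
steady-state profile; the absolute profile only re-enters through the
death-flux and observation weights computed in :class:`ErythroidChain`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import CellKineticParams, EpoPkParams, SigmoidParams
from .regulators import sigmoid_response


@dataclass(frozen=True)
class ErythroidChain:
    """Precomputed rates and weights of the erythrocyte ageing chain.

    ``k_tot`` is the uniform chain rate in normalised coordinates
    (transit + random loss).  ``w_out`` are the death-flux weights over the
    15 ageing stages and the random-ageing compartment (summing to 1), and
    ``w_obs`` the cell-count observation weights proportional to the
    absolute steady-state sizes of the sub-compartments.
    """

    n_ages: int
    k_tot: float
    d_rand: float
    w_out: np.ndarray = field(repr=False)
    w_obs: np.ndarray = field(repr=False)

    @classmethod
    def from_params(cls, p: CellKineticParams) -> "ErythroidChain":
        n = p.n_ages
        k_age = n / p.ery_transit_days
        theta = p.theta_rand
        k_tot = k_age + theta
        # absolute steady-state profile relative to chain influx
        q = k_age / k_tot
        e_star = np.array([q ** i / k_tot for i in range(n)])  # E_i*/I, i = 1..n
        e_rand_star = k_age * e_star[-1] / p.d_rand
        # death flux: random loss along the chain + random-ageing deaths
        w = np.empty(n + 1)
        w[:n] = theta * e_star
        w[n] = p.d_rand * e_rand_star  # equals k_age * E_n*
        w_out = w / w.sum()  # total death flux equals chain influx at rest
        v = np.concatenate([e_star, [e_rand_star]])
        return cls(n_ages=n, k_tot=k_tot, d_rand=p.d_rand,
                   w_out=w_out, w_obs=v / v.sum())


def cell_chain_rhs(cells: np.ndarray, epo_effect: float, kill: float,
                   p: CellKineticParams, chain: ErythroidChain,
                   amp_ce: SigmoidParams, amp_peb: SigmoidParams,
                   maturation: SigmoidParams) -> tuple[np.ndarray, float, float]:
    """Time derivatives of the cell block ``[S, BE, CE, PEB, MEB, RET,
    ERY_1..n, ERY_rand]``.

    Returns ``(dcells, PEB_out, MEB_out)`` where ``PEB_out`` is the
    normalised efflux of proliferating blasts (the marrow iron demand
    signal) and ``MEB_out`` the normalised efflux of maturing blasts.
    Chemotherapy kills only the proliferating compartments S..PEB, scaled by
    the per-compartment sensitivities.
    """
    S, BE, CE, PEB, MEB, RET = cells[:6]
    ery = cells[6:6 + chain.n_ages]
    ery_rand = cells[6 + chain.n_ages]

    a_ce = sigmoid_response(epo_effect, amp_ce)
    a_peb = sigmoid_response(epo_effect, amp_peb)
    m_fac = sigmoid_response(epo_effect, maturation)

    d = np.empty_like(cells)
    d[0] = p.beta_S * S * (1.0 - S) - kill * p.chemo_s_S * S
    d[1] = (S - BE) / p.tau_BE - kill * p.chemo_s_BE * BE
    d[2] = (a_ce * BE - CE) / p.tau_CE - kill * p.chemo_s_CE * CE
    d[3] = (a_peb * CE - PEB) / p.tau_PEB - kill * p.chemo_s_PEB * PEB
    peb_out = PEB
    d[4] = (peb_out - m_fac * MEB) / p.tau_MEB
    meb_out = m_fac * MEB
    d[5] = (meb_out - RET) / p.tau_RET
    d[6] = chain.k_tot * (RET - ery[0])
    d[7:6 + chain.n_ages] = chain.k_tot * (ery[:-1] - ery[1:])
    d[6 + chain.n_ages] = chain.d_rand * (ery[-1] - ery_rand)
    return d, peb_out, meb_out


def death_flux(ery_block: np.ndarray, chain: ErythroidChain) -> float:
    """Normalised efflux of the ageing system (1 at the reference state).

    ``ery_block`` holds the 15 ageing stages followed by the random-ageing
    compartment; works identically for cell counts and for the parallel
    iron chain (then it is the erythrocyte-iron outflux feeding recycling).
    """
    return float(chain.w_out @ ery_block)


def observed_count(ery_block: np.ndarray, chain: ErythroidChain) -> float:
    """Normalised circulating count over the ageing system."""
    return float(chain.w_obs @ ery_block)


def endogenous_epo(HB: float, HB_nor: float, production: SigmoidParams,
                   scale: float = 1.0) -> float:
    """Endogenous EPO production rate as a decreasing sigmoid of HB.

    At ``HB = HB_nor`` the rate equals ``scale`` (the steady-state
    production); anaemia raises it towards ``scale * v_max``.
    """
    if HB < 0:
        raise ValueError("HB must be non-negative")
    if production.b >= 0:
        raise ValueError("endogenous EPO production must decrease with HB (b < 0)")
    return scale * sigmoid_response(HB / HB_nor, production)


def epo_pk_rhs(epo: np.ndarray, endo_production: float,
               p: EpoPkParams) -> np.ndarray:
    """Time derivatives of ``[D_sc, C_cent, C_peri, C_rb, C_int]``.

    First-order central/peripheral exchange, saturable (capacity-limited)
    receptor binding, internalisation of the receptor-bound pool and linear
    elimination from the central compartment.  Doses are applied as state
    jumps by the engine, not through this RHS.
    """
    D_sc, C, Cp, Crb, Cint = epo
    k_on = p.k_int / (p.B_max - 1.0)  # steady-state binding at rest
    free_receptors = max(p.B_max - Crb, 0.0)
    binding = k_on * C * free_receptors
    d = np.empty(5)
    d[0] = -p.k_a * D_sc
    d[1] = (endo_production + p.k_a * D_sc - p.k_el * C
            - p.k_cp * C + p.k_pc * Cp - binding)
    d[2] = p.k_cp * C - p.k_pc * Cp
    d[3] = binding - p.k_int * Crb
    d[4] = p.k_int * (Crb - Cint)
    return d


def epo_production_scale(p: EpoPkParams) -> float:
    """Steady-state endogenous production rate that keeps the normalised PK
    system at the all-ones state."""
    k_on = p.k_int / (p.B_max - 1.0)
    return p.k_el + p.k_cp - p.k_pc + k_on * (p.B_max - 1.0)


def epo_dose_units(dose: float, unit: str, p: EpoPkParams) -> float:
    """Convert an EPO dose (``'iu'`` or ``'iu_per_kg'``) into normalised
    central-compartment units."""
    if dose < 0:
        raise ValueError("EPO dose must be non-negative")
    if unit == "iu":
        iu = dose
    elif unit == "iu_per_kg":
        iu = dose * p.body_weight_kg
    else:
        raise ValueError(f"unknown EPO dose unit {unit!r}")
    return iu / p.epo_amount_ss_iu


@dataclass(frozen=True)
class ChemoSchedule:
    """Cytotoxic chemotherapy as delayed, transient kill-rate pulses.

    Each application at time ``t_i`` contributes a first-order kill rate of
    ``kill_rate`` on the proliferating marrow compartments during
    ``[t_i + delay, t_i + delay + window)``; overlapping windows add.
    """

    times: tuple[float, ...]
    kill_rate: float
    window: float = 4.0
    delay: float = 1.0

    def __post_init__(self):
        if self.kill_rate < 0:
            raise ValueError("chemotherapy kill rate must be >= 0")
        if self.window <= 0:
            raise ValueError("chemotherapy toxicity window must be > 0")
        if self.delay < 0:
            raise ValueError("chemotherapy delay must be >= 0")

    def kill(self, t: float) -> float:
        """Total kill rate (1/day) at time ``t``."""
        rate = 0.0
        for ti in self.times:
            if ti + self.delay <= t < ti + self.delay + self.window:
                rate += self.kill_rate
        return rate

    def edges(self) -> list[float]:
        """Discontinuity times of the kill-rate function."""
        out = []
        for ti in self.times:
            out.append(ti + self.delay)
            out.append(ti + self.delay + self.window)
        return out


def chemo_kill(t: float, schedule: "ChemoSchedule | None") -> float:
    """Kill rate at time ``t`` (0 without a schedule)."""
    if schedule is None:
        return 0.0
    if t < 0:
        raise ValueError("time must be non-negative")
    return schedule.kill(t)
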