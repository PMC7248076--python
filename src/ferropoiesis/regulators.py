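"""Phenomenological regulators of iron homoeostasis.

The three regulators — hepcidin production, ferroportin efficacy and
transferrin production — all use the same saturating-response family

    response(x) = v_max - (v_max - v_min) * exp(-log(r) * x**b),
    r = (v_max - v_min) / (v_max - v_nor),

which is anchored so that ``response(1) = v_nor`` exactly.  With ``b > 0``
the response increases from ``v_min`` (at x = 0) to ``v_max`` (x -> inf);
with ``b < 0`` the limits swap and the response is decreasing, which is how
the hepcidin-blocked ferroportin efficacy and the transferrin drive are
realised.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import ParameterError, RegulatorWeights, SigmoidParams

__all__ = ["sigmoid_response", "hepcidin_drive", "zferro", "ztrf", "ztrf_drive"]


def sigmoid_response(x, p: SigmoidParams):
    """Evaluate the saturating response at drive ``x >= 0``.

    Accepts scalars or numpy arrays.  ``x = 0`` with a negative exponent is
    resolved by the analytic limit (the upper plateau) rather than an error,
    so trajectories that start from an unperturbed zero drive do not crash.
    """
    log_r = math.log((p.v_max - p.v_min) / (p.v_max - p.v_nor))
    if isinstance(x, (int, float)):  # fast scalar path for the ODE right-hand side
        if x < 0:
            raise ValueError("sigmoid drive must be non-negative")
        if x == 0.0:
            xb = math.inf if p.b < 0 else 0.0
        else:
            try:
                xb = x ** p.b
            except OverflowError:
                xb = math.inf
        return p.v_max - (p.v_max - p.v_min) * math.exp(-log_r * xb)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("sigmoid drive must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        xb = np.where(x > 0, np.power(np.where(x > 0, x, 1.0), p.b),
                      np.inf if p.b < 0 else 0.0)
        out = p.v_max - (p.v_max - p.v_min) * np.exp(-log_r * xb)
    return out


def hepcidin_drive(F_S: float, F_P: float, HB: float, HB_nor: float,
                   w: RegulatorWeights) -> float:
    """Weighted-mean drive of hepcidin production.

    ``F_S`` and ``F_P`` are relative storage and plasma iron (1 at rest);
    ``HB / HB_nor`` enters as a proxy for oxygen saturation.  The drive is 1
    at the reference state.
    """
    if min(F_S, F_P, HB) < 0 or HB_nor <= 0:
        raise ValueError("hepcidin drive inputs must be non-negative (HB_nor > 0)")
    total = w.k_HEPFS + w.k_HEPFP + w.k_HEPHB
    if total <= 0:
        raise ParameterError("hepcidin drive weights sum to zero")
    return (w.k_HEPFS * F_S + w.k_HEPFP * F_P + w.k_HEPHB * HB / HB_nor) / total


def zferro(HEP: float, p: SigmoidParams) -> float:
    """Ferroportin efficacy as a decreasing function of relative hepcidin.

    Gates every cellular iron efflux (enterocytes, stores, recycling
    macrophages).  Requires a negative exponent so that elevated hepcidin
    blocks iron release.
    """
    if p.b >= 0:
        raise ParameterError("zferro must be decreasing in hepcidin (b < 0)")
    return sigmoid_response(HEP, p)


def ztrf_drive(F_P: float, HB: float, HB_nor: float, F_S: float, HEP: float,
               w: RegulatorWeights) -> float:
    """Weighted mean of the regulators that suppress transferrin synthesis."""
    if min(F_P, HB, F_S, HEP) < 0 or HB_nor <= 0:
        raise ValueError("transferrin drive inputs must be non-negative (HB_nor > 0)")
    total = w.k_TRFFP + w.k_TRFHB + w.k_TRFFS + w.k_TRFHEP
    if total <= 0:
        raise ParameterError("transferrin drive weights sum to zero")
    return (w.k_TRFFP * F_P + w.k_TRFHB * HB / HB_nor
            + w.k_TRFFS * F_S + w.k_TRFHEP * HEP) / total


def ztrf(F_P: float, HB: float, HB_nor: float, F_S: float, HEP: float,
         w: RegulatorWeights, p: SigmoidParams) -> float:
    """Transferrin production drive, decreasing in each of its regulators.

    Iron deficiency, anaemia and low hepcidin all raise transferrin
    synthesis; iron excess and inflammation suppress it.
    """
    if p.b >= 0:
        raise ParameterError("ztrf must be decreasing in its drive (b < 0)")
    return sigmoid_response(ztrf_drive(F_P, HB, HB_nor, F_S, HEP, w), p)
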