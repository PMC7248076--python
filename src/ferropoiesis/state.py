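"""Flat state-vector layout of the coupled system.

The full state couples three blocks:

* erythroid cell chain: S, BE, CE, PEB, MEB, RET, 15 erythrocyte ageing
  sub-compartments and a random-ageing compartment,
* EPO pharmacokinetics: subcutaneous depot, central, peripheral,
  receptor-bound and internalised EPO,
* iron: the erythroid iron chain mirroring MEB/RET/ERY, plus hepcidin,
  NTBI, stores, loaded/free transferrin, enterocytes, the intestinal delay
  compartment and the recycling system.

Every compartment is normalised to 1 at the healthy steady state except the
intestinal delay compartment ``C_Fe`` (mg of iron in transit), whose
reference value is its diet-driven fixed point ``FeDiet_nor / Delay_intest``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .parameters import ParameterSet

CELL_NAMES = ("S", "BE", "CE", "PEB", "MEB", "RET")
EPO_NAMES = ("D_sc", "C_EPO_cent", "C_EPO_peri", "C_EPO_rb", "C_EPO_int")
IRON_SCALAR_NAMES = ("HEP", "NTBI", "F_S", "TRFl", "TRFu", "F_entero", "C_Fe", "F_HB")


class StateLayout:
    """Index map into the flat state vector for a given number of ERY ages."""

    __slots__ = ("n_ages", "S", "BE", "CE", "PEB", "MEB", "RET", "ERY",
                 "ERY_rand", "D_sc", "C_EPO_cent", "C_EPO_peri", "C_EPO_rb",
                 "C_EPO_int", "Fe_MEB", "Fe_RET", "Fe_ERY", "Fe_ERY_rand",
                 "HEP", "NTBI", "F_S", "TRFl", "TRFu", "F_entero", "C_Fe",
                 "F_HB", "size")

    def __init__(self, n_ages: int = 15):
        n = n_ages
        self.n_ages = n
        self.S, self.BE, self.CE, self.PEB, self.MEB, self.RET = range(6)
        self.ERY = slice(6, 6 + n)
        self.ERY_rand = 6 + n
        self.D_sc = 7 + n
        self.C_EPO_cent = 8 + n
        self.C_EPO_peri = 9 + n
        self.C_EPO_rb = 10 + n
        self.C_EPO_int = 11 + n
        self.Fe_MEB = 12 + n
        self.Fe_RET = 13 + n
        self.Fe_ERY = slice(14 + n, 14 + 2 * n)
        self.Fe_ERY_rand = 14 + 2 * n
        self.HEP = 15 + 2 * n
        self.NTBI = 16 + 2 * n
        self.F_S = 17 + 2 * n
        self.TRFl = 18 + 2 * n
        self.TRFu = 19 + 2 * n
        self.F_entero = 20 + 2 * n
        self.C_Fe = 21 + 2 * n
        self.F_HB = 22 + 2 * n
        self.size = 23 + 2 * n

    def names(self) -> list[str]:
        out = list(CELL_NAMES)
        out += [f"ERY_{i + 1}" for i in range(self.n_ages)]
        out += ["ERY_rand", *EPO_NAMES, "Fe_MEB", "Fe_RET"]
        out += [f"Fe_ERY_{i + 1}" for i in range(self.n_ages)]
        out += ["Fe_ERY_rand", *IRON_SCALAR_NAMES]
        return out


@lru_cache(maxsize=8)
def _layout(n_ages: int) -> StateLayout:
    return StateLayout(n_ages)


def layout_for(params: ParameterSet) -> StateLayout:
    return _layout(params.cells.n_ages)


def reference_state(params: ParameterSet) -> np.ndarray:
    """The homeostatic reference state: all ones, except the empty
    subcutaneous EPO depot and the intestinal delay compartment at its
    diet-driven fixed point."""
    lay = layout_for(params)
    y = np.ones(lay.size)
    y[lay.D_sc] = 0.0
    y[lay.C_Fe] = params.iron.FeDiet_nor / params.iron.Delay_intest
    return y
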