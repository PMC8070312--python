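"""Composition dependence of Arrhenius parameters.

ln k1 of the first-order degradation grows approximately linearly with the
dopant coordination x, with slope epsilon.  Writing the Arrhenius law per
composition, ln k1(x) = ln A(x) - Ea(x)/(R T), and differentiating in x
under that linear trend ties the two parameters together:

    Ea(x) = Ea0 + R T [ (ln A(x) - ln A0) - epsilon * x ]

so any assumed pre-exponential profile ln A(x) fixes the activation-energy
profile, and substituting back reproduces ln k1(x) = ln k1(0) + epsilon * x
identically.  No multi-temperature data enter here; this is a prediction
utility relating the parameters, with epsilon either supplied (default 4.9,
the fixture trend) or re-estimated from fitted ln k1 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ValidationError

__all__ = ["GAS_CONSTANT", "ArrheniusState", "ea_shift", "lnk_from_arrhenius",
           "epsilon_from_lnk"]

#: molar gas constant, J/(mol K)
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class ArrheniusState:
    """Reference Arrhenius parameters at x = 0 plus the ln k1 vs x slope.

    ``temperature`` defaults to the 20 degC bath of the degradation runs.
    """

    ln_a0: float  # dimensionless log pre-exponential at x=0
    ea0: float  # activation energy at x=0, J/mol
    temperature: float = 293.15  # K
    epsilon: float = 4.9  # d(ln k1)/dx, per unit x

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive (kelvin)")
        if self.ea0 < 0:
            raise ValidationError("activation energy cannot be negative")


def ea_shift(state: ArrheniusState, x: float, ln_a_x: float) -> float:
    """Activation energy at composition x given the pre-exponential there.

    Ea(x) = Ea0 + R T [ (ln A(x) - ln A0) - epsilon x ]; at x = 0 with
    ln A(x) = ln A0 this reduces to Ea0.
    """
    rt = GAS_CONSTANT * state.temperature
    return state.ea0 + rt * ((ln_a_x - state.ln_a0) - state.epsilon * x)


def lnk_from_arrhenius(
    state: ArrheniusState, x: float, ln_a_x: float, ea_x: float
) -> float:
    """Forward Arrhenius evaluation: ln k1(x) = ln A(x) - Ea(x)/(R T)."""
    return ln_a_x - ea_x / (GAS_CONSTANT * state.temperature)


def epsilon_from_lnk(xs, lnk1s) -> float:
    """Re-estimate epsilon as the least-squares slope of ln k1 on x."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(lnk1s, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValidationError("need >= 2 matching (x, ln k1) points")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
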