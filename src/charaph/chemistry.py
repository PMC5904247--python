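"""pH/pOH/concentration conversions and Nernst equilibrium potentials.

The transmembrane equilibrium potential for H+ equals that for OH- for any
pH pair (because pH + pOH is constant), which is why a proton efflux and a
hydroxide influx are electrically indistinguishable and the channel carries
the ambiguous name "H+/OH- channel".  This module does not decide which ion
is carried; it exposes both labels and guarantees the identity numerically.

Sign convention: potentials are the electrical potential of the cell
interior minus the exterior (physiological convention; resting potentials
are negative), in millivolts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .constants import CODATA2018, DEFAULT_TEMPERATURE, PhysicalConstants

Ion = Literal["H", "OH"]


@dataclass(frozen=True)
class NernstConditions:
    """External/internal pH and temperature for an equilibrium potential.

    Both pH values must lie in [0, 14]; temperature is in kelvin.
    """

    ph_out: float
    ph_in: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        _check_ph(self.ph_out, "ph_out")
        _check_ph(self.ph_in, "ph_in")
        if not self.temperature > 0:
            raise ValueError(
                f"temperature must be > 0 K, got {self.temperature}"
            )


def _check_ph(ph: float, name: str = "ph") -> None:
    if not 0.0 <= ph <= 14.0:
        bound = "lower bound 0" if ph < 0 else "upper bound 14"
        raise ValueError(f"{name}={ph} violates the {bound} of the pH scale")


def h_concentration(ph: float) -> float:
    """Proton concentration, mol/L: ``10**(-pH)``."""
    _check_ph(ph)
    return 10.0 ** (-ph)


def oh_concentration(
    ph: float, constants: PhysicalConstants = CODATA2018
) -> float:
    """Hydroxide concentration, mol/L: ``10**(pH - pKw)`` with pKw = 14.

    e.g. local pH 9 -> pOH 5 -> 1e-5 mol/L.
    """
    _check_ph(ph)
    return 10.0 ** (ph - constants.kw_pk)


def nernst_potential(
    ion: Ion,
    cond: NernstConditions,
    constants: PhysicalConstants = CODATA2018,
) -> float:
    """Equilibrium (Nernst) potential in mV for H+ (z=+1) or OH- (z=-1).

    Computed from the concentration ratio ``E = (RT / zF) ln(c_out/c_in)``
    with the inside-minus-outside sign convention.  E_H and E_OH are
    numerically identical for every pH pair.
    """
    rt_over_f = (
        constants.gas_constant * cond.temperature / constants.faraday
    )
    if ion == "H":
        z = 1.0
        c_out = h_concentration(cond.ph_out)
        c_in = h_concentration(cond.ph_in)
    elif ion == "OH":
        z = -1.0
        c_out = oh_concentration(cond.ph_out, constants)
        c_in = oh_concentration(cond.ph_in, constants)
    else:
        raise ValueError(f"unknown ion label {ion!r}; expected 'H' or 'OH'")
    return (rt_over_f / z) * math.log(c_out / c_in) * 1000.0
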