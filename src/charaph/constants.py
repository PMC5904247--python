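"""Physical constants used throughout the package.

A single authoritative home for the handful of constants the estimation
chain and the electrophysiological model depend on.  Two instances are
shipped:

``CODATA2018``
    Exact SI (CODATA 2018) values; the package default.
``ROUNDED_CONSTANTS``
    Two-significant-figure values (N_A = 6.02e23, e = 1.6e-19) of the kind
    used in back-of-envelope estimates; useful when reproducing printed
    arithmetic digit for digit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

#: Default absolute temperature, K (20 °C, the culture temperature for
#: Chara australis; also the reference temperature of the 15 fS unitary
#: proton-channel conductance).  Overridable everywhere it is used.
DEFAULT_TEMPERATURE = 293.15

#: Unitary conductance of a voltage-gated proton channel, siemens
#: (15 fS at physiological pH and 20 °C; eosinophil patch-clamp figure).
UNITARY_CONDUCTANCE = 15e-15


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants, all strictly positive.

    ``faraday`` defaults to ``avogadro * elementary_charge`` and is checked
    against that product to 1e-6 relative on construction.
    """

    avogadro: float = 6.02214076e23          # mol^-1
    elementary_charge: float = 1.602176634e-19  # C
    faraday: float | None = None             # C/mol; derived if omitted
    gas_constant: float = 8.31446261815324   # J/(mol K)
    kw_pk: float = 14.0                      # -log10 of the water ion product

    def __post_init__(self) -> None:
        if self.faraday is None:
            object.__setattr__(
                self, "faraday", self.avogadro * self.elementary_charge
            )
        for name in (
            "avogadro",
            "elementary_charge",
            "faraday",
            "gas_constant",
            "kw_pk",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        derived = self.avogadro * self.elementary_charge
        if abs(self.faraday - derived) > 1e-6 * derived:
            raise ValueError(
                "faraday must equal avogadro * elementary_charge within 1e-6 "
                f"relative (got {self.faraday}, expected {derived})"
            )

    def to_json(self) -> str:
        """Serialize to JSON for provenance records."""
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


CODATA2018 = PhysicalConstants()

ROUNDED_CONSTANTS = PhysicalConstants(
    avogadro=6.02e23, elementary_charge=1.6e-19
)
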