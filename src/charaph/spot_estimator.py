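"""From an alkaline-spot observation to an open-channel count.

A transient bright spot on the cell-wall surface reports a localized
hydroxide efflux.  Given the spot's volume and local pH, the hydroxide
content of the spot is a number of ions; ions per unit time is a current;
current per driving potential-difference excursion is a conductance; and
conductance divided by the unitary single-channel conductance is an open
channel count.  Dividing an areal membrane conductance by the unitary
conductance likewise yields an areal channel density.

Two volume conventions are supported.  ``hemisphere_volume`` computes the
geometric volume of a hemispherical cap of a given diameter.  Published
worked estimates of this kind sometimes quote a spot volume directly; a
``volume_override`` on :class:`SpotGeometry` uses such a value verbatim and
records in the output provenance which path was taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

from .chemistry import oh_concentration
from .constants import CODATA2018, UNITARY_CONDUCTANCE, PhysicalConstants

#: Cited areal density range for voltage-gated H+ channels in an eosinophil
#: membrane, channels per μm².
EOSINOPHIL_DENSITY_RANGE = (125.0, 200.0)

#: Default membrane patch area over which the open fraction is assessed, μm².
DEFAULT_PATCH_AREA_UM2 = 1.0


@dataclass(frozen=True)
class SpotGeometry:
    """Geometry and conditions of one observed alkaline spot.

    diameter μm, duration s (the time over which the ions crossed the
    membrane), local_ph at the spot, pd_excursion mV (the potential spike
    driving the conductance estimate), optional volume_override in litres.
    """

    diameter: float = 30.0
    duration: float = 10.0
    local_ph: float = 9.0
    pd_excursion: float = 10.0
    shape: str = "hemisphere"
    volume_override: float | None = None

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"diameter must be > 0 μm, got {self.diameter}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0 s, got {self.duration}")
        if not self.pd_excursion > 0:
            raise ValueError(
                f"pd_excursion must be > 0 mV, got {self.pd_excursion}"
            )
        if not 0.0 <= self.local_ph <= 14.0:
            raise ValueError(f"local_ph {self.local_ph} outside [0, 14]")
        if self.shape != "hemisphere":
            raise ValueError(f"unsupported spot shape {self.shape!r}")
        if self.volume_override is not None and not self.volume_override > 0:
            raise ValueError("volume_override must be > 0 L when given")


@dataclass(frozen=True)
class ChannelEstimate:
    """The full derived chain with the inputs that produced it."""

    oh_concentration: float      # mol/L
    volume: float                # L
    ion_count: float             # dimensionless
    mean_current: float          # A
    conductance: float           # S
    unitary_conductance: float   # S
    open_channels_real: float
    open_channels_rounded: int
    open_fraction_range: tuple[float, float]  # fraction of patch channels open
    provenance: dict[str, Any] = field(default_factory=dict)


def hemisphere_volume(diameter: float) -> float:
    """Volume of a hemisphere of the given diameter (μm), in litres.

    (2/3) π (d/2)³ μm³, with 1 μm³ = 1e-15 L.
    """
    if not diameter > 0:
        raise ValueError(f"diameter must be > 0 μm, got {diameter}")
    radius = diameter / 2.0
    return (2.0 / 3.0) * math.pi * radius**3 * 1e-15


def ion_count(
    c: float, volume: float, constants: PhysicalConstants = CODATA2018
) -> float:
    """Number of ions in a volume: N = c · V · N_A."""
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if volume < 0:
        raise ValueError(f"volume must be >= 0, got {volume}")
    return c * volume * constants.avogadro


def mean_current(
    n_ions: float, duration: float, constants: PhysicalConstants = CODATA2018
) -> float:
    """Mean current (A) carried by n_ions monovalent ions over duration s."""
    if not duration > 0:
        raise ValueError(f"duration must be > 0 s, got {duration}")
    return n_ions * constants.elementary_charge / duration


def conductance_from_current(i: float, pd_excursion: float) -> float:
    """Chord conductance (S) from a current (A) and a PD excursion (mV)."""
    if not pd_excursion > 0:
        raise ValueError(
            f"pd_excursion must be > 0 mV, got {pd_excursion}"
        )
    return i / (pd_excursion * 1e-3)


def open_channel_count(
    g: float,
    unitary: float = UNITARY_CONDUCTANCE,
    density_range: tuple[float, float] = EOSINOPHIL_DENSITY_RANGE,
    patch_area_um2: float = DEFAULT_PATCH_AREA_UM2,
) -> tuple[float, int, tuple[float, float]]:
    """Open channels behind a total conductance g.

    Returns ``(real, rounded, open_fraction_range)`` where ``real = g /
    unitary``, ``rounded`` is the nearest integer (ties away from zero), and
    the open fraction is the rounded count against a plausible total-channel
    range on the given membrane patch (default: the eosinophil density range
    on 1 μm²).  The fraction bounds are ordered low-to-high, i.e. computed
    against the high and low ends of the density range respectively.
    """
    if not unitary > 0:
        raise ValueError(f"unitary conductance must be > 0 S, got {unitary}")
    real = g / unitary
    if real < 0:
        raise ValueError("conductance must be >= 0")
    rounded = int(math.floor(real + 0.5))  # ties away from zero for real >= 0
    lo_density, hi_density = density_range
    fraction = (
        rounded / (hi_density * patch_area_um2),
        rounded / (lo_density * patch_area_um2),
    )
    return real, rounded, fraction


def areal_channel_density(
    g_area: float, unitary: float = UNITARY_CONDUCTANCE
) -> float:
    """Channels per μm² implied by an areal conductance G (S/m²).

    density = (G / γ) · 1e-12, converting per-m² to per-μm².
    """
    if not unitary > 0:
        raise ValueError(f"unitary conductance must be > 0 S, got {unitary}")
    if g_area < 0:
        raise ValueError(f"areal conductance must be >= 0, got {g_area}")
    return g_area / unitary * 1e-12


def estimate_from_spot(
    geom: SpotGeometry,
    constants: PhysicalConstants = CODATA2018,
    unitary: float = UNITARY_CONDUCTANCE,
    density_range: tuple[float, float] = EOSINOPHIL_DENSITY_RANGE,
    patch_area_um2: float = DEFAULT_PATCH_AREA_UM2,
) -> ChannelEstimate:
    """Run the full spot → channel-count chain for one spot observation.

    Every intermediate equals the corresponding standalone operation's
    result; the provenance records every input, including whether the
    volume came from the hemisphere formula or an override.
    """
    if geom.volume_override is not None:
        volume = geom.volume_override
        volume_source = "override"
    else:
        volume = hemisphere_volume(geom.diameter)
        volume_source = "hemisphere"
    c = oh_concentration(geom.local_ph, constants)
    n = ion_count(c, volume, constants)
    i = mean_current(n, geom.duration, constants)
    g = conductance_from_current(i, geom.pd_excursion)
    real, rounded, fraction = open_channel_count(
        g, unitary, density_range, patch_area_um2
    )
    provenance = {
        "diameter_um": geom.diameter,
        "duration_s": geom.duration,
        "local_ph": geom.local_ph,
        "pd_excursion_mv": geom.pd_excursion,
        "volume_source": volume_source,
        "volume_l": volume,
        "unitary_conductance_s": unitary,
        "density_range_per_um2": tuple(density_range),
        "patch_area_um2": patch_area_um2,
        "constants": {
            "avogadro": constants.avogadro,
            "elementary_charge": constants.elementary_charge,
        },
    }
    return ChannelEstimate(
        oh_concentration=c,
        volume=volume,
        ion_count=n,
        mean_current=i,
        conductance=g,
        unitary_conductance=unitary,
        open_channels_real=real,
        open_channels_rounded=rounded,
        open_fraction_range=fraction,
        provenance=provenance,
    )
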