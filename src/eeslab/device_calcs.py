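"""Closed-form engineering calculators for the implanted hardware.

Three small benchtop conversions: the molecular-flow leak-rate equivalence
between air and helium tracer gas, the linear resistivity criterion for lead
conductors, and mean battery current from capacity and therapy duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

__all__ = [
    "LeakRate",
    "M_AIR",
    "M_HELIUM",
    "air_to_helium_leak",
    "linear_resistivity",
    "battery_mean_current",
    "round_sig",
]

M_AIR = 28.97  # g/mol
M_HELIUM = 4.00  # g/mol


@dataclass(frozen=True)
class LeakRate:
    """Gas leak rate in atm·cm^3/s with its tracer gas."""

    value: float
    gas: str  # "air" or "helium"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("leak rate must be non-negative")
        if self.gas not in ("air", "helium"):
            raise ValueError("gas must be 'air' or 'helium'")


def air_to_helium_leak(rate: LeakRate) -> LeakRate:
    """Equivalent helium leak rate for an air-referenced failure limit.

    In the molecular-flow regime a leak conductance scales as
    ``1/sqrt(M)``, so the helium-equivalent rate is the air rate times
    ``sqrt(M_air / M_He)`` (about 2.69).
    """
    if rate.gas != "air":
        raise ValueError("input rate must be referenced to air")
    return LeakRate(rate.value * math.sqrt(M_AIR / M_HELIUM), "helium")


def linear_resistivity(resistance_ohm: float, length_m: float) -> float:
    """Resistance per unit length (Ω/m) of a conductor section."""
    if length_m <= 0:
        raise ValueError("length must be positive")
    return resistance_ohm / length_m


def battery_mean_current(capacity_mah: float, duration_h: float) -> float:
    """Mean current draw (mA) that empties a battery over a duration."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    return capacity_mah / duration_h


def round_sig(value: float, n_digits: int = 3) -> float:
    """Round to a number of significant figures (reporting helper)."""
    if value == 0 or not math.isfinite(value):
        return value
    exp = math.floor(math.log10(abs(value)))
    return round(value, n_digits - 1 - exp)
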