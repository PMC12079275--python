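"""Bulk conductivity from impedance and cell geometry, and single-frequency
LCR-derived quantities.

For a cylindrical measurement cell of length L and radius r, the bulk
conductivity follows from the measured impedance magnitude |Z| as

    σ = L / (|Z| · π r²)        [S/cm with L, r in cm and |Z| in Ω]

The default geometry is L = 10 cm, r = 1 cm. Conductivity ratios taken
at shared geometry reduce to inverse impedance ratios, so enhancement
factors are geometry-free.

LCR meters report a redundant set of quantities at one frequency; from
the series resistance R and reactance X:

    |Z| = sqrt(R² + X²),  θ = arctan(|X| / R)  (degrees, magnitude),
    D = R / |X|           (dissipation factor)

The sign of X (capacitive < 0, inductive > 0) is carried separately
from the reported θ magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, InvalidSpecError

__all__ = ["CellGeometry", "LCRDerived", "conductivity", "conductivity_ratios", "lcr_derive"]


@dataclass(frozen=True)
class CellGeometry:
    """Cylindrical conductivity-cell geometry (cm)."""

    length_cm: float = 10.0
    radius_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.radius_cm <= 0:
            raise InvalidSpecError("cell length and radius must be positive")

    @property
    def area_cm2(self) -> float:
        return math.pi * self.radius_cm**2

    @property
    def cell_constant_per_cm(self) -> float:
        """Geometry factor L/A converting 1/|Z| to conductivity."""
        return self.length_cm / self.area_cm2


@dataclass(frozen=True)
class LCRDerived:
    """Quantities derived from a single-frequency R/X reading."""

    z_mag_kohm: float
    theta_deg: float  # magnitude; X sign kept in reactance_sign
    dissipation: float  # R/|X|; inf when X == 0
    reactance_sign: int


def conductivity(z_mag_ohm: float, geometry: CellGeometry = CellGeometry()) -> float:
    """Bulk conductivity σ = L / (|Z|·πr²) in S/cm."""
    if z_mag_ohm <= 0:
        raise DomainError(f"impedance magnitude must be positive, got {z_mag_ohm}")
    return geometry.cell_constant_per_cm / z_mag_ohm


def conductivity_ratios(sigmas: dict[str, float], reference: str) -> dict[str, float]:
    """Each conductivity divided by the reference sample's conductivity."""
    if reference not in sigmas:
        raise InvalidSpecError(f"reference {reference!r} not among {sorted(sigmas)}")
    ref = sigmas[reference]
    if ref <= 0:
        raise DomainError(f"reference conductivity must be positive, got {ref}")
    return {name: s / ref for name, s in sigmas.items()}


def lcr_derive(r_kohm: float, x_kohm: float) -> LCRDerived:
    """|Z|, θ and dissipation factor from a series R/X pair (kΩ).

    θ is reported as a magnitude in degrees; D = R/|X| is infinite for a
    purely resistive reading (X = 0).
    """
    if r_kohm <= 0:
        raise DomainError(f"resistance must be positive, got {r_kohm}")
    z = math.hypot(r_kohm, x_kohm)
    theta = math.degrees(math.atan2(abs(x_kohm), r_kohm))
    d = math.inf if x_kohm == 0 else r_kohm / abs(x_kohm)
    sign = 0 if x_kohm == 0 else (1 if x_kohm > 0 else -1)
    return LCRDerived(z_mag_kohm=z, theta_deg=theta, dissipation=d, reactance_sign=sign)


def lcr_invert(z_mag_kohm: float, theta_deg: float, reactance_sign: int = -1) -> tuple[float, float]:
    """Reconstruct (R, X) from (|Z|, θ magnitude, sign of X)."""
    if z_mag_kohm <= 0:
        raise DomainError("impedance magnitude must be positive")
    theta = math.radians(abs(theta_deg))
    r = z_mag_kohm * math.cos(theta)
    x = reactance_sign * z_mag_kohm * math.sin(theta)
    return r, x
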