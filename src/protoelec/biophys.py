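"""Closed-form biophysical relations for proteinoid-actin networks.

A small formula library: dipole moments of alternating charged/
hydrophobic residues, membrane-like capacitance, the periodic potential
landscape along an actin filament (13 G-actin monomers per ~36 nm
helical turn), conductivity enhancement ratios, threshold-activation
dynamics, ohmic channel currents, and diffusive RC time constants.

Every function returns a :class:`BiophysQuantity` tagging the value
with its unit, so dimensional bookkeeping survives composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "BiophysQuantity",
    "dipole_moment",
    "membrane_capacitance",
    "actin_periodic_potential",
    "conductivity_enhancement",
    "threshold_update",
    "channel_current",
    "diffusive_tau",
]

_UNITS = {"C*m", "F", "1/nm", "J", "dimensionless", "mV/s", "A", "s"}


@dataclass(frozen=True)
class BiophysQuantity:
    value: float | np.ndarray
    units: str

    def __post_init__(self) -> None:
        if self.units not in _UNITS:
            raise DomainError(f"unknown unit tag {self.units!r}")
        if not np.all(np.isfinite(self.value)):
            raise DomainError("quantity value must be finite")


def dipole_moment(q_coulomb: float, d_vec_m) -> BiophysQuantity:
    """p = q·d: dipole moment (C·m) of a charge pair separated by d."""
    return BiophysQuantity(q_coulomb * np.asarray(d_vec_m, dtype=float), "C*m")


def membrane_capacitance(epsilon_F_m: float, area_m2: float, thickness_m: float) -> BiophysQuantity:
    """Parallel-plate capacitance C = εA/d of a membrane-like boundary."""
    if thickness_m <= 0:
        raise DomainError(f"thickness must be positive, got {thickness_m}")
    return BiophysQuantity(epsilon_F_m * area_m2 / thickness_m, "F")


def actin_spatial_frequency(monomers_per_turn: float = 13.0, pitch_nm: float = 36.0) -> BiophysQuantity:
    """Ion-binding-site spatial frequency f = monomers/pitch along F-actin."""
    if pitch_nm <= 0:
        raise DomainError("pitch must be positive")
    return BiophysQuantity(monomers_per_turn / pitch_nm, "1/nm")


def actin_periodic_potential(
    v0_J: float,
    x_nm,
    monomers_per_turn: float = 13.0,
    pitch_nm: float = 36.0,
) -> tuple[BiophysQuantity, BiophysQuantity]:
    """Periodic potential wells along an actin filament.

    Returns the spatial frequency f = monomers/pitch (nm⁻¹) and the
    cosine well potential U(x) = −V₀·cos(2π f x) evaluated at x (nm),
    so U(0) = −V₀ at a binding site and the landscape repeats with
    period 1/f.
    """
    f = actin_spatial_frequency(monomers_per_turn, pitch_nm)
    u = -v0_J * np.cos(2.0 * np.pi * f.value * np.asarray(x_nm, dtype=float))
    return f, BiophysQuantity(u, "J")


def conductivity_enhancement(sigma_S_cm: float, sigma_actin_S_cm: float) -> BiophysQuantity:
    """Enhancement factor σ/σ_actin over the pure-actin baseline."""
    if sigma_actin_S_cm <= 0:
        raise DomainError("baseline conductivity must be positive")
    return BiophysQuantity(sigma_S_cm / sigma_actin_S_cm, "dimensionless")


def threshold_update(v_mV: float, alpha_mV_s: float, v_th_mV: float) -> BiophysQuantity:
    """Threshold activation dV/dt = α·Θ(V − V_th), Θ(0) = 1 by convention."""
    theta = 1.0 if v_mV >= v_th_mV else 0.0
    return BiophysQuantity(alpha_mV_s * theta, "mV/s")


def channel_current(g_S: float, v_V: float, e_rev_V: float) -> BiophysQuantity:
    """Ohmic channel current I = g·(V − E_rev) in amperes."""
    return BiophysQuantity(g_S * (v_V - e_rev_V), "A")


def diffusive_tau(r_ohm: float, c_farad: float) -> BiophysQuantity:
    """Diffusive relaxation time constant τ = R·C (seconds)."""
    if r_ohm <= 0 or c_farad <= 0:
        raise DomainError("resistance and capacitance must be positive")
    return BiophysQuantity(r_ohm * c_farad, "s")
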