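"""Stokes-Einstein hydrodynamic arithmetic.

D = k_B T / (6 pi eta r_H) relates the diffusion coefficient of a sphere to
its hydrodynamic radius and the solvent viscosity; any two of (D, eta, r_H)
determine the third.  Oligomer masses scale radii roughly as MM^(1/3)
(compact globule) or MM^(1/2), giving simple mass-ratio predictions for the
diffusion of related assemblies, and the log-ratio of a reference (dilute
buffer) to an observed in vivo coefficient yields an effective cytoplasmic
viscosity: eta = eta_0 * D_0 / D_obs.

All core functions take and return strict SI units (m, m^2/s, Pa s, K);
micrometre^2/s convenience conversions are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BOLTZMANN",
    "PhysicalConditions",
    "OligomerMass",
    "stokes_einstein_D",
    "invert_viscosity",
    "invert_radius",
    "mass_scaling_ratio",
    "viscosity_from_logratio",
    "mean_viscosity",
    "um2s_to_m2s",
    "m2s_to_um2s",
]

BOLTZMANN = 1.380649e-23  # J/K, exact


def um2s_to_m2s(d: float) -> float:
    return d * 1e-12


def m2s_to_um2s(d: float) -> float:
    return d * 1e12


@dataclass(frozen=True)
class PhysicalConditions:
    """Temperature (K) and solvent viscosity (Pa s); defaults: room
    temperature, water."""

    temperature: float = 298.15
    viscosity: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.viscosity <= 0:
            raise ValueError("temperature and viscosity must be positive")


@dataclass(frozen=True)
class OligomerMass:
    """Total mass of an oligomeric assembly from (subunit mass Da, copies)."""

    subunits: tuple[tuple[float, int], ...]

    @property
    def total(self) -> float:
        return float(sum(m * n for m, n in self.subunits))


def stokes_einstein_D(r_h: float, cond: PhysicalConditions) -> float:
    """Diffusion coefficient (m^2/s) of a sphere of hydrodynamic radius
    ``r_h`` (m)."""
    if r_h <= 0:
        raise ValueError("hydrodynamic radius must be positive")
    return BOLTZMANN * cond.temperature / (6.0 * np.pi * cond.viscosity * r_h)


def invert_viscosity(d: float, r_h: float, temperature: float = 298.15) -> float:
    """Viscosity (Pa s) from an observed D (m^2/s) and a known radius (m)."""
    if d <= 0 or r_h <= 0:
        raise ValueError("D and r_h must be positive")
    return BOLTZMANN * temperature / (6.0 * np.pi * r_h * d)


def invert_radius(d: float, cond: PhysicalConditions) -> float:
    """Hydrodynamic radius (m) from an observed D (m^2/s) and viscosity."""
    if d <= 0:
        raise ValueError("D must be positive")
    return BOLTZMANN * cond.temperature / (6.0 * np.pi * cond.viscosity * d)


def mass_scaling_ratio(mm_ref: OligomerMass | float, mm_target: OligomerMass | float,
                       exponent: int = 3) -> float:
    """(MM_ref / MM_target)^(1/exponent); multiplying a reference D by this
    predicts the target assembly's D (exponent 3: compact globule; 2:
    surface-dominated scaling)."""
    ref = mm_ref.total if isinstance(mm_ref, OligomerMass) else float(mm_ref)
    tgt = mm_target.total if isinstance(mm_target, OligomerMass) else float(mm_target)
    if ref <= 0 or tgt <= 0:
        raise ValueError("masses must be positive")
    if exponent not in (2, 3):
        raise ValueError("exponent must be 2 or 3")
    return float((ref / tgt) ** (1.0 / exponent))


def viscosity_from_logratio(d0: float, d_obs: float, eta0: float = 1.0e-3) -> float:
    """eta = eta_0 * D_0 / D_obs (from ln(D_0/D_obs) = ln(eta/eta_0));
    D_0 and D_obs may be in any common unit."""
    if d0 <= 0 or d_obs <= 0 or eta0 <= 0:
        raise ValueError("all inputs must be positive")
    return eta0 * d0 / d_obs


def mean_viscosity(pairs: list[tuple[float, float]], eta0: float = 1.0e-3) -> float:
    """Average the viscosity implied by several (D_0, D_obs) pairs."""
    if not pairs:
        raise ValueError("need at least one (D_0, D_obs) pair")
    return float(np.mean([viscosity_from_logratio(d0, dobs, eta0) for d0, dobs in pairs]))
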