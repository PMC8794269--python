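"""Effective viscosity of plasma and nanoparticle-laden plasma.

Wild-type zebrafish blood is treated as a two-phase suspension (red blood
cells tracked individually, plasma as the carrier), while *gata1* mutants
lacking red blood cells are treated as plasma only.  Injected lipid
nanodroplets raise the plasma viscosity; their effect is modelled with the
Corcione correlation for dilute nanofluids,

    mu_eff / mu_f = 1 / (1 - 34.87 (d_p / d_f)^-0.3 * phi^1.03)

where ``d_p`` is the nanoparticle diameter, ``phi`` the nanoparticle volume
fraction and ``d_f`` the equivalent diameter of a base-fluid molecule,

    d_f = 0.1 * (6 M / (N pi rho_f0))^(1/3)

with ``M`` the molecular weight of the base fluid, ``rho_f0`` its mass
density at the reference temperature and ``N`` Avogadro's number.  The
correlation was fitted for volume fractions 1e-4..0.071 and particle sizes
25..200 nm; outside those ranges a warning is raised but the value is still
returned, because the plasma d_p/d_f ratio itself sits at the edge of the
tested regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "AVOGADRO",
    "PLASMA",
    "FluidSpec",
    "NanofluidSpec",
    "CorcioneValidityWarning",
    "equivalent_molecule_diameter",
    "effective_viscosity",
    "injection_volume_fraction",
]

#: Avogadro's number (mol^-1).
AVOGADRO = 6.022e23

#: Corcione correlation validity ranges.
PHI_VALID = (1e-4, 0.071)
DP_VALID = (25e-9, 200e-9)


class CorcioneValidityWarning(UserWarning):
    """Inputs fall outside the correlation's fitted parameter ranges."""


@dataclass(frozen=True)
class FluidSpec:
    """Physical parameters of a base fluid.

    Parameters
    ----------
    mu_f : float
        Dynamic viscosity in mPa·s.
    molecular_weight : float
        Molecular weight M in kg/mol.
    density : float
        Mass density rho_f0 at the reference temperature, kg/m^3.
    temperature : float
        Reference temperature T0 in kelvin.  Carried for provenance; the
        correlation itself is temperature-free because plasma viscosity is
        approximately constant over the relevant range.
    """

    mu_f: float
    molecular_weight: float
    density: float
    temperature: float = 293.0

    def __post_init__(self) -> None:
        if self.mu_f <= 0:
            raise ValueError(f"mu_f must be positive, got {self.mu_f}")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")


#: Zebrafish blood plasma: 1.5 mPa·s, 100 kDa mean protein weight, 997 kg/m^3.
PLASMA = FluidSpec(mu_f=1.5, molecular_weight=100.0, density=997.0, temperature=293.0)


@dataclass(frozen=True)
class NanofluidSpec:
    """A base fluid carrying nanoparticles of diameter ``d_p`` (m) at
    volume fraction ``phi``."""

    fluid: FluidSpec
    d_p: float
    phi: float

    def __post_init__(self) -> None:
        if self.d_p <= 0:
            raise ValueError("d_p must be positive")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"phi must be in [0, 1), got {self.phi}")

    @property
    def in_validity_range(self) -> bool:
        phi_ok = PHI_VALID[0] <= self.phi <= PHI_VALID[1]
        dp_ok = DP_VALID[0] <= self.d_p <= DP_VALID[1]
        return phi_ok and dp_ok


def equivalent_molecule_diameter(fluid: FluidSpec) -> float:
    """Equivalent diameter of a base-fluid molecule, in metres.

    d_f = 0.1 * (6 M / (N pi rho_f0))^(1/3)
    """
    return 0.1 * (6.0 * fluid.molecular_weight
                  / (AVOGADRO * math.pi * fluid.density)) ** (1.0 / 3.0)


def effective_viscosity(spec: NanofluidSpec) -> float:
    """Effective dynamic viscosity of the nanofluid, in the units of
    ``spec.fluid.mu_f`` (mPa·s by convention).

    Raises
    ------
    ValueError
        If the correlation diverges, i.e. 34.87 (d_p/d_f)^-0.3 phi^1.03 >= 1.

    Warns
    -----
    CorcioneValidityWarning
        When phi or d_p fall outside the fitted ranges (value still returned).
    """
    if spec.phi > 0 and not spec.in_validity_range:
        warnings.warn(
            f"phi={spec.phi:g}, d_p={spec.d_p:g} m outside the correlation's "
            f"fitted ranges phi in {PHI_VALID}, d_p in {DP_VALID}",
            CorcioneValidityWarning,
            stacklevel=2,
        )
    ratio = viscosity_ratio(spec)
    return ratio * spec.fluid.mu_f


def viscosity_ratio(spec: NanofluidSpec) -> float:
    """Dimensionless mu_eff / mu_f (independent of the base viscosity)."""
    if spec.phi == 0.0:
        return 1.0
    d_f = equivalent_molecule_diameter(spec.fluid)
    term = 34.87 * (spec.d_p / d_f) ** (-0.3) * spec.phi ** 1.03
    if term >= 1.0:
        raise ValueError(
            f"Corcione correlation diverges: 34.87 (d_p/d_f)^-0.3 phi^1.03 = "
            f"{term:.4g} >= 1; the suspension is outside the model's domain"
        )
    return 1.0 / (1.0 - term)


def injection_volume_fraction(
    stock_fraction: float, injected_volume: float, blood_volume: float
) -> tuple[float, float]:
    """Nanoparticle volume fraction in blood after a bolus injection.

    A stock suspension with nanoparticle volume fraction ``stock_fraction``
    is injected (``injected_volume`` nl) into circulating blood
    (``blood_volume`` nl) and assumed to mix completely:

        phi = stock_fraction * injected / (injected + blood)

    Returns
    -------
    (phi, dilution_factor)
        ``dilution_factor = blood_volume / injected_volume`` is the simple
        1:k dilution convention used when matching the in-blood concentration
        on a rheometer (4.6 nl into 60 nl gives ~1:13).
    """
    if not 0.0 <= stock_fraction <= 1.0:
        raise ValueError("stock_fraction must be in [0, 1]")
    if injected_volume <= 0 or blood_volume <= 0:
        raise ValueError("volumes must be positive")
    phi = stock_fraction * injected_volume / (injected_volume + blood_volume)
    dilution_factor = blood_volume / injected_volume
    return phi, dilution_factor
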