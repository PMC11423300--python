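"""Closed-form DLVO pair potentials in thermal-energy units.

The interaction between two charged spheres of radius ``r`` at
center-to-center distance ``d`` is modelled as the sum of

* the nonretarded Hamaker sphere-sphere van der Waals attraction

  .. math::

     \\beta U_{vdW}(d) = -\\frac{H_A}{6 k_B T}\\left[
        \\frac{2r^2}{d^2 - 4r^2} + \\frac{2r^2}{d^2}
        + \\ln\\!\\left(1 - \\frac{4r^2}{d^2}\\right)\\right]

* and the screened-Coulomb (Yukawa) repulsion for macroions of effective
  valency :math:`Z_{eff}` in an electrolyte of Debye length
  :math:`\\kappa^{-1}`,

  .. math::

     \\beta U_{el}(d) = Z_{eff}^2 \\, L_B
        \\left[\\frac{e^{\\kappa r}}{1+\\kappa r}\\right]^2
        \\frac{e^{-\\kappa d}}{d}

with :math:`L_B` the Bjerrum length of the solvent.  Distances are in nm
and energies in units of :math:`k_B T`.  Both potentials are defined for
``d > 2r``; at and below contact the Monte Carlo engine treats the pair
energy as infinite (hard core).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (BOLTZMANN, ELEMENTARY_CHARGE, VACUUM_PERMITTIVITY,
                        WATER_RELATIVE_PERMITTIVITY, DEFAULT_DIAMETER_NM)

__all__ = [
    "InteractionParams",
    "bjerrum_length_water",
    "u_vdw",
    "u_el",
    "u_dlvo",
]


def bjerrum_length_water(temperature: float,
                         relative_permittivity: float = WATER_RELATIVE_PERMITTIVITY,
                         ) -> float:
    """Bjerrum length L_B = e^2 / (4 pi eps0 eps_r k_B T) in nm.

    With the fixed room-temperature permittivity of water (78.5) this is
    ~0.72 nm at 297 K.  Accepts liquid-water temperatures only.
    """
    if not 273.0 < temperature < 373.0:
        raise ValueError(
            f"temperature {temperature} K outside liquid-water range (273, 373)")
    if relative_permittivity <= 0:
        raise ValueError("relative permittivity must be positive")
    lb_m = ELEMENTARY_CHARGE ** 2 / (
        4.0 * np.pi * VACUUM_PERMITTIVITY * relative_permittivity
        * BOLTZMANN * temperature)
    return lb_m * 1e9


@dataclass(frozen=True)
class InteractionParams:
    """The (Z_eff, kappa^-1) pair plus fixed constants defining a DLVO system.

    Parameters
    ----------
    z_eff
        Effective macroion valency (dimensionless, >= 0).
    kappa_inv
        Debye length in nm (> 0).
    radius
        Sphere radius in nm; default half of the 3.97 nm gold-core diameter.
    hamaker
        Hamaker constant in joules.  Never stated by the source data;
        the default is the order of magnitude for gold across water.
    temperature
        Absolute temperature in kelvin.
    bjerrum_length
        Bjerrum length in nm; computed from ``temperature`` for water
        when not supplied.
    shell_thickness
        Impenetrable ligand-shell thickness in nm per particle surface.
        The Monte Carlo engine places its hard core at
        d = 2*(radius + shell_thickness); the closed-form potentials are
        unaffected (their domain remains d > 2*radius).  Zero by default;
        sterically stabilized particles need a positive value, without
        which the singular contact attraction makes the primary minimum
        an energy sink (see docs/methods.md).
    """

    z_eff: float
    kappa_inv: float
    radius: float = DEFAULT_DIAMETER_NM / 2.0
    hamaker: float = 2.5e-19
    temperature: float = 297.0
    bjerrum_length: float = field(default=None)  # type: ignore[assignment]
    shell_thickness: float = 0.0

    def __post_init__(self):
        if self.bjerrum_length is None:
            object.__setattr__(self, "bjerrum_length",
                               bjerrum_length_water(self.temperature))
        if self.z_eff < 0:
            raise ValueError("z_eff must be >= 0")
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")
        for name in ("kappa_inv", "radius", "temperature", "bjerrum_length"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be positive and finite, got {value}")

    # -- derived quantities used throughout the engine -------------------
    @property
    def kappa(self) -> float:
        """Inverse Debye length, 1/nm."""
        return 1.0 / self.kappa_inv

    @property
    def contact_distance(self) -> float:
        """Steric hard-core center distance 2*(radius + shell), nm."""
        return 2.0 * (self.radius + self.shell_thickness)

    @property
    def hamaker_beta(self) -> float:
        """H_A / (6 k_B T), the dimensionless van der Waals prefactor."""
        return self.hamaker / (6.0 * BOLTZMANN * self.temperature)

    @property
    def yukawa_prefactor(self) -> float:
        """Z^2 L_B (e^{kr}/(1+kr))^2, the Yukawa amplitude in nm*k_BT."""
        kr = self.kappa * self.radius
        surface = np.exp(kr) / (1.0 + kr)
        return self.z_eff ** 2 * self.bjerrum_length * surface ** 2


def _check_domain(d: np.ndarray, params: InteractionParams) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(d <= 2.0 * params.radius):
        raise ValueError(
            "pair distance at or below contact (d <= 2r): the pair energy is "
            "infinite; the MC engine must reject such moves")
    return d


def u_vdw(d, params: InteractionParams):
    """Hamaker sphere-sphere van der Waals attraction, in k_B*T.

    Nonpositive, strictly increasing in d and -> 0 as d -> inf.  Raises
    for d <= 2r (contact/overlap).
    """
    d = _check_domain(d, params)
    two_r2 = 2.0 * params.radius ** 2
    d2 = d * d
    four_r2 = 2.0 * two_r2
    bracket = two_r2 / (d2 - four_r2) + two_r2 / d2 + np.log1p(-four_r2 / d2)
    return -params.hamaker_beta * bracket


def u_el(d, params: InteractionParams):
    """Screened-Coulomb (Yukawa) repulsion between charged spheres, in k_B*T.

    Nonnegative, strictly decreasing in d.  Raises for d <= 2r.
    """
    d = _check_domain(d, params)
    return params.yukawa_prefactor * np.exp(-params.kappa * d) / d


def u_dlvo(d, params: InteractionParams):
    """Total DLVO pair potential u_vdw + u_el, in k_B*T (d > 2r)."""
    return u_vdw(d, params) + u_el(d, params)
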