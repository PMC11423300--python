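"""Physical constants and the package's unit conventions.

Unit conventions (chosen to match common SAXS practice and kept rigid
throughout the package):

* lengths in real space -- nanometres (particle radius, Debye length,
  box edge, pair distances, Bjerrum length);
* scattering vector q -- inverse Angstroms, as written in .dat files;
* energies -- units of k_B*T (dimensionless);
* number density -- nm^-3.

The single nm <-> Angstrom conversion lives in :func:`q_in_nm_inv`; every
reciprocal/real-space product in the scattering module goes through it.
"""

from __future__ import annotations

import numpy as np

# CODATA 2018
BOLTZMANN = 1.380649e-23  # J/K
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Relative permittivity of water near room temperature.
WATER_RELATIVE_PERMITTIVITY = 78.5

#: Bulk gold mass density, used to convert mg/mL concentrations of
#: gold-core nanoparticles into particle number densities.
GOLD_DENSITY_G_CM3 = 19.32

#: Best-fit gold-core diameter of the MUS-AuNP system (nm).
DEFAULT_DIAMETER_NM = 3.97

ANGSTROM_PER_NM = 10.0


def q_in_nm_inv(q_ang_inv):
    """Convert a scattering vector from 1/Angstrom to 1/nm (q_nm = 10*q_A)."""
    return np.asarray(q_ang_inv, dtype=float) * ANGSTROM_PER_NM


def aunp_number_density(mg_per_ml: float = 40.0,
                        diameter_nm: float = DEFAULT_DIAMETER_NM) -> float:
    """Particle number density (nm^-3) of a gold-nanoparticle solution.

    Converts a mass concentration assuming solid gold cores of the given
    diameter.  At 40 mg/mL and d = 3.97 nm this gives ~6.3e-5 nm^-3, i.e.
    a volume fraction of ~2e-3.
    """
    if mg_per_ml <= 0 or diameter_nm <= 0:
        raise ValueError("concentration and diameter must be positive")
    radius_cm = diameter_nm / 2.0 / 1e7
    particle_volume_cm3 = 4.0 / 3.0 * np.pi * radius_cm ** 3
    mass_per_particle_g = GOLD_DENSITY_G_CM3 * particle_volume_cm3
    per_cm3 = (mg_per_ml * 1e-3) / mass_per_particle_g
    return per_cm3 / 1e21  # cm^-3 -> nm^-3


#: Number density of the 40 mg/mL sample whose structure factor the
#: simulations emulate.
DEFAULT_NUMBER_DENSITY = aunp_number_density()
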