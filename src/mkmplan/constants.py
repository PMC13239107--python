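"""Physical constants and the central lineal/specific energy conversion.

All microdosimetric quantities in this package use a single unit convention:
lineal energy ``y`` in keV/um, lengths in um, density in g/cm^3 and specific
energy ``z`` in Gy.
"""

from __future__ import annotations

import numpy as np

#: Atomic mass unit rest energy (MeV).
AMU_MEV = 931.49410242

#: Electron rest energy (MeV).
ELECTRON_MASS_MEV = 0.51099895

#: 4*pi*N_A*r_e^2*m_e*c^2 per mol (MeV cm^2 / mol) -- Bethe prefactor.
K_BETHE = 0.307075

#: <Z/A> of liquid water.
Z_OVER_A_WATER = 0.55509

#: Radiation length of water (cm at unit density).
X0_WATER_CM = 36.08

#: Default density of water (g/cm^3).
RHO_WATER = 1.0

#: Energy-to-dose conversion: 1 keV deposited in 1 pg of matter is 0.1602 Gy.
#:
#: Dimensional analysis: 1 keV = 1.602e-16 J; 1 um^3 of unit-density matter
#: has a mass of 1e-12 g = 1 pg = 1e-15 kg, hence
#: z[Gy] = 0.1602 * e[keV] / (rho[g/cm^3] * V[um^3]).
KEV_PER_PG_TO_GY = 0.1602


def specific_energy(y, radius_um, rho: float = RHO_WATER):
    """Convert lineal energy ``y`` (keV/um) to specific energy ``z`` (Gy).

    Uses the conventional sensitive-volume relation z = 0.1602*y/(rho*pi*r^2)
    for a site of radius ``radius_um``.
    """
    return KEV_PER_PG_TO_GY * np.asarray(y) / (rho * np.pi * radius_um**2)


def lineal_energy(z, radius_um, rho: float = RHO_WATER):
    """Inverse of :func:`specific_energy`; exact round-trip by construction."""
    return np.asarray(z) * (rho * np.pi * radius_um**2) / KEV_PER_PG_TO_GY
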