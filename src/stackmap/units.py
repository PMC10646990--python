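"""Physical constants and small unit-conversion helpers.

Everything downstream works in the natural units of total scattering:
lengths in angstroms (Å), momentum transfer Q in Å⁻¹, scattering lengths
in fm, number densities in atoms·Å⁻³ and intensities in cm⁻¹ (absolute
scale) or barns·sr⁻¹·atom⁻¹ (per-atom scale).
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _c

#: 1 Å⁻¹ expressed in cm⁻¹ (used when Δρ²·V, an Å⁻¹ quantity, is put on
#: the absolute cm⁻¹ scale of a SANS curve).
INV_ANGSTROM_TO_INV_CM = 1.0e8

#: Molarity of pure water at room temperature, mol/L.
WATER_MOLARITY = 55.5


def bjerrum_length(temperature: float = 298.0, dielectric: float = 78.3) -> float:
    """Bjerrum length e²/(4π ε₀ ε_r k_B T) in Å."""
    if temperature <= 0 or dielectric <= 0:
        raise ValueError("temperature and dielectric constant must be positive")
    lb_m = _c.e**2 / (4 * np.pi * _c.epsilon_0 * dielectric * _c.k * temperature)
    return lb_m * 1e10


def debye_kappa(
    ionic_strength: float, temperature: float = 298.0, dielectric: float = 78.3
) -> float:
    """Inverse Debye screening length κ in Å⁻¹ for a 1:1 electrolyte.

    ``ionic_strength`` is in mol/L.  κ² = 8π λ_B n with n the number
    density of each ion species in Å⁻³.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    n_per_a3 = ionic_strength * _c.N_A * 1e-27  # mol/L -> ions/Å³
    return float(np.sqrt(8 * np.pi * bjerrum_length(temperature, dielectric) * n_per_a3))


def molarity_from_mole_ratio(
    n_solute: float, n_water: float, water_molarity: float = WATER_MOLARITY
) -> float:
    """Solute molarity (mol/L) implied by a solute:water mole ratio.

    A 1:500 peptide:water ratio in 55.5 M water corresponds to
    55.5/500 = 0.111 M, i.e. 111 mM.
    """
    if n_solute <= 0 or n_water <= 0:
        raise ValueError("mole counts must be positive")
    return water_molarity * n_solute / n_water
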