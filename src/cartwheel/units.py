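"""Unit system and physical constants.

The simulation unit system is nm / ns / k_BT at T = 293 K.  Concentrations
are expressed in μM and converted with an explicit Avogadro factor;
viscosity defaults to water at 293 K (1.0 mPa·s).
"""

from __future__ import annotations

KB_J_PER_K = 1.380649e-23
AVOGADRO = 6.02214076e23

#: default absolute temperature (K)
T_DEFAULT = 293.0

#: k_BT at the default temperature, in joule
KBT_J = KB_J_PER_K * T_DEFAULT

#: number density of a 1 μM solution, in nm^-3
PER_NM3_PER_UM = AVOGADRO * 1e-6 / 1e24  # mol/L -> molecules/nm^3

#: viscosity of water at 293 K in simulation units (k_BT · ns / nm^3)
VISCOSITY_WATER = 1.0e-3 * 1e-18 / KBT_J


def viscosity_si_to_sim(eta_pa_s: float, temperature: float = T_DEFAULT) -> float:
    """Convert a viscosity in Pa·s to k_BT·ns/nm³ at the given temperature."""
    return eta_pa_s * 1e-18 / (KB_J_PER_K * temperature)


def molar_to_density(c_um: float) -> float:
    """Concentration in μM -> number density in nm^-3."""
    return c_um * PER_NM3_PER_UM


def density_to_molar(rho_per_nm3: float) -> float:
    """Number density in nm^-3 -> concentration in μM."""
    return rho_per_nm3 / PER_NM3_PER_UM


def count_to_molar(n: int | float, volume_nm3: float) -> float:
    """Number of molecules in a volume (nm³) -> concentration in μM."""
    return density_to_molar(n / volume_nm3)


def molar_to_count(c_um: float, volume_nm3: float) -> float:
    """Concentration in μM -> expected molecule count in a volume (nm³)."""
    return molar_to_density(c_um) * volume_nm3


#: rate-constant conversion: (nm³/ns) -> (μM⁻¹ s⁻¹)
NM3_PER_NS_TO_PER_UM_S = 1e9 * PER_NM3_PER_UM
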