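"""Unit system for the simulation.

All internal quantities are expressed in nanometres and thermal energy units
(k_B T at the configured temperature).  SI values from the literature
(bond depths in joules, spring constants in N/m, flexural rigidities in
pN nm) are converted once at the configuration boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, J/K (CODATA exact value).
K_B = 1.380649e-23


@dataclass(frozen=True)
class UnitSystem:
    """Conversions between SI and the internal (nm, k_B T) unit system.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Default 300 K.
    """

    temperature: float = 300.0

    @property
    def kBT_joule(self) -> float:
        """Thermal energy k_B T in joules."""
        return K_B * self.temperature

    # -- energies ---------------------------------------------------------
    def joule_to_kBT(self, e_joule: float) -> float:
        return e_joule / self.kBT_joule

    def kBT_to_joule(self, e_kBT: float) -> float:
        return e_kBT * self.kBT_joule

    def pN_nm_to_kBT(self, e_pn_nm: float) -> float:
        """pN*nm (= 1e-21 J) to k_B T."""
        return e_pn_nm * 1e-21 / self.kBT_joule

    def kBT_to_pN_nm(self, e_kBT: float) -> float:
        return e_kBT * self.kBT_joule / 1e-21

    # -- spring constants -------------------------------------------------
    def N_per_m_to_kBT_per_nm2(self, k_si: float) -> float:
        """N/m (= J/m^2 = 1e-18 J/nm^2) to k_B T / nm^2."""
        return k_si * 1e-18 / self.kBT_joule

    def kBT_per_nm2_to_N_per_m(self, k_int: float) -> float:
        return k_int * self.kBT_joule / 1e-18
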