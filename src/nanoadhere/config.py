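"""Configuration loading with literature defaults and unit conversion.

The machine-readable default table mirrors the model's parameter set
(units stated per key, citation note per entry); a YAML/JSON config file
overrides any subset.  Unknown keys are rejected.  SI inputs are
converted to the internal (nm, k_B T) unit system at this boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mesh import MembraneParams
from .molecules import BondParams, Carrier, ReceptorParams, receptor_count
from .units import UnitSystem


class ConfigError(ValueError):
    pass


#: key -> (default, unit, note)
DEFAULTS: dict[str, tuple] = {
    "temperature_K": (300.0, "K", "system temperature"),
    "patch_area_um2": (0.25, "um^2", "simulation surface area"),
    "box_height_um": (0.5, "um", "simulation height L_z"),
    "nc_diameter_nm": (100.0, "nm", "carrier diameter 2 r_NC"),
    "receptor_length_nm": (19.0, "nm", "receptor rod length L_an"),
    "antibody_length_nm": (15.0, "nm", "ligand rod length L_ab"),
    "receptor_density_per_um2": (2000.0, "um^-2",
                                 "receptor surface density (projected area)"),
    "n_antibodies": (162, "count", "ligands per carrier N_ab"),
    "H0_J": (-7.98e-20, "J", "bond free-energy depth"),
    "kappa_b_N_per_m": (1.0, "N/m", "bond spring constant"),
    "kappa_f_pN_nm": (7000.0, "pN nm",
                      "receptor flexural rigidity (energy per rad^2)"),
    "d_star_nm": (1.0, "nm", "bond reaction range (configurable)"),
    "kappa_kBT": (20.0, "kBT", "membrane bending rigidity"),
    "sigma_kBT_per_nm2": (0.0, "kBT/nm^2", "membrane surface tension"),
    "a0_nm": (10.0, "nm", "membrane discretization length"),
    "link_max_factor": (math.sqrt(3.0), "-", "tether maximum / a0"),
    "link_min_factor": (0.75, "-", "tether hard core / a0"),
    "pinning_fraction": (0.0, "-", "cytoskeletal pinning fraction (0-0.12)"),
    "L_nm": (None, "nm", "projected patch side; sqrt(area) when absent"),
    "shear_rate_per_s": (6000.0, "1/s",
                         "flow shear rate (recorded; flow not modelled here)"),
    "glycocalyx_height_nm": (100.0, "nm",
                             "glycocalyx height (recorded; not modelled)"),
    "glycocalyx_stiffness_J_per_m4": (3.9e9, "J/m^4",
                                      "glycocalyx stiffness (recorded; "
                                      "not modelled)"),
    "D_EC_um": (5.0, "um", "endothelial cell diameter"),
    "D_M_um": (5.0, "um", "macrophage diameter"),
    "L_EC_b_nm": (100.0, "nm", "bound-layer thickness r* (EC)"),
    "L_M_b_nm": (100.0, "nm", "bound-layer thickness r* (macrophage)"),
    "r_star_nm": (100.0, "nm", "PMF cutoff fallback"),
}


@dataclass
class Parameters:
    """Validated configuration in internal units."""

    raw: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.raw[key]

    # -- derived, internal units ----------------------------------------
    @property
    def units(self) -> UnitSystem:
        return UnitSystem(self.raw["temperature_K"])

    @property
    def L(self) -> float:
        if self.raw.get("L_nm"):
            return float(self.raw["L_nm"])
        L = math.sqrt(self.raw["patch_area_um2"]) * 1000.0
        a0 = self.raw["a0_nm"]
        return round(L / a0) * a0

    @property
    def L_z(self) -> float:
        return self.raw["box_height_um"] * 1000.0

    def membrane_params(self) -> MembraneParams:
        return MembraneParams(
            kappa=self.raw["kappa_kBT"],
            sigma=self.raw["sigma_kBT_per_nm2"],
            a0=self.raw["a0_nm"],
            L=self.L,
            temperature=self.raw["temperature_K"],
            link_max_factor=self.raw["link_max_factor"],
            link_min_factor=self.raw["link_min_factor"],
        )

    def receptor_params(self) -> ReceptorParams:
        return ReceptorParams(
            length=self.raw["receptor_length_nm"],
            kappa_f=self.units.pN_nm_to_kBT(self.raw["kappa_f_pN_nm"]),
        )

    def bond_params(self) -> BondParams:
        return BondParams(
            H0=self.units.joule_to_kBT(self.raw["H0_J"]),
            kappa_b=self.units.N_per_m_to_kBT_per_nm2(
                self.raw["kappa_b_N_per_m"]),
            d_star=self.raw["d_star_nm"],
        )

    def carrier(self, center=None) -> Carrier:
        r = self.raw["nc_diameter_nm"] / 2.0
        if center is None:
            center = np.array([self.L / 2.0, self.L / 2.0,
                               r + self.raw["receptor_length_nm"]
                               + self.raw["antibody_length_nm"] + 1.0])
        return Carrier(
            center=np.asarray(center, dtype=float),
            radius=r,
            ligand_length=self.raw["antibody_length_nm"],
            n_ligands=int(self.raw["n_antibodies"]),
        )

    def n_receptors(self) -> int:
        return receptor_count(self.raw["receptor_density_per_um2"],
                              self.L**2)

    def describe(self) -> dict:
        """Defaults table with units and notes (for manifests and docs)."""
        return {
            k: {"value": self.raw[k], "unit": DEFAULTS[k][1],
                "note": DEFAULTS[k][2]}
            for k in DEFAULTS
        }


def load_config(path=None, overrides: dict | None = None) -> Parameters:
    """Load and validate a YAML/JSON config; absent keys take defaults.

    Unknown keys raise ConfigError naming the key and listing the unit
    conventions of the nearest valid keys.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    unknown = set(data) - set(DEFAULTS)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(
            f"unknown configuration key {key!r}; valid keys state their "
            f"unit in the name (e.g. 'H0_J' expects joules)")
    merged = {k: v[0] for k, v in DEFAULTS.items()}
    merged.update(data)
    p = Parameters(raw=merged)
    # basic sanity
    if merged["temperature_K"] <= 0:
        raise ConfigError("temperature_K must be positive")
    if not (0.0 <= merged["pinning_fraction"] <= 0.12):
        raise ConfigError("pinning_fraction outside [0, 0.12]")
    if merged["H0_J"] >= 0:
        raise ConfigError("H0_J must be negative (a bound state)")
    return p
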