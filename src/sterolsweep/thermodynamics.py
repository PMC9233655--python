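"""From docking energies to mole-fraction binding constants.

Docking energies for a sterol inside a membrane slab include hydrogen bonding
of the sterol hydroxyl to the bilayer-interface donor layers as well as to the
protein. To obtain a binding constant for the protein site alone, in the
concentration scale appropriate for membrane solutes (mole fractions), each
docking energy goes through a three-step chain:

1. molar -> mole-fraction standard state: a constant offset (default
   -0.7 kcal/mol, the uniform shift observed between the two standard states
   for this ligand/solvent combination);
2. subtraction of the interfacial *multiplex* hydrogen bond: a single hydroxyl
   acceptor engaging multiple interface donors, ~60% stronger than a canonical
   hydrogen bond in a hydrophobic environment (1.6 x -6.5 = -10.4 kcal/mol in
   mole-fraction units);
3. conversion to an association constant, dG = -RT ln Ka, at 298.15 K.

All energies are kcal/mol; Ka is dimensionless on the mole-fraction scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ThermoConstants",
    "EnergyRecord",
    "to_mole_fraction",
    "multiplex_hbond_energy",
    "subtract_interface_hbond",
    "association_constant",
    "occupancy",
    "half_occupancy_molpercent",
    "additivity_gap",
    "domain_preference",
    "build_energy_record",
    "energy_table",
    "round_sig",
]

#: gas constant in kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.987204259e-3
STANDARD_TEMPERATURE = 298.15


@dataclass(frozen=True)
class ThermoConstants:
    """Constants of the docking-energy -> binding-constant chain."""

    temperature: float = STANDARD_TEMPERATURE  # K
    canonical_hbond: float = -6.5  # kcal/mol, mole-fraction units
    multiplex_factor: float = 1.6  # "60% stronger" than canonical
    molar_to_molefraction_offset: float = -0.7  # kcal/mol

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.multiplex_factor <= 1:
            raise ValueError("multiplex factor must exceed 1")

    @property
    def RT(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature


DEFAULTS = ThermoConstants()


@dataclass(frozen=True)
class EnergyRecord:
    """One site's full docking-energy -> association-constant chain."""

    site: str
    dG_dock_molar: float
    dG_molefraction: float
    dG_protein_only: float
    Ka: float


def to_mole_fraction(dG_molar: float, constants: ThermoConstants = DEFAULTS) -> float:
    """Convert a molar-standard-state docking energy to mole-fraction units."""
    if not math.isfinite(dG_molar):
        raise ValueError("docking energy must be finite")
    return dG_molar + constants.molar_to_molefraction_offset


def multiplex_hbond_energy(constants: ThermoConstants = DEFAULTS) -> float:
    """Free energy of the sterol-OH multiplex hydrogen bond to the interface."""
    return constants.multiplex_factor * constants.canonical_hbond


def subtract_interface_hbond(
    dG_molefraction: float, constants: ThermoConstants = DEFAULTS
) -> float:
    """Binding energy for the protein alone (interface H-bond term removed)."""
    if not math.isfinite(dG_molefraction):
        raise ValueError("energy must be finite")
    return dG_molefraction - multiplex_hbond_energy(constants)


def association_constant(dG: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Ka = exp(-dG / RT), dimensionless in the dG's concentration scale."""
    if not math.isfinite(dG):
        raise ValueError("energy must be finite")
    return math.exp(-dG / (GAS_CONSTANT_KCAL * temperature))


def occupancy(Ka: float, chol_molpercent: float) -> float:
    """Fractional site occupancy f = Ka x / (1 + Ka x), x in mole fraction."""
    if Ka < 0 or chol_molpercent < 0:
        raise ValueError("Ka and cholesterol content must be non-negative")
    x = chol_molpercent / 100.0
    return Ka * x / (1.0 + Ka * x)


def half_occupancy_molpercent(Ka: float) -> float:
    """Cholesterol content (mol%) at which the site is 50% occupied: 100/Ka."""
    if Ka <= 0:
        raise ValueError("Ka must be positive")
    result = 100.0 / Ka
    if result >= 100.0:
        warnings.warn(
            f"half-occupancy at {result:g} mol% is formally >= a pure-cholesterol "
            "membrane; unphysical",
            stacklevel=2,
        )
    return result


def additivity_gap(
    dimer: EnergyRecord, scap: EnergyRecord, insig: EnergyRecord
) -> float:
    """Dimer-site corrected energy minus the sum of the two monomer-site ones.

    A gap of zero means the Scap and Insig half-site contributions to sterol
    binding at the dimer interface are independent and additive.
    """
    return dimer.dG_protein_only - (scap.dG_protein_only + insig.dG_protein_only)


def domain_preference(mean_TM: float, mean_luminal: float) -> float:
    """TM-over-luminal binding preference (kcal/mol, positive = TM favoured)."""
    if not (math.isfinite(mean_TM) and math.isfinite(mean_luminal)):
        raise ValueError("means must be finite")
    return mean_luminal - mean_TM


def build_energy_record(
    site: str, dG_dock_molar: float, constants: ThermoConstants = DEFAULTS
) -> EnergyRecord:
    """Run the full chain from a molar docking energy."""
    dG_mf = to_mole_fraction(dG_dock_molar, constants)
    dG_protein = subtract_interface_hbond(dG_mf, constants)
    Ka = association_constant(dG_protein, constants.temperature)
    return EnergyRecord(site, dG_dock_molar, dG_mf, dG_protein, Ka)


def energy_table(
    sites: list[tuple[str, float]], constants: ThermoConstants = DEFAULTS
) -> pd.DataFrame:
    """Tabulate the chain for several sites (Ka shown at 2 significant figures)."""
    records = [build_energy_record(name, dg, constants) for name, dg in sites]
    return pd.DataFrame(
        {
            "site": [r.site for r in records],
            "dG_dock_molar": [r.dG_dock_molar for r in records],
            "dG_molefraction": [r.dG_molefraction for r in records],
            "dG_protein_only": [r.dG_protein_only for r in records],
            "Ka": [r.Ka for r in records],
            "Ka_2sf": [round_sig(r.Ka, 2) for r in records],
        }
    )


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
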