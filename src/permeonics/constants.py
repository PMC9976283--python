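"""Physical constants and unit conversions.

Internal unit system: lengths in Å, time in ns, energies in units of
k_B·T at the configured temperature (303 K by default, the temperature of
the simulations the analyses are designed for), electron densities in
e/Å³, charge in units of the elementary charge.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, J/K (CODATA, exact).
K_BOLTZMANN = 1.380649e-23
#: Elementary charge, C (CODATA, exact).
E_CHARGE = 1.602176634e-19
#: Avogadro number, 1/mol (CODATA, exact).
N_AVOGADRO = 6.02214076e23
#: Bohr radius in Å (CODATA 2018).
BOHR_TO_ANGSTROM = 0.529177210903
#: Debye per e·Å.
DEBYE_PER_E_ANGSTROM = 4.80320
#: Hartree in J (CODATA 2018).
HARTREE_TO_J = 4.3597447222071e-18

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 303.0


@dataclass(frozen=True)
class Constants:
    """Read-only registry of thermal constants at a given temperature."""

    temperature: float = DEFAULT_TEMPERATURE

    @property
    def kT_joule(self) -> float:
        """k_B·T in J."""
        return K_BOLTZMANN * self.temperature

    @property
    def kT_kj_per_mol(self) -> float:
        """k_B·T in kJ/mol."""
        return K_BOLTZMANN * self.temperature * N_AVOGADRO / 1000.0

    @property
    def kT_ev(self) -> float:
        """k_B·T in eV; useful to express a transmembrane voltage q·V in k_BT."""
        return K_BOLTZMANN * self.temperature / E_CHARGE

    @property
    def volt_per_kT_e(self) -> float:
        """Voltage (V) corresponding to 1 k_BT per elementary charge."""
        return self.kT_ev


def density_to_mol_per_liter(density_per_A3: float) -> float:
    """Convert a number density in Å⁻³ to a molar concentration in mol/L.

    One particle per Å³ is 1/(N_A · 1e-27 L) mol/L ≈ 1660.54 mol/L.
    """
    return density_per_A3 * 1e27 / N_AVOGADRO
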