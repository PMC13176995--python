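"""Physical constants and unit conventions.

All thermodynamic quantities in this package are kept on the kcal/mol
scale, concentrations in mol/L, time in seconds, temperature in kelvin.
Constants are CODATA-2018 exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

#: kcal/mol per hartree, used when ingesting absolute electronic-structure
#: energies (the library otherwise works with relative energies only).
KCAL_PER_HARTREE = 627.5094740631

#: Gas constant in J mol^-1 K^-1 (exact).
R_JOULE = 8.31446261815324

#: One standard atmosphere in Pa (exact).
ATM_PA = 101325.0


@dataclass(frozen=True)
class KineticConstants:
    """Bundle of constants entering Eyring / equilibrium expressions.

    Attributes
    ----------
    k_b : float
        Boltzmann constant, J/K.
    h : float
        Planck constant, J*s.
    r_gas : float
        Gas constant, kcal mol^-1 K^-1.
    temperature : float
        Absolute temperature in K. Defaults to 298.15 K (25 degC).
    water_conc : float
        Solvent water concentration in mol/L used to convert the
        elementary aquation rate constant into a pseudo-first-order
        observable. 55.5 M is the molarity of neat water.
    """

    k_b: float = 1.380649e-23
    h: float = 6.62607015e-34
    r_gas: float = 1.98720425864e-3
    temperature: float = 298.15
    water_conc: float = 55.5

    def __post_init__(self) -> None:
        for name in ("k_b", "h", "r_gas", "temperature", "water_conc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.r_gas * self.temperature

    @property
    def kbt_over_h(self) -> float:
        """Eyring prefactor k_B*T/h in s^-1 (~6.21e12 at 298.15 K)."""
        return self.k_b * self.temperature / self.h

    def at_temperature(self, temperature: float) -> "KineticConstants":
        return replace(self, temperature=temperature)


#: Shared default constant set at 298.15 K.
DEFAULT_CONSTANTS = KineticConstants()
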