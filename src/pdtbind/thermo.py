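"""Thermodynamic conventions.

All energies in this package are in kcal/mol and temperatures in kelvin.
The Boltzmann constant is fixed at 0.0019872041 kcal/(mol K); the inverse
temperature beta = 1/(kB*T) therefore has units of mol/kcal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in kcal/(mol K).
KB = 0.0019872041


@dataclass(frozen=True)
class ThermoSpec:
    """Temperature and derived inverse temperature.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    boltzmann_constant : float
        kB in kcal/(mol K). Fixed by convention; exposed for completeness.
    """

    temperature: float = 300.0
    boltzmann_constant: float = KB

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not self.boltzmann_constant > 0:
            raise ValueError("boltzmann_constant must be positive")

    @property
    def kt(self) -> float:
        """Thermal energy kB*T in kcal/mol."""
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        """Inverse temperature 1/(kB*T) in mol/kcal."""
        return 1.0 / self.kt


DEFAULT_THERMO = ThermoSpec()
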