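"""Physical constants and thermodynamic state.

Units throughout the package: energies in kcal/mol, lengths in Å for
bead-level work (collective-variable landscapes use their own CV units),
temperatures in kelvin.  Time on model landscapes is dimensionless reduced
time; :data:`SECONDS_PER_REDUCED_TIME` calibration constants convert it to
seconds where a physical timescale is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in kcal/(mol·K)
KB_KCAL_MOL_K = 0.0019872041

#: Coulomb constant in kcal·Å/(mol·e²)
COULOMB_KCAL_A_E2 = 332.0637


@dataclass(frozen=True)
class SimulationConstants:
    """Thermodynamic state of a run: temperature and derived β = 1/(kB·T)."""

    temperature: float = 300.0  # kelvin
    kB: float = KB_KCAL_MOL_K   # kcal/(mol·K)
    beta: float = field(init=False)  # mol/kcal

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.kB <= 0:
            raise ValueError(f"kB must be positive, got {self.kB}")
        object.__setattr__(self, "beta", 1.0 / (self.kB * self.temperature))

    @property
    def kT(self) -> float:
        """Thermal energy kB·T in kcal/mol."""
        return self.kB * self.temperature


#: Default room-temperature state used throughout.
ROOM = SimulationConstants()
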