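"""Physical constants and unit conventions.

Units used package-wide: length µm, time ms or s (stated per field),
concentration µM, voltage mV, amounts in ions.  All membrane flux densities
are ions·µm⁻²·s⁻¹.  A single conversion constant links ion counts to
concentrations so that no silent molar/count mix-ups can occur.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Avogadro constant, mol⁻¹ (CODATA exact).
AVOGADRO = 6.02214076e23

#: Faraday constant, C/mol.
FARADAY = 96485.33212

#: Molar gas constant, J/(mol·K).
GAS_CONSTANT = 8.31446262

#: Ions per µm³ per µM: N_A · 1e-6 mol/L · 1e-15 L/µm³.
IONS_PER_UM_UM3 = AVOGADRO * 1e-6 * 1e-15  # = 602.214076

#: Default temperature, K ("room temperature" recordings).
ROOM_TEMPERATURE_K = 295.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Temperature-dependent electro-thermal constants.

    Attributes
    ----------
    faraday_over_RT : float
        F/(R·T) in V⁻¹ at the stated temperature; multiplied by a gating
        charge (in elementary charges) and a voltage it gives the
        dimensionless Boltzmann exponent Q·F·V/(R·T).
    ions_per_uM_um3 : float
        Ions per µm³ of volume per µM of concentration (≈ 602.214).
    temperature_K : float
        Absolute temperature.
    """

    temperature_K: float = ROOM_TEMPERATURE_K
    ions_per_uM_um3: float = IONS_PER_UM_UM3

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def faraday_over_RT(self) -> float:
        """F/(R·T) in inverse volts."""
        return FARADAY / (GAS_CONSTANT * self.temperature_K)

    @property
    def faraday_over_RT_per_mV(self) -> float:
        """F/(R·T) in inverse millivolts (convenience for mV inputs)."""
        return self.faraday_over_RT * 1e-3


DEFAULT_CONSTANTS = PhysicalConstants()
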