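"""Physical constants used by the electrophysiology calculations."""

from dataclasses import dataclass

FARADAY_C_PER_MOL = 96485.0
GAS_CONSTANT_J_PER_MOL_K = 8.314
DEFAULT_TEMPERATURE_K = 310.15  # 37 degrees C


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday and gas constants with an overridable temperature.

    F and R are fixed; only the temperature may vary between experiments.
    """

    temperature_K: float = DEFAULT_TEMPERATURE_K

    @property
    def F(self) -> float:
        return FARADAY_C_PER_MOL

    @property
    def R(self) -> float:
        return GAS_CONSTANT_J_PER_MOL_K

    @property
    def RT_over_F(self) -> float:
        """Thermal voltage R*T/F in volts."""
        return self.R * self.temperature_K / self.F

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError(f"temperature_K must be > 0, got {self.temperature_K}")
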