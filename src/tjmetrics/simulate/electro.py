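"""Simulated dilution-potential / TER measurements from known permeabilities.

The forward model runs the same algebra as :mod:`tjmetrics.barrier` in the
forward direction: true TER follows from P_Na + P_Cl via the
conductance-permeability relation, the true dilution potential from
beta = P_Na/P_Cl via GHK; blank values and Gaussian noise are then added to
produce raw records exactly as an instrument would report them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..barrier import (
    ElectroRecord,
    IonSolution,
    ghk_dilution_potential,
    solution_a,
    solution_b,
)
from ..constants import DEFAULT_TEMPERATURE_K, PhysicalConstants
from ..barrier import MM_TO_MOL_PER_CM3

__all__ = ["ElectroSpec", "generate_electro_dataset", "true_ter_ohm_cm2"]


@dataclass(frozen=True)
class ElectroSpec:
    """Ground-truth permeabilities plus measurement-noise model."""

    true_P_Na: float = 1e-5  # cm/s
    true_P_Cl: float = 2e-6  # cm/s
    membrane_area_cm2: float = 1.12
    solution_apical: IonSolution = field(default_factory=solution_a)
    solution_basolateral: IonSolution = field(default_factory=solution_b)
    temperature_K: float = DEFAULT_TEMPERATURE_K
    blank_resistance_ohm: float = 100.0
    blank_potential_mV: float = 0.5
    resistance_noise_sd_ohm: float = 0.0
    potential_noise_sd_mV: float = 0.0
    reference_NaCl_mM: float = 140.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_P_Na <= 0 or self.true_P_Cl <= 0:
            raise ValueError("true permeabilities must be > 0")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")
        if self.membrane_area_cm2 <= 0:
            raise ValueError("membrane_area_cm2 must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.resistance_noise_sd_ohm < 0 or self.potential_noise_sd_mV < 0:
            raise ValueError("noise SDs must be >= 0")


def true_ter_ohm_cm2(spec: ElectroSpec) -> float:
    """TER implied by the spec's true permeabilities (inverse of the
    conductance-permeability relation)."""
    const = PhysicalConstants(spec.temperature_K)
    c_mol_cm3 = spec.reference_NaCl_mM * MM_TO_MOL_PER_CM3
    total = spec.true_P_Na + spec.true_P_Cl
    return (const.R * const.temperature_K / const.F**2) / (total * c_mol_cm3)


def generate_electro_dataset(spec: ElectroSpec) -> list[ElectroRecord]:
    """Emit raw replicate records (blank and noise included)."""
    rng = np.random.default_rng(spec.seed)
    ter = true_ter_ohm_cm2(spec)
    beta = spec.true_P_Na / spec.true_P_Cl
    v_mV = ghk_dilution_potential(
        beta, spec.solution_apical, spec.solution_basolateral, spec.temperature_K
    )
    records = []
    for _ in range(spec.n_replicates):
        r_noise = (
            spec.resistance_noise_sd_ohm * rng.standard_normal()
            if spec.resistance_noise_sd_ohm > 0
            else 0.0
        )
        v_noise = (
            spec.potential_noise_sd_mV * rng.standard_normal()
            if spec.potential_noise_sd_mV > 0
            else 0.0
        )
        records.append(
            ElectroRecord(
                raw_resistance_ohm=ter / spec.membrane_area_cm2
                + spec.blank_resistance_ohm
                + r_noise,
                blank_resistance_ohm=spec.blank_resistance_ohm,
                raw_potential_mV=v_mV + spec.blank_potential_mV + v_noise,
                blank_potential_mV=spec.blank_potential_mV,
                area_cm2=spec.membrane_area_cm2,
                apical=spec.solution_apical,
                basolateral=spec.solution_basolateral,
                temperature_K=spec.temperature_K,
            )
        )
    return records
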