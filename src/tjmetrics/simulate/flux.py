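"""Simulated tracer-flux time series under the sink assumption.

True apical amount Q(t) = P_app * A * C0 * t (apical concentration assumed
negligible against the basolateral C0), converted to fluorescence through a
linear calibration; noiseless calibration standards spanning the series'
amount range are emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..barrier import MM_TO_MOL_PER_CM3

__all__ = ["FluxSpec", "RawFluxDataset", "generate_flux_dataset"]


@dataclass(frozen=True)
class FluxSpec:
    """Ground-truth apparent permeability plus assay geometry and noise."""

    true_P_app: float = 2e-6  # cm/s
    area_cm2: float = 1.12
    C0_mM: float = 0.2
    sample_times_h: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    calib_slope: float = 5000.0  # fluorescence units per nmol
    calib_intercept: float = 10.0
    fluorescence_noise_sd: float = 0.0
    n_standards: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times_h, dtype=float)
        if t.size < 1 or np.any(t < 0) or (t.size > 1 and not np.all(np.diff(t) > 0)):
            raise ValueError("sample_times_h must be non-negative and strictly increasing")
        if self.C0_mM <= 0 or self.area_cm2 <= 0:
            raise ValueError("C0_mM and area_cm2 must be > 0")
        if self.true_P_app < 0:
            raise ValueError("true_P_app must be >= 0")
        if self.calib_slope <= 0:
            raise ValueError("calib_slope must be > 0")
        if self.fluorescence_noise_sd < 0:
            raise ValueError("fluorescence_noise_sd must be >= 0")
        if self.n_standards < 2:
            raise ValueError("n_standards must be >= 2")


@dataclass(frozen=True)
class RawFluxDataset:
    """Raw assay output: fluorescence readings plus calibration standards."""

    times_h: np.ndarray
    fluorescence: np.ndarray
    standard_amounts_nmol: np.ndarray
    standard_fluorescence: np.ndarray
    C0_mM: float
    area_cm2: float


def _true_Q_nmol(spec: FluxSpec, times_h: np.ndarray) -> np.ndarray:
    c0_mol_cm3 = spec.C0_mM * MM_TO_MOL_PER_CM3
    q_mol = spec.true_P_app * spec.area_cm2 * c0_mol_cm3 * (times_h * 3600.0)
    return q_mol * 1e9


def generate_flux_dataset(spec: FluxSpec) -> RawFluxDataset:
    """Emit one flux series and its (noiseless) calibration standards."""
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.sample_times_h, dtype=float)
    q_nmol = _true_Q_nmol(spec, times)
    fluor = spec.calib_slope * q_nmol + spec.calib_intercept
    if spec.fluorescence_noise_sd > 0:
        fluor = fluor + spec.fluorescence_noise_sd * rng.standard_normal(fluor.shape)
    # standards cover the series' range with headroom; amount 0 included
    q_max = float(q_nmol.max())
    top = 1.2 * q_max if q_max > 0 else 1.0
    std_amounts = np.linspace(0.0, top, spec.n_standards)
    std_fluor = spec.calib_slope * std_amounts + spec.calib_intercept
    return RawFluxDataset(
        times_h=times,
        fluorescence=fluor,
        standard_amounts_nmol=std_amounts,
        standard_fluorescence=std_fluor,
        C0_mM=spec.C0_mM,
        area_cm2=spec.area_cm2,
    )
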