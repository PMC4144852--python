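"""Tight-junction barrier physiology.

Transepithelial resistance (TER) with blank subtraction, charge selectivity
(P_Na/P_Cl) from NaCl dilution potentials via the Goldman-Hodgkin-Katz
voltage relation, absolute P_Na and P_Cl from TER via the
conductance-permeability (Kimizuka-Koketsu) relation, linear fluorescence
calibration, and tracer apparent permeability P_app = (dQ/dt)/(A*C0).

Unit contract: concentrations in mM unless suffixed otherwise, resistances
in ohm or ohm*cm^2 as named, potentials in mV, permeabilities in cm/s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats

from .constants import PhysicalConstants

logger = logging.getLogger(__name__)

MM_TO_MOL_PER_CM3 = 1e-6  # 1 mM = 1e-3 mol/L = 1e-6 mol/cm^3


# --------------------------------------------------------------------------
# solutions


@dataclass(frozen=True)
class IonSolution:
    """Monovalent ion totals of a bathing solution, in mM.

    Divalent cations (Mg, Ca) are not tracked as permeant species; they
    enter only through the Cl they contribute. Use :meth:`from_salts` to
    build totals from salt recipes.
    """

    na_mM: float
    k_mM: float
    cl_mM: float

    def __post_init__(self) -> None:
        for name in ("na_mM", "k_mM", "cl_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_salts(
        cls,
        nacl_mM: float = 0.0,
        kcl_mM: float = 0.0,
        mgcl2_mM: float = 0.0,
        cacl2_mM: float = 0.0,
    ) -> "IonSolution":
        """Build ion totals from salt concentrations.

        Cl total = NaCl + KCl + 2*MgCl2 + 2*CaCl2.  Non-ionic components
        (sucrose, glucose, HEPES) are osmotic ballast and do not appear.
        """
        return cls(
            na_mM=nacl_mM,
            k_mM=kcl_mM,
            cl_mM=nacl_mM + kcl_mM + 2.0 * mgcl2_mM + 2.0 * cacl2_mM,
        )


def solution_a() -> IonSolution:
    """Standard apical solution: 140 NaCl / 5 KCl / 1 MgCl2 / 1 CaCl2 (mM)."""
    return IonSolution.from_salts(nacl_mM=140.0, kcl_mM=5.0, mgcl2_mM=1.0, cacl2_mM=1.0)


def solution_b() -> IonSolution:
    """NaCl-diluted basolateral solution: 70 NaCl / 5 KCl / 1 MgCl2 / 1 CaCl2 (mM),
    osmolarity balanced with sucrose (not tracked)."""
    return IonSolution.from_salts(nacl_mM=70.0, kcl_mM=5.0, mgcl2_mM=1.0, cacl2_mM=1.0)


# --------------------------------------------------------------------------
# records and results


@dataclass(frozen=True)
class ElectroRecord:
    """One raw electrophysiology measurement with its blank references."""

    raw_resistance_ohm: float
    blank_resistance_ohm: float
    raw_potential_mV: float
    blank_potential_mV: float
    area_cm2: float
    apical: IonSolution
    basolateral: IonSolution
    temperature_K: float

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise ValueError("area_cm2 must be > 0")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")

    @property
    def corrected_potential_mV(self) -> float:
        return self.raw_potential_mV - self.blank_potential_mV


@dataclass(frozen=True)
class PermeabilityResult:
    """Derived barrier parameters for one record."""

    TER_ohm_cm2: float
    beta: float  # P_Na / P_Cl
    P_Na_cm_s: float
    P_Cl_cm_s: float


@dataclass(frozen=True)
class FluxSeries:
    """Apical tracer amount (nmol, after calibration) vs time for one monolayer."""

    times_h: np.ndarray
    Q_nmol: np.ndarray
    C0_mM: float
    area_cm2: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        q = np.asarray(self.Q_nmol, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "Q_nmol", q)
        if t.ndim != 1 or t.size < 1 or q.shape != t.shape:
            raise ValueError("times_h and Q_mol must be 1-D arrays of equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times_h must be strictly increasing")
        if self.C0_mM <= 0 or self.area_cm2 <= 0:
            raise ValueError("C0_mM and area_cm2 must be > 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear fluorescence-vs-amount calibration, fluorescence = slope*x + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def apply(self, fluorescence: np.ndarray | float) -> np.ndarray | float:
        """Invert the calibration: amount = (fluorescence - intercept) / slope."""
        return (np.asarray(fluorescence, dtype=float) - self.intercept) / self.slope


# --------------------------------------------------------------------------
# operations


def compute_ter(record: ElectroRecord) -> float:
    """Blank-subtracted TER in ohm*cm^2: (R_raw - R_blank) * area."""
    dr = record.raw_resistance_ohm - record.blank_resistance_ohm
    if dr <= 0:
        raise ValueError(
            f"raw resistance ({record.raw_resistance_ohm} ohm) must exceed the blank "
            f"({record.blank_resistance_ohm} ohm); non-positive TER is unphysical"
        )
    return dr * record.area_cm2


def ghk_dilution_potential(
    beta: float,
    apical: IonSolution,
    basolateral: IonSolution,
    temperature_K: float | None = None,
    kappa: float | None = None,
) -> float:
    """Forward GHK dilution potential in mV, apical relative to basolateral.

    V = (RT/F) * ln[(beta*Na_ap + kappa*K_ap + Cl_bl) /
                    (beta*Na_bl + kappa*K_bl + Cl_ap)]

    with beta = P_Na/P_Cl and kappa = P_K/P_Cl.  By default K+ is treated
    like Na+ (kappa = beta).  Only monovalent ions carry current; divalents
    contribute solely through their Cl counter-ions (already folded into the
    solution Cl totals).
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if kappa is None:
        kappa = beta
    const = PhysicalConstants(temperature_K or PhysicalConstants().temperature_K)
    num = beta * apical.na_mM + kappa * apical.k_mM + basolateral.cl_mM
    den = beta * basolateral.na_mM + kappa * basolateral.k_mM + apical.cl_mM
    if num <= 0 or den <= 0:
        raise ValueError("degenerate solutions: GHK argument non-positive")
    return const.RT_over_F * math.log(num / den) * 1e3


def nernst_limits_mV(
    apical: IonSolution, basolateral: IonSolution, temperature_K: float
) -> tuple[float, float]:
    """Attainable dilution-potential interval (sorted) as beta spans (0, inf).

    beta -> inf gives the cation Nernst limit, beta -> 0 the anion limit.
    """
    const = PhysicalConstants(temperature_K)
    v_cation = const.RT_over_F * math.log(
        (apical.na_mM + apical.k_mM) / (basolateral.na_mM + basolateral.k_mM)
    ) * 1e3
    v_anion = const.RT_over_F * math.log(basolateral.cl_mM / apical.cl_mM) * 1e3
    return (min(v_cation, v_anion), (max(v_cation, v_anion)))


def ghk_ratio(record: ElectroRecord, kappa: float | None = None) -> float:
    """Invert the blank-corrected dilution potential for beta = P_Na/P_Cl.

    The GHK relation is linear in beta at fixed kappa, so the inversion is
    closed-form; when kappa is tied to beta (the default) the same closed
    form applies with K+ grouped with Na+.
    """
    v_mV = record.corrected_potential_mV
    lo, hi = nernst_limits_mV(record.apical, record.basolateral, record.temperature_K)
    if not (lo < v_mV < hi):
        raise ValueError(
            f"corrected potential {v_mV:.4g} mV outside the attainable interval "
            f"({lo:.4g}, {hi:.4g}) mV for these solutions; beta is unbounded"
        )
    const = PhysicalConstants(record.temperature_K)
    e = math.exp(v_mV * 1e-3 / const.RT_over_F)
    ap, bl = record.apical, record.basolateral
    if kappa is None:
        # kappa = beta: group K with Na
        num = e * ap.cl_mM - bl.cl_mM
        den = (ap.na_mM + ap.k_mM) - e * (bl.na_mM + bl.k_mM)
    else:
        num = e * ap.cl_mM - bl.cl_mM - kappa * (ap.k_mM - e * bl.k_mM)
        den = ap.na_mM - e * bl.na_mM
    if den == 0:
        raise ValueError(
            "beta unidentifiable: solutions too symmetric for this potential"
        )
    beta = num / den
    if beta <= 0:
        raise ValueError(f"inverted beta non-positive ({beta:.4g}); check sign convention")
    return beta


def kimizuka_koketsu(
    TER_ohm_cm2: float,
    beta: float,
    reference_NaCl_mM: float = 140.0,
    temperature_K: float | None = None,
) -> tuple[float, float]:
    """Absolute (P_Na, P_Cl) in cm/s from TER and the permeability ratio.

    Conductance-permeability relation with a symmetric NaCl reference
    concentration C (mol/cm^3):

        P_Na + P_Cl = (RT / F^2) / (TER * C)

    then the total is split by beta: P_Na = beta/(1+beta) * total.
    """
    if TER_ohm_cm2 <= 0:
        raise ValueError("TER must be > 0")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if reference_NaCl_mM <= 0:
        raise ValueError("reference_NaCl_mM must be > 0")
    const = PhysicalConstants(temperature_K or PhysicalConstants().temperature_K)
    c_mol_cm3 = reference_NaCl_mM * MM_TO_MOL_PER_CM3
    total = (const.R * const.temperature_K / const.F**2) / (TER_ohm_cm2 * c_mol_cm3)
    p_na = beta / (1.0 + beta) * total
    p_cl = total / (1.0 + beta)
    return p_na, p_cl


def analyze_record(
    record: ElectroRecord,
    reference_NaCl_mM: float = 140.0,
    kappa: float | None = None,
) -> PermeabilityResult:
    """Full pipeline for one record: TER -> beta -> (P_Na, P_Cl)."""
    ter = compute_ter(record)
    beta = ghk_ratio(record, kappa=kappa)
    p_na, p_cl = kimizuka_koketsu(
        ter, beta, reference_NaCl_mM=reference_NaCl_mM, temperature_K=record.temperature_K
    )
    return PermeabilityResult(TER_ohm_cm2=ter, beta=beta, P_Na_cm_s=p_na, P_Cl_cm_s=p_cl)


# --------------------------------------------------------------------------
# tracer flux


def fit_standard_curve(
    amounts: np.ndarray, fluorescence: np.ndarray
) -> CalibrationCurve:
    """Ordinary least-squares line: fluorescence = slope * amount + intercept."""
    x = np.asarray(amounts, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.size < 2 or x.shape != y.shape:
        raise ValueError("need >= 2 paired standards")
    if np.ptp(x) == 0:
        raise ValueError("degenerate standards: all amounts identical")
    res = _scipy_stats.linregress(x, y)
    if res.slope <= 0:
        raise ValueError(f"non-positive calibration slope ({res.slope:.4g})")
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def apply_calibration(curve: CalibrationCurve, fluorescence) -> np.ndarray:
    """Convert fluorescence readings to amounts via the inverted calibration."""
    return np.asarray(curve.apply(fluorescence), dtype=float)


def dextran_papp(series: FluxSeries) -> float:
    """Apparent permeability (dQ/dt)/(A*C0) in cm/s from a flux time series.

    dQ/dt is the least-squares slope of Q vs t, converted to mol/s.  With a
    single time point the line is forced through the origin.  A negative
    fitted slope is returned signed, with a warning.
    """
    t_s = series.times_h * 3600.0
    q_mol = series.Q_nmol * 1e-9
    if t_s.size == 1:
        slope = q_mol[0] / t_s[0]
    else:
        slope = float(np.polyfit(t_s, q_mol, 1)[0])
    if slope < 0:
        logger.warning("negative fitted flux slope (%.4g mol/s); returning signed P_app", slope)
    c0_mol_cm3 = series.C0_mM * MM_TO_MOL_PER_CM3
    return slope / (series.area_cm2 * c0_mol_cm3)
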