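"""Sedimentation equivalent of the EN 481 respirable convention.

Fine particles that would penetrate deep into the lungs also remain
longest in suspension. Consider an initially homogeneous column of liquid
of height H, left to settle for a time t, after which the top h of the
column is extracted. A particle of aerodynamic diameter D settles at its
Stokes velocity v(D) ∝ D², so the fraction of size-D particles remaining
in the extracted layer is the survival function

    S(D) = max(0, 1 - (D / D_c)²)

where D_c is the cut diameter — the aerodynamic diameter that settles
exactly through h in time t. The sedimentation is made equivalent to the
respirable convention R(D) by equating the integrals of the two
probability curves:

    ∫₀^∞ R(D) dD  =  ∫₀^{D_c} S(D) dD  =  (2/3) · D_c
    ⇒  D_c = 1.5 · ∫ R dD   (≈ 6.42 µm for default convention parameters)

The settling time for D_c follows from Stokes' law with buoyancy, written
in aerodynamic diameter (physical diameter d = D_c·sqrt(ρ₀/ρ_p)):

    t = 18 η h ρ_p / (g (ρ_p − ρ_l) ρ₀ D_c²)

The gravimetric estimator corrects the extracted-layer mass for the
extracted share of the column: SWeRF = (m·H) / (M·h), with M the
dispersed mass and m the residue recovered from the supernatant. For a
mixture, SWeRF_CS = SWeRF × f_CS with f_CS the crystalline-silica
fraction of the residue (from FT-IR or XRD).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .conventions import ConventionParams, DEFAULT_PARAMS, respirable_integral
from .engine import SwerfResult
from .exceptions import DomainError, FormatError, InvalidStateError
from .psd import DiameterBasis, SizeDistribution

__all__ = [
    "LiquidProperties",
    "WATER_20C",
    "SedimentationPlan",
    "SedimentationMeasurement",
    "cut_diameter",
    "settling_time",
    "survival_probability",
    "swerf_from_measurement",
    "swerf_cs_from_measurement",
    "virtual_sedimentation",
    "read_measurements",
    "check_solids_loading",
]

logger = logging.getLogger(__name__)

GRAVITY = 9.81  # m s^-2
UNIT_DENSITY = 1000.0  # kg m^-3

#: Default protocol: ~5 g of powder dispersed and made up to 250 ml.
DEFAULT_SAMPLE_MASS_G = 5.0
DEFAULT_CYLINDER_VOLUME_ML = 250.0
MAX_SOLIDS_VOLUME_FRACTION = 0.01

# Stokes' law holds for creeping flow; warn above this particle Reynolds number.
_REYNOLDS_WARN = 0.3


@dataclass(frozen=True)
class LiquidProperties:
    """Sedimentation liquid: dynamic viscosity (kg m⁻¹ s⁻¹) and density (kg m⁻³)."""

    dynamic_viscosity: float
    density: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.dynamic_viscosity > 0):
            raise DomainError("dynamic_viscosity must be strictly positive")
        if not (self.density > 0):
            raise DomainError("liquid density must be strictly positive")


#: Water at 20 °C; temperature itself is not modelled.
WATER_20C = LiquidProperties(dynamic_viscosity=1.002e-3, density=998.0, name="water")


def cut_diameter(params: ConventionParams = DEFAULT_PARAMS) -> float:
    """Aerodynamic cut diameter D_c (µm) equivalent to the respirable convention.

    Solves ∫₀^∞ R dD = ∫₀^{D_c} (1 − (D/D_c)²) dD = (2/3)·D_c in closed
    form: D_c = 1.5 × the convention integral.
    """
    return 1.5 * respirable_integral(params)


def settling_time(
    liquid: LiquidProperties,
    particle_density: float,
    extraction_height: float,
    cut_diameter_um: float,
    unit_density: float = UNIT_DENSITY,
    gravity: float = GRAVITY,
) -> float:
    """Settling time t (s) for the aerodynamic cut diameter, Stokes' law.

    ``extraction_height`` is the extracted supernatant depth h in metres.
    The particle of aerodynamic diameter D_c has physical diameter
    d = D_c·sqrt(ρ₀/ρ_p); buoyancy uses (ρ_p − ρ_l).
    """
    if extraction_height <= 0:
        raise DomainError("extraction height must be positive")
    if cut_diameter_um <= 0:
        raise DomainError("cut diameter must be positive")
    if particle_density <= liquid.density:
        raise DomainError(
            "particles do not settle: particle density "
            f"{particle_density} kg/m3 <= liquid density {liquid.density} kg/m3"
        )
    d_c_m = cut_diameter_um * 1e-6
    return (18.0 * liquid.dynamic_viscosity * extraction_height * particle_density) / (
        gravity * (particle_density - liquid.density) * unit_density * d_c_m**2
    )


@dataclass(frozen=True)
class SedimentationPlan:
    """A derived sedimentation protocol equivalent to the respirable convention.

    Use :meth:`derive` to build one; it computes the cut diameter from the
    convention parameters and the settling time from Stokes' law, and
    emits a warning if the particle Reynolds number at the cut diameter
    leaves the creeping-flow regime.
    """

    liquid: LiquidProperties
    particle_density: float
    extraction_height: float  # h, m
    column_height: float  # H, m
    unit_density: float = UNIT_DENSITY
    gravity: float = GRAVITY
    cut_diameter_um: Optional[float] = None
    settling_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.extraction_height <= self.column_height):
            raise DomainError("need 0 < h <= H")
        if self.particle_density <= self.liquid.density:
            raise DomainError("particles do not settle (rho_p <= rho_l)")
        if self.cut_diameter_um is not None and self.cut_diameter_um <= 0:
            raise DomainError("cut diameter must be positive")
        if self.settling_time_s is not None and self.settling_time_s <= 0:
            raise DomainError("settling time must be positive")

    @property
    def is_derived(self) -> bool:
        return self.cut_diameter_um is not None and self.settling_time_s is not None

    @classmethod
    def derive(
        cls,
        liquid: LiquidProperties,
        particle_density: float,
        extraction_height: float,
        column_height: Optional[float] = None,
        params: ConventionParams = DEFAULT_PARAMS,
    ) -> "SedimentationPlan":
        """Derive D_c and t for the given liquid, density and geometry (m)."""
        if column_height is None:
            column_height = extraction_height
        d_c = cut_diameter(params)
        t = settling_time(liquid, particle_density, extraction_height, d_c)
        plan = cls(
            liquid=liquid,
            particle_density=particle_density,
            extraction_height=extraction_height,
            column_height=column_height,
            cut_diameter_um=d_c,
            settling_time_s=t,
        )
        re = plan.reynolds_number()
        if re > _REYNOLDS_WARN:
            logger.warning(
                "particle Reynolds number %.3g at the cut diameter exceeds the "
                "creeping-flow regime; Stokes' law is approximate", re,
            )
        return plan

    def settling_velocity(self) -> float:
        """Stokes settling velocity (m/s) of the cut-diameter particle."""
        if not self.is_derived:
            raise InvalidStateError("plan is not derived (no cut diameter)")
        return self.extraction_height / self.settling_time_s

    def reynolds_number(self) -> float:
        """Particle Reynolds number of the cut-diameter particle in the liquid."""
        if not self.is_derived:
            raise InvalidStateError("plan is not derived (no cut diameter)")
        d_phys = self.cut_diameter_um * 1e-6 * math.sqrt(
            self.unit_density / self.particle_density
        )
        v = self.settling_velocity()
        return self.liquid.density * v * d_phys / self.liquid.dynamic_viscosity


def survival_probability(D, plan: SedimentationPlan):
    """Probability S(D) that a particle of aerodynamic diameter D (µm) remains
    in the extracted supernatant: max(0, 1 − (D/D_c)²).

    Accepts scalars or arrays; requires a derived plan.
    """
    if not plan.is_derived:
        raise InvalidStateError("plan is not derived (no cut diameter)")
    arr = np.asarray(D, dtype=float)
    if np.any(arr < 0):
        raise DomainError("aerodynamic diameter must be non-negative")
    out = np.clip(1.0 - (arr / plan.cut_diameter_um) ** 2, 0.0, 1.0)
    return float(out) if np.isscalar(D) or arr.ndim == 0 else out


@dataclass(frozen=True)
class SedimentationMeasurement:
    """A gravimetric sedimentation record.

    Masses in mg, heights in mm. ``cs_fraction_in_residue`` is the
    crystalline-silica fraction of the supernatant residue (FT-IR/XRD),
    in [0, 1].
    """

    total_mass_mg: float
    supernatant_residue_mg: float
    column_height_mm: float
    extraction_height_mm: float
    cs_fraction_in_residue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.total_mass_mg <= 0:
            raise DomainError("total dispersed mass must be positive")
        if not (0 <= self.supernatant_residue_mg <= self.total_mass_mg):
            raise DomainError("need 0 <= m <= M")
        if not (0 < self.extraction_height_mm <= self.column_height_mm):
            raise DomainError("need 0 < h <= H")
        if self.cs_fraction_in_residue is not None and not (
            0.0 <= self.cs_fraction_in_residue <= 1.0
        ):
            raise DomainError("cs_fraction_in_residue must lie in [0, 1]")


def swerf_from_measurement(meas: SedimentationMeasurement) -> SwerfResult:
    """Gravimetric SWeRF estimate: (m·H) / (M·h).

    The ratio corrects the extracted residue for the extracted share of
    the column. Raw ratios slightly above 1 (weighing noise) are clamped
    to 1 with a warning. If the measurement carries a crystalline-silica
    residue fraction, SWeRF_CS = SWeRF × f_CS is attached.
    """
    raw = (meas.supernatant_residue_mg * meas.column_height_mm) / (
        meas.total_mass_mg * meas.extraction_height_mm
    )
    value = raw
    if raw > 1.0:
        logger.warning(
            "gravimetric SWeRF ratio %.4f exceeds 1; clamping to 1 "
            "(weighing noise)", raw,
        )
        value = 1.0
    swerf_cs = None
    if meas.cs_fraction_in_residue is not None:
        swerf_cs = swerf_cs_from_measurement(value, meas.cs_fraction_in_residue)
    return SwerfResult(
        swerf=value,
        swerf_cs=swerf_cs,
        method="sedimentation",
        details={
            "M_mg": meas.total_mass_mg,
            "m_mg": meas.supernatant_residue_mg,
            "H_mm": meas.column_height_mm,
            "h_mm": meas.extraction_height_mm,
            "raw_ratio": raw,
        },
    )


def swerf_cs_from_measurement(swerf: float, f_cs: float) -> float:
    """Crystalline-silica share of a measured SWeRF: SWeRF × f_CS.

    ``f_cs`` is the crystalline-silica fraction of the supernatant
    residue, determined by FT-IR or XRD.
    """
    if not (0.0 <= swerf <= 1.0):
        raise DomainError("swerf must lie in [0, 1]")
    if not (0.0 <= f_cs <= 1.0):
        raise DomainError("f_cs must lie in [0, 1]")
    return swerf * f_cs


def virtual_sedimentation(
    psd: SizeDistribution, plan: SedimentationPlan
) -> SwerfResult:
    """Expected gravimetric SWeRF of an ideal sedimentation experiment.

    Σ P(bin)·S(D_rep): the expected (m·H)/(M·h) with no flocculation,
    hindered settling, or wall effects. Requires an aerodynamic-basis PSD.
    """
    if psd.diameter_basis is not DiameterBasis.AERODYNAMIC:
        raise InvalidStateError(
            "virtual sedimentation requires an aerodynamic-basis PSD; "
            "convert with to_aerodynamic first"
        )
    reps = psd.representative_diameters()
    value = float(np.sum(psd.bin_fractions * survival_probability(reps, plan)))
    return SwerfResult(
        swerf=min(max(value, 0.0), 1.0),
        method="sedimentation",
        details={
            "n_bins": psd.n_bins,
            "cut_diameter_um": plan.cut_diameter_um,
            "settling_time_s": plan.settling_time_s,
            "virtual": True,
        },
    )


def check_solids_loading(
    sample_mass_g: float = DEFAULT_SAMPLE_MASS_G,
    particle_density: float = 2660.0,
    volume_ml: float = DEFAULT_CYLINDER_VOLUME_ML,
) -> float:
    """Solids volume fraction of the suspension; warns above 1% v/v.

    The protocol keeps solids at or below 1% of the liquid volume so
    individual particles settle unhindered; the limit is advisory, so a
    violation warns rather than errors.
    """
    if sample_mass_g <= 0 or volume_ml <= 0 or particle_density <= 0:
        raise DomainError("mass, density and volume must be positive")
    solids_volume_ml = sample_mass_g / particle_density * 1e6 / 1000.0
    fraction = solids_volume_ml / volume_ml
    if fraction > MAX_SOLIDS_VOLUME_FRACTION:
        logger.warning(
            "solids loading %.2f%% v/v exceeds the 1%% guideline; "
            "sedimentation may be hindered", 100 * fraction,
        )
    return fraction


_MEAS_COLUMNS = ("M_mg", "m_mg", "H_mm", "h_mm")


def read_measurements(path) -> list[SedimentationMeasurement]:
    """Read sedimentation records from CSV (columns M_mg, m_mg, H_mm, h_mm
    and optional f_cs) for batch evaluation."""
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read measurement file {path!r}: {exc}") from exc
    missing = [c for c in _MEAS_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"measurement file missing columns {missing}")
    records = []
    for row in frame.itertuples(index=False):
        f_cs = getattr(row, "f_cs", None)
        if f_cs is not None and pd.isna(f_cs):
            f_cs = None
        records.append(
            SedimentationMeasurement(
                total_mass_mg=float(row.M_mg),
                supernatant_residue_mg=float(row.m_mg),
                column_height_mm=float(row.H_mm),
                extraction_height_mm=float(row.h_mm),
                cs_fraction_in_residue=None if f_cs is None else float(f_cs),
            )
        )
    return records
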