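"""Synthetic powders and virtual experiments.

Laser-diffraction PSDs of milled mineral powders are well described by
lognormal volume distributions, so the generator builds a binned lognormal
over log-spaced bins. Spiked blends mirror the classic recovery design —
a silica-free base spiked with known mass fractions of a quartz flour —
and the noisy sedimentation run emulates the gravimetric repeatability of
the pipette protocol, where the dominant error is evaporation/weighing of
the tens-of-mg supernatant residue. Column heights are treated as exact.

What the generator does not emulate: instrument optics (Mie/Fraunhofer),
particle shape and porosity distributions, flocculation, or between-
laboratory effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .engine import SwerfResult, blend_swerf, swerf_cs_calculated, swerf_from_psd
from .conventions import ConventionParams, DEFAULT_PARAMS
from .exceptions import DomainError
from .psd import DiameterBasis, Material, QuantityBasis, SizeDistribution
from .sedimentation import (
    SedimentationMeasurement,
    SedimentationPlan,
    virtual_sedimentation,
)

__all__ = [
    "LognormalSpec",
    "lognormal_psd",
    "Blend",
    "spiked_blend",
    "noisy_sedimentation_run",
]


@dataclass(frozen=True)
class LognormalSpec:
    """A lognormal volume PSD: median (µm), GSD, binning and seed.

    Bins are log-spaced over median·gsd^±range_factor; four geometric
    standard deviations capture all but ~6e-5 of the mass.
    """

    median: float
    gsd: float
    n_bins: int = 128
    range_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.median > 0):
            raise DomainError("median must be positive")
        if not (self.gsd > 1):
            raise DomainError("gsd must exceed 1")
        if self.n_bins < 10:
            raise DomainError("need at least 10 bins")
        if not (self.range_factor > 0):
            raise DomainError("range_factor must be positive")


def lognormal_psd(
    spec: LognormalSpec,
    diameter_basis: DiameterBasis = DiameterBasis.SPHERICAL_EQUIVALENT,
) -> SizeDistribution:
    """Binned lognormal PSD with d50 within 1% of ``spec.median``.

    Deterministic for a given spec: bin fractions are lognormal CDF
    differences over log-spaced edges, renormalized over the covered
    range.
    """
    sigma = np.log(spec.gsd)
    lo = spec.median * spec.gsd ** (-spec.range_factor)
    hi = spec.median * spec.gsd ** (spec.range_factor)
    edges = np.geomspace(lo, hi, spec.n_bins + 1)
    dist = stats.lognorm(s=sigma, scale=spec.median)
    cdf = dist.cdf(edges)
    fractions = np.diff(cdf)
    return SizeDistribution(
        bin_edges=edges,
        bin_fractions=fractions / fractions.sum(),
        diameter_basis=diameter_basis,
        quantity_basis=QuantityBasis.VOLUME,
    )


@dataclass(frozen=True)
class Blend:
    """A two-component blend kept at the component level.

    PSDs of different densities are never merged; the blend's SWeRF and
    SWeRF_CS are mass-weighted over per-component results. When the spike
    is pure crystalline silica, the blend's CS mass fraction equals the
    spike fraction.
    """

    base_psd: SizeDistribution
    base_material: Material
    spike_psd: SizeDistribution
    spike_material: Material
    spike_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.spike_fraction <= 1.0):
            raise DomainError("spike_fraction must lie in [0, 1]")

    @property
    def cs_mass_fraction(self) -> float:
        base_cs = self.base_material.cs_mass_fraction or 0.0
        spike_cs = (
            1.0
            if self.spike_material.cs_mass_fraction is None
            else self.spike_material.cs_mass_fraction
        )
        return (
            (1.0 - self.spike_fraction) * base_cs + self.spike_fraction * spike_cs
        )

    def calculated_swerf(
        self, params: ConventionParams = DEFAULT_PARAMS
    ) -> SwerfResult:
        """Mass-weighted blend of the per-component calculated SWeRFs."""
        base = swerf_from_psd(self.base_psd, self.base_material, params)
        base = _with_cs(base, self.base_material, default_cs=0.0)
        spike = swerf_from_psd(self.spike_psd, self.spike_material, params)
        spike = _with_cs(spike, self.spike_material, default_cs=1.0)
        return blend_swerf(
            [(1.0 - self.spike_fraction, base), (self.spike_fraction, spike)]
        )


def _with_cs(result: SwerfResult, material: Material, default_cs: float) -> SwerfResult:
    if material.cs_mass_fraction is None:
        material = Material(
            name=material.name,
            specific_gravity=material.specific_gravity,
            effective_density=material.effective_density,
            cs_mass_fraction=default_cs,
        )
    return swerf_cs_calculated(result, material)


def spiked_blend(
    base_psd: SizeDistribution,
    base_material: Material,
    spike_psd: SizeDistribution,
    spike_material: Material,
    spike_fraction: float,
) -> Blend:
    """Spike a base powder with ``spike_fraction`` (mass fraction of the
    blend) of a second powder, typically a quartz flour into a
    silica-free base."""
    return Blend(base_psd, base_material, spike_psd, spike_material, spike_fraction)


def noisy_sedimentation_run(
    psd: SizeDistribution,
    plan: SedimentationPlan,
    noise: float,
    seed: Optional[int] = None,
    total_mass_mg: float = 5000.0,
    cs_fraction_in_residue: Optional[float] = None,
) -> SedimentationMeasurement:
    """Simulate one gravimetric sedimentation run of an aerodynamic PSD.

    The expected residue mass is M·h/H × SWeRF_virtual; multiplicative
    Gaussian noise with relative SD ``noise`` perturbs the residue mass
    only (heights exact). ``noise = 0`` is deterministic and
    seed-independent.
    """
    if noise < 0:
        raise DomainError("noise must be non-negative")
    expected = virtual_sedimentation(psd, plan)
    h_mm = plan.extraction_height * 1000.0
    H_mm = plan.column_height * 1000.0
    m_expected = total_mass_mg * h_mm / H_mm * expected.swerf
    if noise > 0:
        rng = np.random.default_rng(seed)
        m = m_expected * (1.0 + noise * rng.standard_normal())
    else:
        m = m_expected
    m = float(np.clip(m, 0.0, total_mass_mg))
    return SedimentationMeasurement(
        total_mass_mg=total_mass_mg,
        supernatant_residue_mg=m,
        column_height_mm=H_mm,
        extraction_height_mm=h_mm,
        cs_fraction_in_residue=cs_fraction_in_residue,
    )
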