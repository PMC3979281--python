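"""Binned particle size distributions and the aerodynamic conversion.

Laser diffraction reports a volume-based distribution over the
spherical-equivalent diameter d. The sampling conventions operate on the
aerodynamic diameter D — the diameter of a unit-density sphere with the
same settling velocity — related by

    D = d * sqrt(SG)

with SG the specific gravity of the particle (effective density / 1000
kg m⁻³ for porous or hollow particles). Volume and mass fractions are
interchangeable within a single uniform-density material; materials of
different density must be combined at the component level, never by
merging their PSDs.

Bins are half-open intervals [lower, upper) of diameter in µm; cumulative
tables are "percent passing at stated diameter".
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DomainError, FormatError, InvalidStateError

__all__ = [
    "DiameterBasis",
    "QuantityBasis",
    "Material",
    "SizeDistribution",
    "read_psd",
    "write_psd",
    "to_aerodynamic",
    "d50",
    "QUARTZ_SG",
    "BARITE_SG",
]

logger = logging.getLogger(__name__)

#: Specific gravities of the two reference minerals used throughout.
QUARTZ_SG = 2.66
BARITE_SG = 4.48

#: Floor applied to a zero lower edge before taking geometric means, µm.
ZERO_EDGE_FLOOR_UM = 0.01

_NORMALIZATION_TOL = 1e-9


class DiameterBasis(str, enum.Enum):
    SPHERICAL_EQUIVALENT = "spherical_equivalent"
    AERODYNAMIC = "aerodynamic"


class QuantityBasis(str, enum.Enum):
    VOLUME = "volume"
    MASS = "mass"


@dataclass(frozen=True)
class Material:
    """Density descriptors and optional crystalline-silica content.

    ``specific_gravity`` is the particle density relative to unit density
    (2.66 for quartz, 4.48 for barite). ``effective_density`` (kg m⁻³),
    when given, overrides SG·1000 in every density-dependent formula —
    the correct treatment for porous/hollow particles. ``cs_mass_fraction``
    is the crystalline-silica mass fraction in [0, 1], typically from
    XRD or FT-IR.
    """

    name: str
    specific_gravity: float
    effective_density: Optional[float] = None
    cs_mass_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.specific_gravity > 0):
            raise DomainError("specific_gravity must be strictly positive")
        if self.effective_density is not None and not (self.effective_density > 0):
            raise DomainError("effective_density must be strictly positive")
        if self.cs_mass_fraction is not None and not (
            0.0 <= self.cs_mass_fraction <= 1.0
        ):
            raise DomainError("cs_mass_fraction must lie in [0, 1]")

    @property
    def density_kg_m3(self) -> float:
        """Particle density in kg m⁻³ (effective density if set)."""
        if self.effective_density is not None:
            return self.effective_density
        return self.specific_gravity * 1000.0

    @property
    def aerodynamic_scale(self) -> float:
        """sqrt(density / unit density): the d → D edge multiplier."""
        return math.sqrt(self.density_kg_m3 / 1000.0)


@dataclass(frozen=True)
class SizeDistribution:
    """A binned mass/volume particle size distribution.

    ``bin_edges`` are n+1 strictly increasing diameters in µm (first edge
    >= 0); ``bin_fractions`` are the n per-bin fractions, normalized to
    sum to 1. The ``diameter_basis`` flag records whether edges are
    spherical-equivalent or aerodynamic, preventing silent double
    conversion.
    """

    bin_edges: np.ndarray
    bin_fractions: np.ndarray
    diameter_basis: DiameterBasis = DiameterBasis.SPHERICAL_EQUIVALENT
    quantity_basis: QuantityBasis = QuantityBasis.VOLUME

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        fractions = np.asarray(self.bin_fractions, dtype=float)
        if edges.ndim != 1 or fractions.ndim != 1 or edges.size != fractions.size + 1:
            raise DomainError(
                "bin_edges must have length len(bin_fractions) + 1"
            )
        if fractions.size == 0:
            raise DomainError("distribution must contain at least one bin")
        if edges[0] < 0:
            raise DomainError("first bin edge must be >= 0")
        if np.any(np.diff(edges) <= 0):
            raise DomainError("bin_edges must be strictly increasing")
        if np.any(fractions < 0):
            raise DomainError("bin_fractions must be non-negative")
        total = float(fractions.sum())
        if total <= 0:
            raise DomainError("bin_fractions must have positive total")
        if abs(total - 1.0) > _NORMALIZATION_TOL:
            logger.warning(
                "bin fractions sum to %.6g; renormalizing to 1", total
            )
            fractions = fractions / total
        edges.setflags(write=False)
        fractions.setflags(write=False)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_fractions", fractions)
        if not isinstance(self.diameter_basis, DiameterBasis):
            object.__setattr__(
                self, "diameter_basis", DiameterBasis(self.diameter_basis)
            )
        if not isinstance(self.quantity_basis, QuantityBasis):
            object.__setattr__(
                self, "quantity_basis", QuantityBasis(self.quantity_basis)
            )

    @property
    def n_bins(self) -> int:
        return self.bin_fractions.size

    def representative_diameters(self) -> np.ndarray:
        """Geometric mean of each bin's edges, µm.

        Log-scale binning is standard for laser diffraction, so the
        geometric mean is the natural bin representative; a zero lower
        edge is floored at 0.01 µm first to avoid the degenerate zero.
        """
        lower = np.maximum(self.bin_edges[:-1], ZERO_EDGE_FLOOR_UM)
        upper = self.bin_edges[1:]
        return np.sqrt(lower * np.maximum(upper, lower))

    def cumulative(self) -> np.ndarray:
        """Cumulative fraction passing at each edge (length n+1, ends at 1)."""
        return np.concatenate([[0.0], np.cumsum(self.bin_fractions)])


def d50(psd: SizeDistribution) -> float:
    """Median diameter in µm by linear interpolation of the cumulative curve."""
    cum = psd.cumulative()
    idx = int(np.searchsorted(cum, 0.5))
    if idx == 0:
        return float(psd.bin_edges[0])
    lo_c, hi_c = cum[idx - 1], cum[idx]
    lo_d, hi_d = psd.bin_edges[idx - 1], psd.bin_edges[idx]
    if hi_c == lo_c:
        return float(lo_d)
    return float(lo_d + (0.5 - lo_c) / (hi_c - lo_c) * (hi_d - lo_d))


def to_aerodynamic(psd: SizeDistribution, material: Material) -> SizeDistribution:
    """Convert a spherical-equivalent PSD to aerodynamic diameter.

    Every bin edge is multiplied by sqrt(SG) (or sqrt(effective_density /
    1000) when an effective density is set); fractions are untouched, so
    per-bin mass is preserved exactly.

    Raises
    ------
    InvalidStateError
        If the distribution is already on the aerodynamic basis.
    """
    if psd.diameter_basis is DiameterBasis.AERODYNAMIC:
        raise InvalidStateError(
            "distribution is already aerodynamic; refusing double conversion"
        )
    scale = material.aerodynamic_scale
    return replace(
        psd,
        bin_edges=psd.bin_edges * scale,
        diameter_basis=DiameterBasis.AERODYNAMIC,
    )


_BIN_COLUMNS = ("lower_um", "upper_um", "fraction")
_CUM_COLUMNS = ("diameter_um", "cumulative_percent")


def read_psd(
    path,
    dialect: str = "bin_table",
    diameter_basis: DiameterBasis | str = DiameterBasis.SPHERICAL_EQUIVALENT,
    quantity_basis: QuantityBasis | str = QuantityBasis.VOLUME,
) -> SizeDistribution:
    """Read a PSD from CSV.

    Two dialects are supported. ``bin_table`` has columns
    ``lower_um, upper_um, fraction`` with contiguous bins;
    ``cumulative_passing`` has ``diameter_um`` (increasing) and
    ``cumulative_percent`` (non-decreasing, final value 100 ± 0.5) and is
    differenced into bins with an implicit first edge at 0 µm.
    """
    basis = DiameterBasis(diameter_basis)
    qbasis = QuantityBasis(quantity_basis)
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read PSD file {path!r}: {exc}") from exc

    if dialect == "bin_table":
        _require_columns(frame, _BIN_COLUMNS, path)
        lower = frame["lower_um"].to_numpy(dtype=float)
        upper = frame["upper_um"].to_numpy(dtype=float)
        fractions = frame["fraction"].to_numpy(dtype=float)
        if np.any(fractions < 0):
            raise FormatError("negative bin fractions in PSD file")
        if np.any(upper <= lower):
            raise FormatError("each upper_um must exceed its lower_um")
        if lower.size > 1 and not np.allclose(lower[1:], upper[:-1], rtol=0, atol=1e-9):
            raise FormatError("bin_table bins must be contiguous and increasing")
        if np.any(np.diff(lower) <= 0):
            raise FormatError("bin_table diameters must be increasing")
        edges = np.concatenate([lower, upper[-1:]])
    elif dialect == "cumulative_passing":
        _require_columns(frame, _CUM_COLUMNS, path)
        diam = frame["diameter_um"].to_numpy(dtype=float)
        cum = frame["cumulative_percent"].to_numpy(dtype=float)
        if np.any(np.diff(diam) <= 0):
            raise FormatError("cumulative diameter column must be strictly increasing")
        if np.any(np.diff(cum) < 0):
            raise FormatError("cumulative_percent must be non-decreasing")
        if np.any(cum < 0):
            raise FormatError("cumulative_percent must be non-negative")
        final = float(cum[-1])
        if abs(final - 100.0) > 0.5:
            raise FormatError(
                f"cumulative_percent must end at 100 ± 0.5, got {final:.3f}"
            )
        edges = np.concatenate([[0.0], diam])
        fractions = np.diff(np.concatenate([[0.0], cum])) / 100.0
    else:
        raise FormatError(f"unknown PSD dialect {dialect!r}")

    return SizeDistribution(
        bin_edges=edges,
        bin_fractions=fractions,
        diameter_basis=basis,
        quantity_basis=qbasis,
    )


def _require_columns(frame: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(
            f"PSD file {path!r} is missing required columns {missing}"
        )


def write_psd(psd: SizeDistribution, path) -> None:
    """Write a PSD as a ``bin_table`` CSV.

    Values carry 10 significant digits so that
    ``read_psd(write_psd(psd))`` round-trips within 1e-9.
    """
    frame = pd.DataFrame(
        {
            "lower_um": psd.bin_edges[:-1],
            "upper_um": psd.bin_edges[1:],
            "fraction": psd.bin_fractions,
        }
    )
    frame.to_csv(path, index=False, float_format="%.10g")
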