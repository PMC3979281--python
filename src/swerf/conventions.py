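"""EN 481 workplace-aerosol sampling conventions.

EN 481 defines the health-related size fractions of airborne dust as
probability curves over the aerodynamic diameter D. The respirable
convention R(D) — the probability that a particle of aerodynamic diameter
D, once inhaled, reaches the lungs' unciliated airways — is expressed here
relative to total airborne particles as the product of the inhalable
convention and a lognormal complement:

    E_I(D) = 0.5 * (1 + exp(-a * D))                 (inhalable, a = 0.06/µm)
    R(D)   = E_I(D) * (1 - Phi(ln(D / m) / ln(g)))   (m = 4.25 µm, g = 1.5)

where Phi is the standard normal CDF. With the default parameters R(1 µm)
= 97.1% and R(10 µm) = 1.3%, the conventional anchor values.

All probabilities are fractions in [0, 1]; conversion to percent happens
only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import ndtr

from .exceptions import DomainError, NumericalError

__all__ = [
    "ConventionParams",
    "DEFAULT_PARAMS",
    "inhalable_fraction",
    "respirable_fraction",
    "respirable_integral",
]


@dataclass(frozen=True)
class ConventionParams:
    """Parameters of the EN 481 inhalable/respirable conventions.

    Parameters
    ----------
    inhalable_decay
        Exponential decay coefficient of the inhalable convention, per µm.
    respirable_median
        Median of the lognormal respirable cut, µm.
    respirable_gsd
        Geometric standard deviation of the lognormal cut (> 1).
    """

    inhalable_decay: float = 0.06
    respirable_median: float = 4.25
    respirable_gsd: float = 1.5

    def __post_init__(self) -> None:
        if not (self.inhalable_decay > 0):
            raise DomainError("inhalable_decay must be strictly positive")
        if not (self.respirable_median > 0):
            raise DomainError("respirable_median must be strictly positive")
        if not (self.respirable_gsd > 1):
            raise DomainError("respirable_gsd must exceed 1")


DEFAULT_PARAMS = ConventionParams()


def _check_nonnegative(D) -> np.ndarray:
    arr = np.asarray(D, dtype=float)
    if np.any(arr < 0):
        raise DomainError("aerodynamic diameter must be non-negative")
    return arr


def inhalable_fraction(D, params: ConventionParams = DEFAULT_PARAMS):
    """Inhalable-convention sampling efficiency at aerodynamic diameter ``D`` (µm).

    Returns ``0.5 * (1 + exp(-a*D))``; 1 at D=0, 0.5 in the coarse limit.
    Accepts scalars or arrays.
    """
    arr = _check_nonnegative(D)
    out = 0.5 * (1.0 + np.exp(-params.inhalable_decay * arr))
    return float(out) if np.isscalar(D) or arr.ndim == 0 else out


def respirable_fraction(D, params: ConventionParams = DEFAULT_PARAMS):
    """Respirable-convention probability R(D) at aerodynamic diameter ``D`` (µm).

    The probability of reaching the alveoli, relative to total airborne
    particles. R(0) = 1 and R decreases monotonically, reaching ~1e-9 by
    100 µm for default parameters. Accepts scalars or arrays.
    """
    arr = _check_nonnegative(D)
    inh = 0.5 * (1.0 + np.exp(-params.inhalable_decay * arr))
    ln_gsd = math.log(params.respirable_gsd)
    with np.errstate(divide="ignore"):
        z = np.where(
            arr > 0,
            np.log(np.maximum(arr, 1e-300) / params.respirable_median) / ln_gsd,
            -np.inf,
        )
    out = inh * (1.0 - ndtr(z))
    return float(out) if np.isscalar(D) or arr.ndim == 0 else out


def respirable_integral(
    params: ConventionParams = DEFAULT_PARAMS, upper_limit: float = 100.0
) -> float:
    """Integral of the respirable convention, ∫₀^upper R(D) dD, in µm.

    Adaptive quadrature with relative tolerance 1e-10; the result is
    insensitive to ``upper_limit`` beyond ~30 µm for default parameters.
    ~4.2810 µm for the defaults.

    Raises
    ------
    DomainError
        If ``upper_limit`` truncates non-negligible tail mass
        (R(upper_limit) >= 1e-6).
    NumericalError
        If the quadrature does not reach its accuracy target.
    """
    if upper_limit <= 0:
        raise DomainError("upper_limit must be positive")
    if respirable_fraction(float(upper_limit), params) >= 1e-6:
        raise DomainError(
            "upper_limit %.3g µm truncates the convention tail "
            "(R there is >= 1e-6); increase it" % upper_limit
        )
    value, abserr = quad(
        lambda d: respirable_fraction(d, params),
        0.0,
        upper_limit,
        epsabs=0.0,
        epsrel=1e-10,
        limit=200,
    )
    if not math.isfinite(value) or (value > 0 and abserr / value > 1e-8):
        raise NumericalError(
            f"respirable_integral quadrature did not converge: "
            f"value={value!r}, abserr={abserr!r}"
        )
    return value
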