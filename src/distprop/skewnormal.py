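"""Skew-normal distribution core.

The skew-normal family extends the normal distribution with a shape
parameter ``alpha`` controlling skewness; ``alpha = 0`` recovers the
normal.  Two parameterisations are used throughout:

* the *direct* parameterisation (location ``xi``, scale ``w``, shape
  ``alpha``) in which the density is ``(2/w) * phi(z) * Phi(alpha*z)``
  with ``z = (x - xi)/w``;
* the *centred* parameterisation (mean ``mu``, SD ``sigma``, shape
  ``alpha``), which is the natural scale for data summaries.

The two are linked by ``mu_z = sqrt(2/pi) * alpha / sqrt(1 + alpha^2)``
(the mean of the standardised kernel), ``w = sigma / sqrt(1 - mu_z^2)``
and ``xi = mu - w * mu_z``.

Besides density and CDF, this module provides the derivative of the
tail probability with respect to the population *mean* — the building
block of the delta-method standard errors used by the distributional
dichotomisation estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

from .exceptions import DomainError, NumericalError

__all__ = [
    "MAX_ABS_SKEWNESS",
    "SkewNormalParams",
    "Threshold",
    "to_direct",
    "pdf",
    "cdf",
    "cdf_quadrature",
    "dcdf_dmean",
]

#: Supremum of |gamma1| (moment skewness) attainable by the skew-normal
#: family, reached as alpha -> +/- infinity.
MAX_ABS_SKEWNESS = 0.9952717464311565

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def _validate_scalar(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SkewNormalParams:
    """Skew-normal parameters in the centred (mean, SD, shape) form.

    Parameters
    ----------
    mu : float
        Population mean, in outcome units.
    sigma : float
        Population standard deviation, in outcome units; must be > 0.
    alpha : float, default 0.0
        Shape (skewness) parameter; 0 gives the normal distribution.
    """

    mu: float
    sigma: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", _validate_scalar("mu", self.mu))
        object.__setattr__(self, "sigma", _validate_scalar("sigma", self.sigma))
        object.__setattr__(self, "alpha", _validate_scalar("alpha", self.alpha))
        if self.sigma <= 0:
            raise DomainError(f"sigma must be > 0, got {self.sigma}")

    @property
    def delta(self) -> float:
        """alpha / sqrt(1 + alpha^2), in (-1, 1)."""
        return self.alpha / math.hypot(1.0, self.alpha)

    @property
    def mu_z(self) -> float:
        """Mean of the standardised kernel; sign(mu_z) = sign(alpha)."""
        return _SQRT_2_OVER_PI * self.delta

    @property
    def w(self) -> float:
        """Direct scale parameter; w >= sigma, equality iff alpha = 0."""
        return self.sigma / math.sqrt(1.0 - self.mu_z**2)

    @property
    def xi(self) -> float:
        """Direct location parameter xi = mu - w * mu_z."""
        return self.mu - self.w * self.mu_z

    @classmethod
    def from_direct(cls, xi: float, w: float, alpha: float) -> "SkewNormalParams":
        """Build from direct (location, scale, shape) parameters."""
        xi = _validate_scalar("xi", xi)
        w = _validate_scalar("w", w)
        alpha = _validate_scalar("alpha", alpha)
        if w <= 0:
            raise DomainError(f"w must be > 0, got {w}")
        delta = alpha / math.hypot(1.0, alpha)
        mu_z = _SQRT_2_OVER_PI * delta
        mu = xi + w * mu_z
        sigma = w * math.sqrt(1.0 - mu_z**2)
        return cls(mu=mu, sigma=sigma, alpha=alpha)

    def skewness(self) -> float:
        """Moment skewness gamma1 implied by alpha; |gamma1| < 0.9953."""
        mz = self.mu_z
        return (4.0 - math.pi) / 2.0 * mz**3 / (1.0 - mz**2) ** 1.5


@dataclass(frozen=True)
class Threshold:
    """A clinical cut-point with its tail direction.

    ``tail="below"`` reports P(X < x0) (e.g. low birthweight < 2500 g);
    ``tail="above"`` reports P(X > x0) (e.g. SBP > 160 mmHg).
    """

    x0: float
    tail: str = "below"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0", _validate_scalar("x0", self.x0))
        if self.tail not in ("below", "above"):
            raise DomainError(f"tail must be 'below' or 'above', got {self.tail!r}")

    def flipped(self) -> "Threshold":
        return Threshold(self.x0, "above" if self.tail == "below" else "below")


def to_direct(mu: float, sigma: float, alpha: float) -> tuple[float, float, float]:
    """Convert centred (mean, SD, shape) to direct (location, scale, shape).

    Returns ``(xi, w, alpha)`` such that the skew-normal with these direct
    parameters has mean ``mu`` and standard deviation ``sigma``.
    """
    p = SkewNormalParams(mu, sigma, alpha)
    return p.xi, p.w, p.alpha


def _z(x, params: SkewNormalParams):
    return (np.asarray(x, dtype=float) - params.xi) / params.w


def pdf(x, params: SkewNormalParams):
    """Skew-normal density (2/w) * phi(z) * Phi(alpha*z), z = (x - xi)/w."""
    z = _z(x, params)
    out = (2.0 / params.w) * stats.norm.pdf(z) * stats.norm.cdf(params.alpha * z)
    return out if out.ndim else float(out)


def cdf(x0, params: SkewNormalParams):
    """P(X <= x0) via the Owen's T closed form Phi(z) - 2*T(z, alpha)."""
    z = _z(x0, params)
    out = stats.norm.cdf(z) - 2.0 * special.owens_t(z, params.alpha)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def cdf_quadrature(x0: float, params: SkewNormalParams, tol: float = 1e-10) -> float:
    """P(X <= x0) by adaptive quadrature of the density (oracle/fallback)."""
    val, err = integrate.quad(
        lambda t: pdf(t, params), -np.inf, float(x0), epsabs=tol, limit=200
    )
    if not math.isfinite(val) or err > max(100 * tol, 1e-7):
        raise NumericalError(
            f"quadrature of the skew-normal CDF did not converge: value={val}, "
            f"error estimate={err}, x0={x0}, params={params}"
        )
    return min(max(val, 0.0), 1.0)


def dcdf_dmean(x0, params: SkewNormalParams):
    """Derivative of P(X < x0) with respect to the population mean.

    For a fixed cut-point the proportion below it falls as the mean
    rises, at a rate equal to the density at the cut-point:
    ``p'(mu) = -(2/w) * phi(z) * Phi(alpha*z)`` with ``z = (x0 - xi)/w``.
    This is the building block of every delta-method standard error in
    the distributional dichotomisation method.
    """
    out = -pdf(x0, params)
    return out
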