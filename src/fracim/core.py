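"""Scalar fractional-calculus machinery.

This module evaluates the quantities every mask in :mod:`fracim.masks` is
built from: the Grunwald-Letnikov (GL) series coefficients, the
Mittag-Leffler function, the Atangana-Baleanu normalization function
``M(alpha) = 1 - alpha + alpha / Gamma(alpha)``, and the four mask weights
``rho0..rho3`` obtained by truncating the GL discretization of the
Atangana-Baleanu fractional integral at four terms.

The fractional order ``alpha`` lives in ``(0, 1]``: ``alpha = 1`` recovers
the classical first difference, while ``alpha -> 0+`` degenerates towards an
identity-weighted operator. The GL step ``h`` is fixed at 1, the spacing of
the pixel lattice the masks are applied on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CoefficientSet",
    "GLSeries",
    "gl_series_coefficients",
    "mittag_leffler",
    "normalizer",
    "rho_coefficients",
    "validate_alpha",
]

#: hard cap on Mittag-Leffler series terms before declaring non-convergence
_ML_MAX_TERMS = 10_000
#: minimum number of terms always evaluated before the tolerance may stop the sum
_ML_MIN_TERMS = 10


def validate_alpha(alpha: float) -> float:
    """Check that a fractional order lies in the usable range ``(0, 1]``."""
    alpha = float(alpha)
    if not math.isfinite(alpha) or not 0.0 < alpha <= 1.0:
        raise ValueError(f"fractional order must lie in (0, 1], got {alpha!r}")
    return alpha


@dataclass(frozen=True)
class GLSeries:
    """Truncated Grunwald-Letnikov coefficient sequence.

    ``weights[k]`` is the signed generalized binomial coefficient
    ``(-1)^k * C(alpha, k)``; ``weights[0]`` is always 1.
    """

    alpha: float
    weights: tuple[float, ...]

    @property
    def n_terms(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class CoefficientSet:
    """The four mask weights at a given fractional order.

    ``rho0 = 1/M``, ``rho1 = alpha/(2M)``, ``rho2 = (alpha^3 - alpha^2)/(2M)``,
    ``rho3 = (alpha^2 - alpha^4)/(6M)`` with ``M`` the Atangana-Baleanu
    normalization function. For ``alpha`` in ``(0, 1)`` the signs are
    ``rho0, rho1, rho3 > 0`` and ``rho2 < 0``; at ``alpha = 1`` the set is
    ``(1, 0.5, 0, 0)``.
    """

    alpha: float
    normalizer: float
    rho0: float
    rho1: float
    rho2: float
    rho3: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.rho0, self.rho1, self.rho2, self.rho3)


def gl_series_coefficients(alpha: float, n_terms: int) -> GLSeries:
    """First ``n_terms`` Grunwald-Letnikov coefficients ``(-1)^k C(alpha, k)``.

    Uses the recurrence ``w[k] = w[k-1] * (k - 1 - alpha) / k`` with
    ``w[0] = 1``, which is numerically stable and avoids the gamma-function
    overflow of the direct ratio formula.

    Parameters
    ----------
    alpha : float
        Fractional order in ``(0, 1]``.
    n_terms : int
        Number of coefficients to return, at least 1.
    """
    alpha = validate_alpha(alpha)
    n_terms = int(n_terms)
    if n_terms < 1:
        raise ValueError(f"n_terms must be >= 1, got {n_terms}")
    weights = [1.0]
    for k in range(1, n_terms):
        weights.append(weights[-1] * (k - 1 - alpha) / k)
    return GLSeries(alpha=alpha, weights=tuple(weights))


def mittag_leffler(order: float, t: float, tol: float = 1e-14) -> float:
    """One-parameter Mittag-Leffler function ``E_order(t)``.

    Evaluates ``sum_k t^k / Gamma(order*k + 1)`` by direct summation,
    stopping once the absolute term falls below ``tol`` (after at least 10
    terms). ``E_1(t) = exp(t)``. Intended for the moderate ``|t|`` range the
    enhancement stack needs, not as a general-purpose special-function
    routine.

    Raises
    ------
    ArithmeticError
        If the series has not converged within 10,000 terms.
    """
    order = float(order)
    if order <= 0:
        raise ValueError(f"Mittag-Leffler index must be > 0, got {order}")
    if tol <= 0:
        raise ValueError(f"tolerance must be > 0, got {tol}")
    t = float(t)
    total = 0.0
    for k in range(_ML_MAX_TERMS):
        # t^k / Gamma(order*k + 1) in log space would lose the sign; the
        # direct power is fine for the |t| <= ~30 range used here.
        term = t**k / math.gamma(order * k + 1.0)
        total += term
        if k + 1 >= _ML_MIN_TERMS and abs(term) < tol:
            return total
    raise ArithmeticError(
        f"Mittag-Leffler series did not converge within {_ML_MAX_TERMS} terms "
        f"(order={order}, t={t})"
    )


def normalizer(alpha: float) -> float:
    """Atangana-Baleanu normalization ``M(alpha) = 1 - alpha + alpha/Gamma(alpha)``.

    Strictly positive on ``(0, 1]``; ``M(1) = 1`` and ``M(alpha) -> 1`` as
    ``alpha -> 0+`` (since ``alpha / Gamma(alpha) ~ alpha^2``).
    """
    alpha = validate_alpha(alpha)
    return 1.0 - alpha + alpha / math.gamma(alpha)


def rho_coefficients(alpha: float) -> CoefficientSet:
    """The four mask weights ``rho0..rho3`` at fractional order ``alpha``."""
    alpha = validate_alpha(alpha)
    m = normalizer(alpha)
    return CoefficientSet(
        alpha=alpha,
        normalizer=m,
        rho0=1.0 / m,
        rho1=alpha / (2.0 * m),
        rho2=(alpha**3 - alpha**2) / (2.0 * m),
        rho3=(alpha**2 - alpha**4) / (6.0 * m),
    )
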