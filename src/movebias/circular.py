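"""Circular-statistics primitives for biased correlated random walks.

Angles are radians on the half-open interval [-pi, pi), measured
counter-clockwise from a fixed reference direction.  Only angle
*differences* enter any likelihood in this package, so the choice of
reference (east here, north in much of the movement-ecology literature)
is immaterial; :func:`wrap_angle` enforces the interval after every
operation.

The central construction is the compromise (mean-direction) vector of a
biased correlated random walk: the unit vector of the previous bearing
plus bias-weighted unit vectors toward one or more targets.  Its
direction is the expected heading and its length measures the agreement
between persistence and taxis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "TWO_PI",
    "CompromiseVector",
    "wrap_angle",
    "mean_direction",
    "consensus_length",
    "log_bessel_i0",
    "bessel_ratio",
    "log_vm_density",
    "sample_von_mises",
    "kuiper_test",
    "circular_mean",
    "resultant_length",
    "InvalidAngleError",
    "InsufficientSampleError",
]

TWO_PI = 2.0 * math.pi

#: below this compromise-vector length the mean direction is reported as 0
#: with the ``degenerate`` flag set; the consensus density stays well
#: defined there (concentration -> 0 gives the uniform circle).
DEGENERATE_FLOOR = 1e-12


class InvalidAngleError(ValueError):
    """Raised when an angle argument is non-finite."""


class InsufficientSampleError(ValueError):
    """Raised when a test is asked for with too few angles."""


def wrap_angle(theta):
    """Wrap an angle (radians) into [-pi, pi).

    Accepts scalars or arrays.  ``wrap_angle(theta + 2*pi*k) ==
    wrap_angle(theta)`` for any integer k; the left endpoint -pi is
    included, +pi maps to -pi.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise InvalidAngleError("angle must be finite")
    in_range = (theta >= -math.pi) & (theta < math.pi)
    wrapped = np.where(in_range, theta, np.mod(theta + math.pi, TWO_PI) - math.pi)
    # guard the floating-point edge where mod returns exactly 2*pi
    wrapped = np.where(wrapped >= math.pi, -math.pi, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class CompromiseVector:
    """Mean-direction vector of a BCRW step.

    ``east``/``north`` are the components of the sum of the previous
    bearing's unit vector and the bias-weighted target unit vectors;
    ``length`` is the agreement between persistence and taxis and
    ``direction`` the expected heading.  ``degenerate`` marks a vector
    whose length fell below the numerical floor, in which case the
    direction is reported as 0 by convention.
    """

    east: float
    north: float
    length: float
    direction: float
    degenerate: bool = False


def mean_direction(y_prev: float, psi, beta) -> CompromiseVector:
    """Compromise between the previous bearing and one or more targets.

    Parameters
    ----------
    y_prev
        Previous step angle (radians).
    psi
        Target bearing(s): a scalar or a sequence of K bearings.
    beta
        Non-negative bias weight(s), one per target bearing.

    Returns
    -------
    CompromiseVector
        east = cos(y_prev) + sum_k beta_k cos(psi_k) and the analogous
        north component; direction via the two-argument arctangent,
        which is invariant to adding 2*pi to any input angle.
    """
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if psi.shape != beta.shape:
        raise ValueError("psi and beta must have equal length")
    if not (np.isfinite(beta).all() and np.isfinite(psi).all()):
        raise InvalidAngleError("psi and beta must be finite")
    east = math.cos(y_prev) + float(np.sum(beta * np.cos(psi)))
    north = math.sin(y_prev) + float(np.sum(beta * np.sin(psi)))
    length = math.hypot(east, north)
    if length < DEGENERATE_FLOOR:
        return CompromiseVector(east, north, length, 0.0, degenerate=True)
    return CompromiseVector(east, north, length, wrap_angle(math.atan2(north, east)))


def consensus_length(y_prev: float, psi: float, beta: float) -> float:
    """Agreement length of the single-bias compromise vector.

    Equals ``[(sin y_prev + beta sin psi)^2 + (cos y_prev + beta cos
    psi)^2]^{1/2}``; ranges over [|1-beta|, 1+beta] for beta >= 0, the
    maximum when the target lies straight ahead and the minimum when it
    lies directly behind.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return mean_direction(y_prev, psi, beta).length


def log_bessel_i0(x):
    """log I0(x) for x >= 0, overflow-free via exponential scaling."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("argument of I0 must be finite and non-negative")
    out = np.log(special.i0e(x)) + x
    if out.ndim == 0:
        return float(out)
    return out


def bessel_ratio(x):
    """A(x) = I1(x)/I0(x), the mean resultant length of vM(., x)."""
    x = np.asarray(x, dtype=float)
    out = special.i1e(x) / special.i0e(x)
    if out.ndim == 0:
        return float(out)
    return out


def log_vm_density(y, mu, kappa):
    """Log density of the von Mises distribution vM(mu, kappa) at y.

    kappa = 0 gives the uniform circle, log(1/(2*pi)).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("concentration must be non-negative")
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = kappa * np.cos(y - mu) - math.log(TWO_PI) - log_bessel_i0(kappa)
    if out.ndim == 0:
        return float(out)
    return out


def sample_von_mises(mu: float, kappa: float, n: int, rng: np.random.Generator):
    """Draw n angles from vM(mu, kappa), wrapped to [-pi, pi).

    Uses the Best-Fisher rejection sampler (as implemented by numpy);
    kappa = 0 short-circuits to uniform draws on the circle.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("concentration must be non-negative")
    if kappa == 0.0:
        return rng.uniform(-math.pi, math.pi, size=n)
    return wrap_angle(rng.vonmises(mu, kappa, size=n))


def _kuiper_pvalue(v: float, n: int) -> float:
    # asymptotic series with Stephens' finite-sample correction
    lam = (math.sqrt(n) + 0.155 + 0.24 / math.sqrt(n)) * v
    if lam < 0.4:
        return 1.0
    terms = 0.0
    for m in range(1, 101):
        a = 2.0 * (m * lam) ** 2
        term = (2.0 * a - 1.0) * math.exp(-a)
        terms += term
        if abs(term) < 1e-12 * max(terms, 1e-300):
            break
    return float(min(max(2.0 * terms, 0.0), 1.0))


def kuiper_test(angles) -> tuple[float, float]:
    """Kuiper's V_n test of circular uniformity.

    Returns ``(statistic, p_value)``.  The statistic is D+ + D- of the
    angles mapped to [0, 1); unlike Kolmogorov-Smirnov it is invariant
    to rotation of the circle's origin.  Requires at least 8 angles.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n < 8:
        raise InsufficientSampleError("Kuiper's test needs at least 8 angles")
    u = np.sort((wrap_angle(angles) + math.pi) / TWO_PI)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    v = float(d_plus + d_minus)
    return v, _kuiper_pvalue(v, n)


def circular_mean(angles) -> float:
    """Direction of the resultant vector of a sample of angles."""
    angles = np.asarray(angles, dtype=float)
    return wrap_angle(math.atan2(np.sin(angles).mean(), np.cos(angles).mean()))


def resultant_length(angles) -> float:
    """Mean resultant length (0 = diffuse, 1 = all angles equal)."""
    angles = np.asarray(angles, dtype=float)
    return float(math.hypot(np.cos(angles).mean(), np.sin(angles).mean()))
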