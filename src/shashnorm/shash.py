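"""The sinh-arcsinh (SHASH) distribution family.

The base SHASH law S(epsilon, delta) is obtained by pushing a standard
Gaussian Z through the inverse sinh-arcsinh transform,

    X = sinh((arcsinh(Z) + epsilon) / delta),

so that ``epsilon`` controls skew and ``delta`` controls tail weight
(delta < 1 heavy-tailed, delta > 1 light-tailed).  Three parameterisations
are provided:

* ``S``  — the two-parameter base law (zero location/scale structure);
* ``So`` — location/scale added *after* the transform,
  ``Omega = mu + sigma * X``, whose mean and variance entangle with the
  shape parameters;
* ``Sb`` — the moment-standardised reparameterisation: X is first shifted
  by its analytic mean ``m(1)`` and scaled by its analytic standard
  deviation ``eta`` before mu/sigma are applied, so that the distribution
  mean is exactly ``mu`` and the variance exactly ``sigma**2`` for every
  (epsilon, delta).

Analytic non-central moments use the modified Bessel function of the
second kind, evaluated in exponentially scaled form to avoid overflow at
small argument / large order.

All functions are vectorised over numpy arrays and are pure.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import comb, kve

__all__ = [
    "ShapeParams",
    "ShashParams",
    "DELTA_FLOOR",
    "sinh_arcsinh",
    "inv_sinh_arcsinh",
    "shash_logpdf",
    "bessel_term_P",
    "shash_moment",
    "shash_mean_var",
    "shasho_logpdf",
    "shashb_logpdf",
    "shashb_sample",
    "lambda_transform",
    "lambda_inverse",
    "softplus",
    "softplus_inv",
    "delta_link",
    "delta_link_inv",
]

#: Lower bound enforced on delta by the sampling link.  Values below it are
#: numerically unstable (the standardising variance explodes through the
#: Bessel term), so the link keeps the sampler away from that region.  The
#: raw density functions accept any delta > 0.
DELTA_FLOOR = 0.3

#: Factor by which the softplus inside the delta link is scaled to behave
#: nearly linearly between 0 and 1.
DELTA_LINK_SCALE = 10.0

_LOG_2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass(frozen=True)
class ShapeParams:
    """Skew/tail-weight pair (epsilon, delta) of a SHASH law; delta > 0."""

    epsilon: float
    delta: float

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=float)
        dlt = np.asarray(self.delta, dtype=float)
        if not np.all(np.isfinite(eps)) or not np.all(np.isfinite(dlt)):
            raise ValueError("epsilon and delta must be finite")
        if np.any(dlt <= 0.0):
            raise ValueError("delta must be strictly positive")


@dataclasses.dataclass(frozen=True)
class ShashParams:
    """Full four-parameter description (mu, sigma, epsilon, delta); sigma > 0."""

    mu: float
    sigma: float
    epsilon: float
    delta: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma, dtype=float) <= 0.0):
            raise ValueError("sigma must be strictly positive")
        ShapeParams(self.epsilon, self.delta)

    @property
    def shape(self) -> ShapeParams:
        return ShapeParams(self.epsilon, self.delta)


def _check_delta(delta) -> np.ndarray:
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0.0):
        raise ValueError("delta must be strictly positive")
    return delta


def _check_sigma(sigma) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0.0):
        raise ValueError("sigma must be strictly positive")
    return sigma


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def sinh_arcsinh(x, epsilon, delta):
    """Forward transform xi(x) = sinh(delta * arcsinh(x) - epsilon).

    Maps a SHASH(epsilon, delta) variate back to a standard Gaussian one.
    Strictly increasing in x for any delta > 0.
    """
    delta = _check_delta(delta)
    x = np.asarray(x, dtype=float)
    return np.sinh(delta * np.arcsinh(x) - np.asarray(epsilon, dtype=float))


def inv_sinh_arcsinh(z, epsilon, delta):
    """Inverse transform xi^-1(z) = sinh((arcsinh(z) + epsilon) / delta)."""
    delta = _check_delta(delta)
    z = np.asarray(z, dtype=float)
    return np.sinh((np.arcsinh(z) + np.asarray(epsilon, dtype=float)) / delta)


def _log_cosh(s):
    # log cosh(s) = |s| + log1p(exp(-2|s|)) - log 2, overflow-safe
    a = np.abs(s)
    return a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def shash_logpdf(x, epsilon, delta):
    """Log-density of the base SHASH law S(epsilon, delta).

    Computed fully in log space,

        log delta + log cosh(S) - 0.5*log(1 + x^2) - 0.5*log(2*pi) - xi^2/2,

    with ``S = delta*arcsinh(x) - epsilon`` and ``xi = sinh(S)``, so the
    cosh factor never overflows for |x| up to 1e6.
    """
    delta = _check_delta(delta)
    x = np.asarray(x, dtype=float)
    s = delta * np.arcsinh(x) - np.asarray(epsilon, dtype=float)
    xi = np.sinh(s)
    return (
        np.log(delta)
        + _log_cosh(s)
        - 0.5 * np.log1p(x * x)
        - 0.5 * _LOG_2PI
        - 0.5 * xi * xi
    )


def shasho_logpdf(x, mu, sigma, epsilon, delta):
    """Log-density of SHASH_o: location/scale applied after the transform."""
    sigma = _check_sigma(sigma)
    x = np.asarray(x, dtype=float)
    return shash_logpdf((x - mu) / sigma, epsilon, delta) - np.log(sigma)


def shashb_logpdf(x, mu, sigma, epsilon, delta):
    """Log-density of the moment-standardised SHASH_b law.

    The argument is first mapped to the base-law scale,
    ``u = (x - mu)/sigma * eta + m1``, where ``m1`` and ``eta`` are the
    analytic mean and standard deviation of S(epsilon, delta); the Jacobian
    contributes ``log(eta) - log(sigma)``.  The resulting distribution has
    mean exactly ``mu`` and variance exactly ``sigma**2``.
    """
    sigma = _check_sigma(sigma)
    x = np.asarray(x, dtype=float)
    m1, eta2 = shash_mean_var(epsilon, delta)
    eta = np.sqrt(eta2)
    u = (x - mu) / sigma * eta + m1
    return shash_logpdf(u, epsilon, delta) + np.log(eta) - np.log(sigma)


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

def bessel_term_P(q):
    """The Bessel factor P(q) entering the analytic SHASH moments.

    P(q) = e^{1/4} / sqrt(8 pi) * (K_{(q+1)/2}(1/4) + K_{(q-1)/2}(1/4))

    with K the modified Bessel function of the second kind.  Evaluated via
    exponentially scaled Bessel functions (kve = kv * e^x), which absorbs
    the e^{1/4} prefactor exactly.  Symmetric in q and strictly positive.
    """
    q = np.abs(np.asarray(q, dtype=float))
    return (kve((q + 1.0) / 2.0, 0.25) + kve((q - 1.0) / 2.0, 0.25)) / np.sqrt(
        8.0 * np.pi
    )


def shash_moment(r, epsilon, delta):
    """Analytic r-th non-central moment E[X^r] of S(epsilon, delta).

    m(r) = 2^-r * sum_{i=0}^{r} C(r, i) (-1)^i exp((r-2i) eps/delta) P((r-2i)/delta)
    """
    if r < 1 or int(r) != r:
        raise ValueError("moment order r must be a positive integer")
    delta = _check_delta(delta)
    epsilon = np.asarray(epsilon, dtype=float)
    out = 0.0
    for i in range(int(r) + 1):
        k = r - 2 * i
        out = out + (
            comb(r, i, exact=True)
            * (-1.0) ** i
            * np.exp(k * epsilon / delta)
            * bessel_term_P(k / delta)
        )
    return out / 2.0**r


def shash_mean_var(epsilon, delta):
    """Analytic mean m(1) and central variance eta^2 of S(epsilon, delta)."""
    m1 = shash_moment(1, epsilon, delta)
    m2 = shash_moment(2, epsilon, delta)
    return m1, m2 - m1 * m1


def _mean_var_shape_grads(epsilon, delta, h=1e-5):
    """d(m1)/d(eps,delta) and d(eta)/d(eps,delta) by central differences.

    The delta-derivative of P would need d/d(order) of K, which has no
    library form; both shape derivatives of the two scalar moment maps are
    therefore taken numerically.  Returns (dm1_de, dm1_dd, deta_de, deta_dd).
    """
    he = h * np.maximum(1.0, np.abs(epsilon))
    hd = h * np.maximum(1.0, np.abs(delta))

    def mv(e, d):
        m1, eta2 = shash_mean_var(e, d)
        return m1, np.sqrt(eta2)

    m1_ep, eta_ep = mv(epsilon + he, delta)
    m1_em, eta_em = mv(epsilon - he, delta)
    m1_dp, eta_dp = mv(epsilon, delta + hd)
    m1_dm, eta_dm = mv(epsilon, delta - hd)
    return (
        (m1_ep - m1_em) / (2.0 * he),
        (m1_dp - m1_dm) / (2.0 * hd),
        (eta_ep - eta_em) / (2.0 * he),
        (eta_dp - eta_dm) / (2.0 * hd),
    )


# ---------------------------------------------------------------------------
# The standardising transform lambda and sampling
# ---------------------------------------------------------------------------

def lambda_transform(z, mu, sigma, epsilon, delta):
    """Gaussian-space value z -> SHASH_b-space value (the centile map).

    lambda(z) = (xi^-1(z) - m1) / eta * sigma + mu
    """
    m1, eta2 = shash_mean_var(epsilon, delta)
    return (inv_sinh_arcsinh(z, epsilon, delta) - m1) / np.sqrt(eta2) * sigma + mu


def lambda_inverse(y, mu, sigma, epsilon, delta):
    """SHASH_b-space value y -> Gaussian-space value (the z-score map)."""
    sigma = _check_sigma(sigma)
    m1, eta2 = shash_mean_var(epsilon, delta)
    u = (np.asarray(y, dtype=float) - mu) / sigma * np.sqrt(eta2) + m1
    return sinh_arcsinh(u, epsilon, delta)


def shashb_sample(n, mu, sigma, epsilon, delta, seed=None):
    """Draw ``n`` reproducible samples from SHASH_b(mu, sigma, epsilon, delta).

    ``seed`` may be an int or a numpy Generator.  Parameters may be scalars
    or length-n vectors (heterogeneous draws).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(int(n))
    return lambda_transform(z, mu, sigma, epsilon, delta)


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------

def softplus(x):
    """Overflow-safe softplus(x) = log(1 + e^x), positive and increasing."""
    return np.logaddexp(0.0, np.asarray(x, dtype=float))


def softplus_inv(y):
    """Inverse softplus; y must be strictly positive."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0):
        raise ValueError("softplus_inv requires y > 0")
    # log(e^y - 1) = y + log(1 - e^-y)
    return y + np.log(-np.expm1(-y))


def delta_link(x):
    """Map an unconstrained value to the admissible tail-weight range.

    softplus(10x)/10 + 0.3: the scaled softplus is nearly linear on (0, 1),
    and the additive floor keeps delta >= 0.3, outside the numerically
    unstable region of the standardising moments.
    """
    return softplus(DELTA_LINK_SCALE * np.asarray(x, dtype=float)) / DELTA_LINK_SCALE + DELTA_FLOOR


def delta_link_inv(d):
    """Inverse of ``delta_link``; d must exceed the 0.3 floor."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= DELTA_FLOOR):
        raise ValueError(f"delta must exceed the link floor {DELTA_FLOOR}")
    return softplus_inv(DELTA_LINK_SCALE * (d - DELTA_FLOOR)) / DELTA_LINK_SCALE
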