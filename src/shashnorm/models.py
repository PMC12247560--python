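"""Hierarchical Bayesian regression models over SHASH likelihoods.

Four likelihood variants are supported, named after the family and the way
the shape parameters are modelled:

* ``N``   — Gaussian likelihood; mean with a site random intercept,
  heteroskedastic scale through a softplus-linked linear model.
* ``So1`` — SHASH_o likelihood; constant skew/tail parameters.
* ``Sb1`` — moment-standardised SHASH_b likelihood; constant skew/tail.
* ``Sb2`` — SHASH_b with skew and tail parameters regressed on the design
  matrix (covariate-dependent shape).

Every variant shares the same mean and scale structure: the mean is a
linear model on the design matrix plus a per-site random intercept
(non-centred: offset_s = mu_tau + sigma_tau * nu_s with nu_s ~ N(0, 1)),
and the scale is softplus of a linear predictor.  The tail parameter is
mapped through ``delta_link`` (scaled softplus + 0.3 floor) wherever a
SHASH family is used.

Models expose the log-joint density and its analytic gradient on a flat
unconstrained parameter vector, which is what the NUTS sampler and the MAP
optimiser consume.  The only non-analytic pieces are the shape derivatives
of the two standardising moment maps, taken by central differences (see
``shash._mean_var_shape_grads``).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from typing import Optional

import numpy as np
from scipy.interpolate import BSpline

from . import shash
from .shash import (
    _mean_var_shape_grads,
    delta_link,
    shash_mean_var,
    softplus,
)

logger = logging.getLogger("shashnorm")

_LOG_2PI = np.log(2.0 * np.pi)

N_SPLINE = 5  # cubic basis functions spanning the training age range
SPLINE_DEGREE = 3


class SubModelKind(str, enum.Enum):
    """How one likelihood parameter depends on covariates and site."""

    CONSTANT = "constant"
    FIXED_LINEAR = "fixed_linear"
    LINEAR_RANDOM_INTERCEPT = "linear_random_intercept"


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def bspline_knots(age_min: float, age_max: float) -> np.ndarray:
    """Clamped cubic knot vector over the training age range.

    One interior knot at the midpoint gives exactly ``N_SPLINE`` basis
    functions; boundary knots are repeated degree+1 times.
    """
    if not age_max > age_min:
        raise ValueError("age range must be non-degenerate")
    a, b = float(age_min), float(age_max)
    return np.array([a] * 4 + [0.5 * (a + b)] + [b] * 4)


def build_design_matrix(age, sex, knots: Optional[np.ndarray] = None):
    """Design matrix [5 cubic b-spline bases of age, age, sex].

    Parameters
    ----------
    age, sex
        Covariate vectors; sex must be coded 0/1.
    knots
        Full clamped knot vector from a previous (training) call.  When
        omitted it is derived from the range of ``age``.  Ages outside the
        knot span at prediction time are clamped, with a logged warning.

    Returns
    -------
    (X, knots) : the n x 7 matrix and the knot vector to persist.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if age.ndim != 1 or sex.shape != age.shape:
        raise ValueError("age and sex must be 1-d vectors of equal length")
    if not np.all(np.isfinite(age)):
        raise ValueError("age must be finite")
    if not np.all(np.isin(sex, (0.0, 1.0))):
        raise ValueError("sex must be coded 0/1")
    if knots is None:
        lo, hi = age.min(), age.max()
        if hi == lo:  # degenerate input: widen so the basis is well defined
            lo, hi = lo - 0.5, hi + 0.5
        knots = bspline_knots(lo, hi)
    else:
        knots = np.asarray(knots, dtype=float)

    lo, hi = knots[SPLINE_DEGREE], knots[-SPLINE_DEGREE - 1]
    if np.any(age < lo) or np.any(age > hi):
        logger.warning(
            "ages outside the training knot span [%.3g, %.3g] were clamped", lo, hi
        )
    clamped = np.clip(age, lo, hi)
    # extrapolate=False returns NaN at the right boundary in some scipy
    # versions; nudge the endpoint inward by one ulp instead.
    clamped = np.minimum(clamped, np.nextafter(hi, lo))
    B = BSpline.design_matrix(clamped, knots, SPLINE_DEGREE).toarray()
    X = np.column_stack([B, age, sex])
    return X, knots


# ---------------------------------------------------------------------------
# Priors and model specification
# ---------------------------------------------------------------------------

def _default_priors(family: str, shape_submodel: SubModelKind) -> dict:
    """Prior (location, standard deviation) per free parameter.

    Printed covariances (e.g. 0.2 * I on the shape-parameter weights) are
    variances; standard deviations are stored here.
    """
    priors = {
        "w_mu": (0.0, 1.0),
        "tau_mu": (0.0, 1.0),          # fixed-effect intercept (ablations)
        "mu_tau_mu": (0.0, 1.0),
        "sigma_tau_mu": (0.0, 1.0),    # half-normal scale on the offset sd
        "nu_tau_mu": (0.0, 1.0),
        "w_sigma": (0.0, 1.0),
        "tau_sigma": (1.0, 1.0),
    }
    if family in ("shash_o", "shash_b"):
        if shape_submodel is SubModelKind.CONSTANT:
            priors["epsilon"] = (0.0, 1.0)
            priors["delta_raw"] = (1.0, 1.0)
        else:
            priors["w_epsilon"] = (0.0, np.sqrt(0.2))
            priors["tau_epsilon"] = (0.0, np.sqrt(0.2))
            priors["w_delta"] = (0.0, np.sqrt(0.2))
            priors["tau_delta"] = (1.0, np.sqrt(0.3))
    return priors


@dataclasses.dataclass
class ModelSpec:
    """Declarative description of one likelihood variant.

    ``family`` is one of ``normal``, ``shash_o``, ``shash_b``; each
    likelihood parameter is assigned a :class:`SubModelKind`; ``priors``
    maps free-parameter names to (location, sd) pairs.  Round-trips through
    a plain JSON dict via :meth:`to_dict` / :meth:`from_dict`.
    """

    family: str = "shash_b"
    mu: SubModelKind = SubModelKind.LINEAR_RANDOM_INTERCEPT
    sigma: SubModelKind = SubModelKind.FIXED_LINEAR
    shape: SubModelKind = SubModelKind.CONSTANT  # epsilon and delta jointly
    priors: dict = dataclasses.field(default_factory=dict)
    knots: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.family not in ("normal", "shash_o", "shash_b"):
            raise ValueError(f"unknown likelihood family: {self.family!r}")
        full = _default_priors(self.family, self.shape)
        full.update(self.priors)
        for name, (loc, sd) in full.items():
            if sd <= 0:
                raise ValueError(f"prior scale for {name} must be positive")
        self.priors = full

    # -- canonical variants ------------------------------------------------
    @classmethod
    def N(cls, **kw) -> "ModelSpec":
        return cls(family="normal", **kw)

    @classmethod
    def So1(cls, **kw) -> "ModelSpec":
        return cls(family="shash_o", shape=SubModelKind.CONSTANT, **kw)

    @classmethod
    def Sb1(cls, **kw) -> "ModelSpec":
        return cls(family="shash_b", shape=SubModelKind.CONSTANT, **kw)

    @classmethod
    def Sb2(cls, **kw) -> "ModelSpec":
        return cls(family="shash_b", shape=SubModelKind.FIXED_LINEAR, **kw)

    @classmethod
    def by_name(cls, name: str) -> "ModelSpec":
        try:
            return {"N": cls.N, "So1": cls.So1, "Sb1": cls.Sb1, "Sb2": cls.Sb2}[name]()
        except KeyError:
            raise ValueError(f"unknown model variant {name!r}") from None

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mu": self.mu.value,
            "sigma": self.sigma.value,
            "shape": self.shape.value,
            "priors": {k: list(v) for k, v in self.priors.items()},
            "knots": None if self.knots is None else list(map(float, self.knots)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            family=d["family"],
            mu=SubModelKind(d["mu"]),
            sigma=SubModelKind(d["sigma"]),
            shape=SubModelKind(d["shape"]),
            priors={k: tuple(v) for k, v in d["priors"].items()},
            knots=None if d.get("knots") is None else np.asarray(d["knots"], float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# The generative model: log-joint and gradient
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class HBRModel:
    """One likelihood variant bound to data, exposing log-joint + gradient.

    Parameters are a flat unconstrained vector; the layout (name -> slice)
    is fixed at construction.  The per-site mean offset uses the
    non-centred parameterisation, the offset sd lives on the log scale
    (half-normal prior plus the exp Jacobian), and sigma/delta are mapped
    through their links inside the likelihood.
    """

    def __init__(self, spec: ModelSpec, X: np.ndarray, batch: np.ndarray,
                 y: np.ndarray, n_sites: Optional[int] = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        batch = np.asarray(batch, dtype=int)
        if X.ndim != 2 or y.shape != (X.shape[0],) or batch.shape != y.shape:
            raise ValueError("inconsistent shapes for X, batch, y")
        if batch.min() < 0:
            raise ValueError("batch indices must be dense non-negative codes")
        self.spec = spec
        self.X, self.y, self.batch = X, y, batch
        self.n, self.D = X.shape
        self.S = int(n_sites if n_sites is not None else batch.max() + 1)
        if batch.max() >= self.S:
            raise ValueError("batch label outside the declared number of sites")

        layout = []
        if spec.mu in (SubModelKind.FIXED_LINEAR, SubModelKind.LINEAR_RANDOM_INTERCEPT):
            layout.append(("w_mu", self.D))
        if spec.mu is SubModelKind.LINEAR_RANDOM_INTERCEPT:
            layout += [("mu_tau_mu", 1), ("log_sigma_tau_mu", 1), ("nu_tau_mu", self.S)]
        else:
            layout.append(("tau_mu", 1))
        if spec.sigma is SubModelKind.FIXED_LINEAR:
            layout.append(("w_sigma", self.D))
        layout.append(("tau_sigma", 1))
        if spec.family != "normal":
            if spec.shape is SubModelKind.CONSTANT:
                layout += [("epsilon", 1), ("delta_raw", 1)]
            else:
                layout += [("w_epsilon", self.D), ("tau_epsilon", 1),
                           ("w_delta", self.D), ("tau_delta", 1)]
        self.slices = {}
        i = 0
        for name, size in layout:
            self.slices[name] = slice(i, i + size)
            i += size
        self.dim = i

    # -- parameter vector helpers -----------------------------------------
    _VECTOR_PARAMS = frozenset(
        ["w_mu", "w_sigma", "w_epsilon", "w_delta", "nu_tau_mu"]
    )

    def unpack(self, theta: np.ndarray) -> dict:
        theta = np.asarray(theta, dtype=float)
        out = {}
        for name, sl in self.slices.items():
            v = theta[sl]
            out[name] = v if name in self._VECTOR_PARAMS else v[0]
        return out

    def pack(self, params: dict) -> np.ndarray:
        theta = np.zeros(self.dim)
        for name, sl in self.slices.items():
            theta[sl] = params[name]
        return theta

    def parameter_scales(self) -> np.ndarray:
        """Rough per-coordinate posterior scales (regression-weight
        coordinates shrink with the RMS of their design column), used to
        seed the sampler mass matrix and scale initialisation jitter."""
        col_rms = np.sqrt(np.mean(self.X * self.X, axis=0))
        col_rms = np.maximum(col_rms, 1e-3)
        scales = np.ones(self.dim)
        for name, sl in self.slices.items():
            if name.startswith("w_"):
                scales[sl] = 1.0 / col_rms
        return scales

    def initial_point(self, rng=None, jitter: float = 0.1) -> np.ndarray:
        """Prior means (offset sd at its half-normal mean) plus scaled jitter."""
        rng = np.random.default_rng(rng)
        theta = np.zeros(self.dim)
        pr = self.spec.priors
        for name, sl in self.slices.items():
            if name == "log_sigma_tau_mu":
                theta[sl] = np.log(pr["sigma_tau_mu"][1] * np.sqrt(2.0 / np.pi))
            elif name.startswith("w_"):
                theta[sl] = pr[name][0]
            elif name in pr:
                theta[sl] = pr[name][0]
        return theta + jitter * self.parameter_scales() * rng.standard_normal(
            self.dim
        )

    # -- deterministic transforms ------------------------------------------
    def _linear_predictors(self, p: dict, X=None, batch=None, strict=True):
        """Per-subject (mu, sigma, epsilon, delta) and cached intermediates."""
        X = self.X if X is None else X
        batch = self.batch if batch is None else batch
        spec = self.spec
        if spec.mu is SubModelKind.LINEAR_RANDOM_INTERCEPT:
            s_tau = np.exp(p["log_sigma_tau_mu"])
            offsets = p["mu_tau_mu"] + s_tau * p["nu_tau_mu"]
            known = batch < self.S
            if strict and not np.all(known):
                raise ValueError("batch label unseen at fit time")
            off = np.where(known, offsets[np.minimum(batch, self.S - 1)],
                           p["mu_tau_mu"])
            mu = X @ p["w_mu"] + off
        elif spec.mu is SubModelKind.FIXED_LINEAR:
            mu = X @ p["w_mu"] + p["tau_mu"]
        else:
            mu = np.full(X.shape[0], p["tau_mu"])
        if spec.sigma is SubModelKind.FIXED_LINEAR:
            u_sig = X @ p["w_sigma"] + p["tau_sigma"]
        else:
            u_sig = np.full(X.shape[0], p["tau_sigma"])
        sigma = softplus(u_sig)
        if spec.family == "normal":
            eps, dlt, v_dlt = None, None, None
        elif spec.shape is SubModelKind.CONSTANT:
            eps = p["epsilon"]
            v_dlt = p["delta_raw"]
            dlt = delta_link(v_dlt)
        else:
            eps = X @ p["w_epsilon"] + p["tau_epsilon"]
            v_dlt = X @ p["w_delta"] + p["tau_delta"]
            dlt = delta_link(v_dlt)
        return mu, sigma, u_sig, eps, dlt, v_dlt

    def predict_likelihood_params(self, theta, X=None, batch=None):
        """Per-subject (mu, sigma, epsilon, delta) at one parameter point.

        ``theta`` may be a flat vector or an unpacked dict.  Sites not seen
        at fit time (codes >= S) receive the group-mean offset.  For the
        Gaussian family epsilon/delta are reported as (0, 1), its SHASH
        embedding.
        """
        p = theta if isinstance(theta, dict) else self.unpack(theta)
        mu, sigma, _, eps, dlt, _ = self._linear_predictors(
            p, X=X, batch=batch, strict=False
        )
        n = mu.shape[0]
        if eps is None:
            eps, dlt = np.zeros(n), np.ones(n)
        return mu, sigma, np.broadcast_to(np.asarray(eps, float), (n,)), \
            np.broadcast_to(np.asarray(dlt, float), (n,))

    # -- log densities ------------------------------------------------------
    def _prior_logp_grad(self, theta, grad):
        pr = self.spec.priors
        logp = 0.0
        for name, sl in self.slices.items():
            x = theta[sl]
            if name == "log_sigma_tau_mu":
                scale = pr["sigma_tau_mu"][1]
                s = np.exp(x)
                logp += float(
                    np.sum(0.5 * np.log(2.0 / np.pi) - np.log(scale)
                           - 0.5 * (s / scale) ** 2 + x)
                )
                grad[sl] += 1.0 - (s / scale) ** 2
            else:
                key = "nu_tau_mu" if name == "nu_tau_mu" else name
                loc, sd = pr[key]
                z = (x - loc) / sd
                logp += float(np.sum(-0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI))
                grad[sl] += -z / sd
        return logp

    @staticmethod
    def _shash_base_terms(u, eps, dlt):
        """Base-law log-density at u and its partials (d/du, d/deps, d/ddelta)."""
        a = np.arcsinh(u)
        s = dlt * a - eps
        xi = np.sinh(s)
        ch = np.cosh(s)
        t = np.tanh(s)
        logf = (
            np.log(dlt) + shash._log_cosh(s)
            - 0.5 * np.log1p(u * u) - 0.5 * _LOG_2PI - 0.5 * xi * xi
        )
        core = t - xi * ch
        r2 = 1.0 + u * u
        dldu = core * dlt / np.sqrt(r2) - u / r2
        dlde = -core
        dldd = 1.0 / dlt + core * a
        return logf, dldu, dlde, dldd

    def logp_and_grad(self, theta):
        """Log-joint density and its gradient on the unconstrained scale."""
        theta = np.asarray(theta, dtype=float)
        grad = np.zeros(self.dim)
        logp = self._prior_logp_grad(theta, grad)
        p = self.unpack(theta)
        mu, sigma, u_sig, eps, dlt, v_dlt = self._linear_predictors(p)
        y, X, batch, spec = self.y, self.X, self.batch, self.spec

        if spec.family == "normal":
            r = (y - mu) / sigma
            logp += float(np.sum(-0.5 * r * r - np.log(sigma) - 0.5 * _LOG_2PI))
            dldmu = r / sigma
            dldsig = (r * r - 1.0) / sigma
            dldeps = dlddlt = None
        elif spec.family == "shash_o":
            u = (y - mu) / sigma
            logf, dldu, dlde, dldd = self._shash_base_terms(u, eps, dlt)
            logp += float(np.sum(logf - np.log(sigma)))
            dldmu = -dldu / sigma
            dldsig = -dldu * u / sigma - 1.0 / sigma
            dldeps, dlddlt = dlde, dldd
        else:  # shash_b
            m1, eta2 = shash_mean_var(eps, dlt)
            eta = np.sqrt(eta2)
            w = (y - mu) / sigma
            u = w * eta + m1
            logf, dldu, dlde, dldd = self._shash_base_terms(u, eps, dlt)
            logp += float(np.sum(logf + np.log(eta) - np.log(sigma)))
            dm1_de, dm1_dd, deta_de, deta_dd = _mean_var_shape_grads(eps, dlt)
            dldmu = -dldu * eta / sigma
            dldsig = -dldu * w * eta / sigma - 1.0 / sigma
            dldeps = dlde + dldu * (w * deta_de + dm1_de) + deta_de / eta
            dlddlt = dldd + dldu * (w * deta_dd + dm1_dd) + deta_dd / eta

        # chain rule into the unconstrained parameters
        sl = self.slices
        if spec.mu in (SubModelKind.FIXED_LINEAR, SubModelKind.LINEAR_RANDOM_INTERCEPT):
            grad[sl["w_mu"]] += X.T @ dldmu
        if spec.mu is SubModelKind.LINEAR_RANDOM_INTERCEPT:
            s_tau = np.exp(p["log_sigma_tau_mu"])
            per_site = np.bincount(batch, weights=dldmu, minlength=self.S)
            grad[sl["mu_tau_mu"]] += dldmu.sum()
            grad[sl["log_sigma_tau_mu"]] += s_tau * float(per_site @ p["nu_tau_mu"])
            grad[sl["nu_tau_mu"]] += s_tau * per_site
        elif spec.mu is SubModelKind.FIXED_LINEAR:
            grad[sl["tau_mu"]] += dldmu.sum()
        else:
            grad[sl["tau_mu"]] += dldmu.sum()

        dsig = dldsig * _sigmoid(u_sig)
        if spec.sigma is SubModelKind.FIXED_LINEAR:
            grad[sl["w_sigma"]] += X.T @ dsig
        grad[sl["tau_sigma"]] += dsig.sum()

        if spec.family != "normal":
            if spec.shape is SubModelKind.CONSTANT:
                grad[sl["epsilon"]] += np.sum(dldeps)
                grad[sl["delta_raw"]] += np.sum(dlddlt) * _sigmoid(
                    shash.DELTA_LINK_SCALE * v_dlt
                )
            else:
                ddlt = dlddlt * _sigmoid(shash.DELTA_LINK_SCALE * v_dlt)
                grad[sl["w_epsilon"]] += X.T @ dldeps
                grad[sl["tau_epsilon"]] += np.sum(dldeps)
                grad[sl["w_delta"]] += X.T @ ddlt
                grad[sl["tau_delta"]] += np.sum(ddlt)
        return logp, grad

    def logp(self, theta) -> float:
        return self.logp_and_grad(theta)[0]


def make_model(spec: ModelSpec, covariates: np.ndarray, batch: np.ndarray,
               response: np.ndarray, n_sites: Optional[int] = None) -> HBRModel:
    """Bind a :class:`ModelSpec` to data, returning the generative model."""
    return HBRModel(spec, covariates, batch, response, n_sites=n_sites)
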