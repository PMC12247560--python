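"""Posterior inference: NUTS sampling, convergence diagnostics, MAP.

The sampler is a No-U-Turn sampler (recursive doubling with a slice
variable), with dual-averaging step-size adaptation and a diagonal mass
matrix estimated during warmup.  It consumes any model object exposing

* ``dim`` — the number of unconstrained parameters,
* ``logp_and_grad(theta) -> (float, ndarray)``,
* ``initial_point(rng) -> ndarray``.

Convergence is summarised by the potential-scale-reduction statistic
(R-hat): the default is the rank-normalised split-chain variant computed
by arviz; the classic Gelman-Rubin between/within-chain ratio is available
behind ``method="classic"``.  Values near 1 indicate convergence; 1.05 and
1.1 are the conventional warning thresholds.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import arviz as az
import numpy as np
from scipy.optimize import minimize

from .shash import delta_link

logger = logging.getLogger("shashnorm")

_DELTA_MAX = 1000.0  # energy-error threshold flagging a divergent transition
_MAX_TREE_DEPTH = 10
_DIVERGENCE_TOLERANCE = 0.05  # fraction of post-warmup divergences tolerated


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws on the unconstrained scale.

    ``raw`` has shape (chains, draws, dim); ``slices`` maps parameter names
    into the last axis.  :meth:`get` also serves the derived constrained
    parameters ``delta`` (tail weight after the link) and ``sigma_tau_mu``
    (site-offset sd).
    """

    raw: np.ndarray
    slices: dict
    seed: Optional[int]
    burn_in: int
    stats: dict = dataclasses.field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.raw.shape[0]

    @property
    def n_draws(self) -> int:
        return self.raw.shape[1]

    def parameter_names(self):
        names = list(self.slices)
        if "delta_raw" in self.slices:
            names.append("delta")
        if "log_sigma_tau_mu" in self.slices:
            names.append("sigma_tau_mu")
        return names

    def get(self, name: str) -> np.ndarray:
        """(chains, draws[, k]) array for one parameter, scalars squeezed."""
        if name == "delta" and "delta_raw" in self.slices:
            return delta_link(self.get("delta_raw"))
        if name == "sigma_tau_mu" and "log_sigma_tau_mu" in self.slices:
            return np.exp(self.get("log_sigma_tau_mu"))
        sl = self.slices[name]
        out = self.raw[:, :, sl]
        return out[:, :, 0] if sl.stop - sl.start == 1 else out

    def point(self, chain: int, draw: int) -> np.ndarray:
        return self.raw[chain, draw]

    def posterior_mean(self) -> np.ndarray:
        return self.raw.reshape(-1, self.raw.shape[-1]).mean(axis=0)

    def max_logp_point(self) -> np.ndarray:
        lp = np.asarray(self.stats["logp"])
        c, d = np.unravel_index(np.argmax(lp), lp.shape)
        return self.raw[c, d]

    def to_arviz(self) -> az.InferenceData:
        data = {}
        for name in self.parameter_names():
            data[name] = self.get(name)
        return az.from_dict(posterior=data)

    def save(self, path) -> None:
        """Persist as a self-describing .npz (names, dims, seed embedded)."""
        names = list(self.slices)
        meta = {
            "raw": self.raw,
            "names": np.array(names),
            "starts": np.array([self.slices[n].start for n in names]),
            "stops": np.array([self.slices[n].stop for n in names]),
            "seed": np.array(-1 if self.seed is None else self.seed),
            "burn_in": np.array(self.burn_in),
            "logp": np.asarray(self.stats.get("logp", np.zeros((0, 0)))),
        }
        np.savez(path, **meta)

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as f:
            slices = {
                str(n): slice(int(a), int(b))
                for n, a, b in zip(f["names"], f["starts"], f["stops"])
            }
            seed = int(f["seed"])
            return cls(
                raw=f["raw"],
                slices=slices,
                seed=None if seed < 0 else seed,
                burn_in=int(f["burn_in"]),
                stats={"logp": f["logp"]},
            )


@dataclasses.dataclass
class MapEstimate:
    """Posterior mode on the unconstrained scale."""

    theta: np.ndarray
    logp: float
    grad_norm: float
    converged: bool
    n_restarts: int


@dataclasses.dataclass
class ConvergenceReport:
    """Per-parameter R-hat with conventional threshold flags."""

    rhat: dict
    method: str

    @property
    def worst(self) -> float:
        return max(float(np.max(v)) for v in self.rhat.values())

    def flags(self) -> dict:
        return {
            name: ("ok" if v <= 1.05 else "warn" if v <= 1.1 else "fail")
            for name, v in ((k, float(np.max(x))) for k, x in self.rhat.items())
        }


# ---------------------------------------------------------------------------
# NUTS
# ---------------------------------------------------------------------------

class _Nuts:
    """NUTS with a diagonal or dense inverse mass matrix.

    The inverse mass approximates the posterior covariance; a dense
    estimate (feasible at the dimensions used here) removes the strong
    correlations between spline weights, intercept and site offsets that
    a diagonal matrix cannot, shrinking tree depths substantially.
    """

    def __init__(self, logp_and_grad, dim, rng, target_accept=0.85):
        self.f = logp_and_grad
        self.dim = dim
        self.rng = rng
        self.target = target_accept
        self.n_eval = 0
        self.set_mass(np.ones(dim))

    def set_mass(self, minv: np.ndarray) -> None:
        """Install a new inverse mass (1-D diagonal or 2-D dense)."""
        self.minv = minv
        if minv.ndim == 2:
            # momentum ~ N(0, M) with M = Minv^-1: r = L^-T z, L L^T = Minv
            self._chol = np.linalg.cholesky(minv)
        else:
            self._chol = None

    def _vel(self, r):
        return self.minv @ r if self._chol is not None else self.minv * r

    def _momentum(self):
        z = self.rng.standard_normal(self.dim)
        if self._chol is None:
            return z / np.sqrt(self.minv)
        from scipy.linalg import solve_triangular

        return solve_triangular(self._chol.T, z, lower=False)

    def _call(self, theta):
        self.n_eval += 1
        logp, grad = self.f(theta)
        if not np.isfinite(logp):
            logp = -np.inf
            grad = np.zeros_like(grad)
        return logp, grad

    def _leapfrog(self, theta, r, grad, step):
        r = r + 0.5 * step * grad
        theta = theta + step * self._vel(r)
        logp, grad = self._call(theta)
        r = r + 0.5 * step * grad
        return theta, r, logp, grad

    def _kinetic(self, r):
        return 0.5 * float(r @ self._vel(r))

    def find_reasonable_step(self, theta, logp, grad):
        step = 1.0
        r0 = self._momentum()
        joint0 = logp - self._kinetic(r0)
        _, r1, logp1, _ = self._leapfrog(theta, r0, grad, step)
        joint1 = logp1 - self._kinetic(r1)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        a = 1.0 if joint1 - joint0 > np.log(0.5) else -1.0
        while a * (joint1 - joint0) > -a * np.log(2.0):
            step *= 2.0**a
            if step > 1e7 or step < 1e-10:
                break
            _, r1, logp1, _ = self._leapfrog(theta, r0, grad, step)
            joint1 = logp1 - self._kinetic(r1)
            if not np.isfinite(joint1):
                joint1 = -np.inf
        return step

    def _build_tree(self, theta, r, grad, logu, v, j, step, joint0):
        if j == 0:
            theta1, r1, logp1, grad1 = self._leapfrog(theta, r, grad, v * step)
            joint = logp1 - self._kinetic(r1)
            n1 = int(logu <= joint)
            s1 = int(logu < joint + _DELTA_MAX)
            alpha = min(1.0, np.exp(min(0.0, joint - joint0)))
            return (theta1, r1, grad1, theta1, r1, grad1,
                    theta1, grad1, logp1, n1, s1, alpha, 1)
        (tm, rm, gm, tp, rp, gp, t1, g1, lp1, n1, s1, a1, na1) = self._build_tree(
            theta, r, grad, logu, v, j - 1, step, joint0
        )
        if s1 == 1:
            if v == -1:
                (tm, rm, gm, _, _, _, t2, g2, lp2, n2, s2, a2, na2) = self._build_tree(
                    tm, rm, gm, logu, v, j - 1, step, joint0
                )
            else:
                (_, _, _, tp, rp, gp, t2, g2, lp2, n2, s2, a2, na2) = self._build_tree(
                    tp, rp, gp, logu, v, j - 1, step, joint0
                )
            if n1 + n2 > 0 and self.rng.uniform() < n2 / (n1 + n2):
                t1, g1, lp1 = t2, g2, lp2
            a1 += a2
            na1 += na2
            s1 = s2 * self._no_uturn(tm, tp, rm, rp)
            n1 += n2
        return tm, rm, gm, tp, rp, gp, t1, g1, lp1, n1, s1, a1, na1

    def _no_uturn(self, tm, tp, rm, rp):
        d = tp - tm
        return int((d @ self._vel(rm) >= 0) and (d @ self._vel(rp) >= 0))

    def step(self, theta, logp, grad, step_size):
        r0 = self._momentum()
        joint0 = logp - self._kinetic(r0)
        logu = joint0 + np.log(self.rng.uniform())
        tm = tp = theta
        rm = rp = r0
        gm = gp = grad
        t_new, g_new, lp_new = theta, grad, logp
        j, n, s = 0, 1, 1
        alpha, n_alpha = 0.0, 1
        divergent = False
        while s == 1 and j < _MAX_TREE_DEPTH:
            v = 1 if self.rng.uniform() < 0.5 else -1
            if v == -1:
                (tm, rm, gm, _, _, _, t1, g1, lp1, n1, s1, alpha, n_alpha) = (
                    self._build_tree(tm, rm, gm, logu, v, j, step_size, joint0)
                )
            else:
                (_, _, _, tp, rp, gp, t1, g1, lp1, n1, s1, alpha, n_alpha) = (
                    self._build_tree(tp, rp, gp, logu, v, j, step_size, joint0)
                )
            if s1 == 1 and self.rng.uniform() < min(1.0, n1 / n):
                t_new, g_new, lp_new = t1, g1, lp1
            n += n1
            if s1 == 0 and n1 == 0:
                divergent = True
            s = s1 * self._no_uturn(tm, tp, rm, rp)
            j += 1
        return t_new, lp_new, g_new, alpha / max(n_alpha, 1), divergent, j


def _run_chain(model, iterations, burn_in, rng, target_accept, init=None):
    nuts = _Nuts(model.logp_and_grad, model.dim, rng, target_accept)
    if hasattr(model, "parameter_scales"):
        nuts.set_mass(model.parameter_scales() ** 2)
    theta = model.initial_point(rng) if init is None else np.array(init, float)
    logp, grad = nuts._call(theta)
    if not np.isfinite(logp):
        raise RuntimeError("log-joint not finite at the initial point")

    # dual averaging (Hoffman & Gelman), restarted after mass-matrix updates
    gamma, t0, kappa = 0.05, 10.0, 0.75

    def reset_da():
        step0 = nuts.find_reasonable_step(theta, logp, grad)
        return step0, np.log(10.0 * step0), 0.0, 0.0, 0

    step, mu_da, log_step_bar, h_bar, m_da = reset_da()
    window = []
    # mass-matrix re-estimation points within warmup (Stan-like windows)
    updates = {int(burn_in * 0.5): (int(burn_in * 0.2), int(burn_in * 0.5)),
               int(burn_in * 0.8): (int(burn_in * 0.5), int(burn_in * 0.8))}

    draws = np.empty((iterations - burn_in, model.dim))
    logps = np.empty(iterations - burn_in)
    divergences = 0
    depths = []
    for it in range(iterations):
        theta, logp, grad, accept, divergent, depth = nuts.step(
            theta, logp, grad, step
        )
        if it < burn_in:
            window.append(theta.copy())
            m_da += 1
            h_bar += (1.0 / (m_da + t0)) * ((target_accept - accept) - h_bar)
            log_step = mu_da - np.sqrt(m_da) / gamma * h_bar
            eta = m_da**-kappa
            log_step_bar = eta * log_step + (1.0 - eta) * log_step_bar
            step = float(np.exp(log_step))
            if it + 1 in updates:
                lo, hi = updates[it + 1]
                seg = np.asarray(window[lo:hi])
                n_seg = seg.shape[0]
                shrink = n_seg / (n_seg + 5.0)
                if n_seg > model.dim + 4:
                    cov = np.cov(seg.T)
                    minv = shrink * cov + (1.0 - shrink) * 1e-3 * np.eye(model.dim)
                else:  # too few draws for a stable dense estimate
                    var = seg.var(axis=0, ddof=1)
                    minv = shrink * var + (1.0 - shrink) * 1e-3
                nuts.set_mass(minv)
                step, mu_da, log_step_bar, h_bar, m_da = reset_da()
            if it == burn_in - 1:
                step = float(np.exp(log_step_bar))
        else:
            draws[it - burn_in] = theta
            logps[it - burn_in] = logp
            divergences += int(divergent)
            depths.append(depth)
    return draws, logps, {
        "divergences": divergences,
        "step_size": step,
        "mean_tree_depth": float(np.mean(depths)) if depths else 0.0,
        "n_grad_evals": nuts.n_eval,
    }


def sample_posterior(model, chains: int = 2, iterations: int = 1500,
                     burn_in: int = 500, seed: Optional[int] = None,
                     target_accept: float = 0.85) -> PosteriorSamples:
    """Sample the hierarchical posterior with NUTS.

    Defaults follow the study protocol: two chains of 1500 iterations with
    the first 500 discarded as burn-in (used for step-size and mass-matrix
    adaptation), leaving 1000 retained draws per chain.  Reproducible given
    ``seed``.  Runs in which more than 5% of post-burn-in transitions are
    divergent raise, rather than returning silently biased draws.
    """
    if chains < 1 or iterations <= burn_in:
        raise ValueError("need chains >= 1 and iterations > burn_in")
    seqs = np.random.SeedSequence(seed).spawn(chains)
    all_draws, all_logps, stats = [], [], []
    for c in range(chains):
        rng = np.random.default_rng(seqs[c])
        draws, logps, st = _run_chain(
            model, iterations, burn_in, rng, target_accept
        )
        all_draws.append(draws)
        all_logps.append(logps)
        stats.append(st)
        logger.info("chain %d: %s", c, st)
    kept = iterations - burn_in
    total_div = sum(s["divergences"] for s in stats)
    if total_div > _DIVERGENCE_TOLERANCE * chains * kept:
        raise RuntimeError(
            f"{total_div} divergent transitions out of {chains * kept}: "
            "the posterior geometry was not sampled reliably"
        )
    slices = dict(getattr(model, "slices", None)
                  or {"theta": slice(0, model.dim)})
    return PosteriorSamples(
        raw=np.asarray(all_draws),
        slices=slices,
        seed=seed,
        burn_in=burn_in,
        stats={"logp": np.asarray(all_logps), "chains": stats},
    )


# ---------------------------------------------------------------------------
# R-hat
# ---------------------------------------------------------------------------

def _classic_gelman_rubin(x: np.ndarray) -> float:
    """Between/within potential scale reduction for (chains, draws) draws."""
    m, n = x.shape
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def rhat(samples: PosteriorSamples, parameter: str, method: str = "rank"):
    """Potential-scale-reduction R-hat for one parameter.

    ``method="rank"`` (default) is the rank-normalised split-chain
    statistic; ``method="classic"`` the original between/within-chain
    Gelman-Rubin ratio.  Requires at least two chains and two draws.
    Vector parameters return one value per component.
    """
    x = np.asarray(samples.get(parameter), dtype=float)
    if samples.n_chains < 2:
        raise ValueError("R-hat requires at least two chains")
    if samples.n_draws < 2:
        raise ValueError("R-hat requires at least two draws per chain")
    if x.ndim == 2:
        comps = [x]
    else:
        comps = [x[:, :, k] for k in range(x.shape[2])]
    vals = []
    for comp in comps:
        if method == "classic":
            vals.append(_classic_gelman_rubin(comp))
        elif method == "rank":
            ds = az.rhat(az.from_dict(posterior={"p": comp}))
            vals.append(float(ds["p"].values))
        else:
            raise ValueError(f"unknown R-hat method {method!r}")
    return vals[0] if len(vals) == 1 else np.asarray(vals)


def rhat_trajectory(samples: PosteriorSamples, parameter: str,
                    n_points: int = 20, method: str = "rank"):
    """R-hat computed on growing chain prefixes (convergence-vs-length).

    Returns (lengths, values); useful for judging how many draws were
    needed for the chains to mix.
    """
    lengths = np.unique(
        np.linspace(4, samples.n_draws, n_points).astype(int)
    )
    vals = []
    for L in lengths:
        prefix = PosteriorSamples(
            raw=samples.raw[:, :L],
            slices=samples.slices,
            seed=samples.seed,
            burn_in=samples.burn_in,
        )
        vals.append(np.max(rhat(prefix, parameter, method=method)))
    return lengths, np.asarray(vals)


def convergence_report(samples: PosteriorSamples, parameters=None,
                       method: str = "rank") -> ConvergenceReport:
    parameters = parameters or samples.parameter_names()
    return ConvergenceReport(
        rhat={p: rhat(samples, p, method=method) for p in parameters},
        method=method,
    )


# ---------------------------------------------------------------------------
# MAP
# ---------------------------------------------------------------------------

def map_estimate(model, restarts: int = 3, seed: Optional[int] = None,
                 maxiter: int = 2000) -> MapEstimate:
    """Maximise the log-joint over the unconstrained parameters (L-BFGS).

    Starts from prior means with jitter; the best of ``restarts`` runs is
    returned.  Raises if no restart reaches a finite optimum that improves
    on its own initial point.
    """
    rng = np.random.default_rng(seed)

    def neg(theta):
        logp, grad = model.logp_and_grad(theta)
        return -logp, -grad

    best = None
    failures = []
    for k in range(restarts):
        x0 = model.initial_point(rng, jitter=0.05 if k == 0 else 0.5)
        logp0, _ = model.logp_and_grad(x0)
        res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        logp = -res.fun
        if not np.isfinite(logp) or logp < logp0:
            failures.append(res.message)
            continue
        if best is None or logp > best.logp:
            _, grad = model.logp_and_grad(res.x)
            best = MapEstimate(
                theta=res.x, logp=float(logp),
                grad_norm=float(np.linalg.norm(grad)),
                converged=bool(res.success), n_restarts=restarts,
            )
    if best is None:
        raise RuntimeError(f"all MAP restarts failed to improve: {failures}")
    return best
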