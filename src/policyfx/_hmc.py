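"""Self-contained No-U-Turn sampler with dual-averaging step-size adaptation
and windowed (diagonal or dense) mass-matrix adaptation.

The target is supplied as a callable returning the log density and its
gradient.  Everything is driven by a ``numpy.random.Generator``, so chains are
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular

_MAX_DELTA_ENERGY = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class ChainStats:
    divergences: int = 0
    step_size: float = float("nan")
    mean_accept: float = float("nan")
    treedepths: list = field(default_factory=list)


class Metric:
    """Euclidean metric M = Sigma^-1 built from a posterior-scale estimate.

    ``scale`` is either a variance vector (diagonal metric) or a covariance
    matrix (dense metric).  Momenta are N(0, M); the leapfrog velocity is
    Sigma p.
    """

    def __init__(self, scale: np.ndarray):
        scale = np.asarray(scale, dtype=float)
        if scale.ndim == 1:
            self.diag = np.maximum(scale, 1e-10)
            self._chol = None
        else:
            self.diag = None
            # guard positive-definiteness with a small ridge
            ridge = 1e-10 * np.trace(scale) / scale.shape[0]
            self._cov = scale + ridge * np.eye(scale.shape[0])
            self._chol = cholesky(self._cov, lower=True)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        if self.diag is not None:
            return self.diag * p
        return self._cov @ p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.velocity(p))

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        if self.diag is not None:
            return rng.standard_normal(self.diag.shape) / np.sqrt(self.diag)
        z = rng.standard_normal(self._chol.shape[0])
        return solve_triangular(self._chol, z, lower=True, trans="T")


def _leapfrog(logp_grad, q, p, grad, eps, metric: Metric):
    p = p + 0.5 * eps * grad
    q = q + eps * metric.velocity(p)
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _find_reasonable_epsilon(logp_grad, q, rng, metric: Metric):
    eps = 1.0
    logp, grad = logp_grad(q)
    p = metric.sample_momentum(rng)
    joint0 = logp - metric.kinetic(p)
    _, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, metric)
    joint1 = logp1 - metric.kinetic(p1)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, metric)
        joint1 = logp1 - metric.kinetic(p1)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging on log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.t += 1
        w = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        eta = self.t ** -self.kappa
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Tree:
    """State bundle for the recursive NUTS tree build (slice variant)."""

    __slots__ = ("logp_grad", "metric", "eps", "log_u", "joint0", "rng",
                 "n_accept_sum", "n_accept_count", "divergent")

    def __init__(self, logp_grad, metric, eps, log_u, joint0, rng):
        self.logp_grad = logp_grad
        self.metric = metric
        self.eps = eps
        self.log_u = log_u
        self.joint0 = joint0
        self.rng = rng
        self.n_accept_sum = 0.0
        self.n_accept_count = 0
        self.divergent = False

    def build(self, q, p, grad, v, j):
        if j == 0:
            q1, p1, logp1, grad1 = _leapfrog(
                self.logp_grad, q, p, grad, v * self.eps, self.metric
            )
            joint = logp1 - self.metric.kinetic(p1)
            if not np.isfinite(joint):
                joint = -np.inf
            n_valid = int(self.log_u <= joint)
            no_divergence = self.log_u < joint + _MAX_DELTA_ENERGY
            if not no_divergence:
                self.divergent = True
            self.n_accept_sum += min(1.0, np.exp(joint - self.joint0))
            self.n_accept_count += 1
            return q1, p1, grad1, q1, p1, grad1, q1, logp1, grad1, n_valid, no_divergence
        (qm, pm, gm, qp, pp_, gp, q1, logp1, grad1, n1, s1) = self.build(q, p, grad, v, j - 1)
        if s1:
            if v == -1:
                (qm, pm, gm, _, _, _, q2, logp2, grad2, n2, s2) = self.build(
                    qm, pm, gm, v, j - 1
                )
            else:
                (_, _, _, qp, pp_, gp, q2, logp2, grad2, n2, s2) = self.build(
                    qp, pp_, gp, v, j - 1
                )
            if n1 + n2 > 0 and self.rng.uniform() < n2 / (n1 + n2):
                q1, logp1, grad1 = q2, logp2, grad2
            dq = qp - qm
            s1 = (
                s2
                and (dq @ self.metric.velocity(pm)) >= 0
                and (dq @ self.metric.velocity(pp_)) >= 0
            )
            n1 += n2
        return qm, pm, gm, qp, pp_, gp, q1, logp1, grad1, n1, s1


def _nuts_step(logp_grad, q, logp, grad, eps, metric, rng, max_treedepth):
    p0 = metric.sample_momentum(rng)
    joint0 = logp - metric.kinetic(p0)
    log_u = joint0 + np.log(rng.uniform())
    tree = _Tree(logp_grad, metric, eps, log_u, joint0, rng)
    qm = qp = q
    pm = pp_ = p0
    gm = gp = grad
    q_new, logp_new, grad_new = q, logp, grad
    n, s, depth = 1, True, 0
    while s and depth < max_treedepth:
        v = 1 if rng.uniform() < 0.5 else -1
        if v == -1:
            (qm, pm, gm, _, _, _, q1, logp1, grad1, n1, s1) = tree.build(qm, pm, gm, v, depth)
        else:
            (_, _, _, qp, pp_, gp, q1, logp1, grad1, n1, s1) = tree.build(qp, pp_, gp, v, depth)
        if s1 and rng.uniform() < min(1.0, n1 / max(n, 1)):
            q_new, logp_new, grad_new = q1, logp1, grad1
        n += n1
        dq = qp - qm
        s = (
            s1
            and (dq @ metric.velocity(pm)) >= 0
            and (dq @ metric.velocity(pp_)) >= 0
        )
        depth += 1
    accept_prob = tree.n_accept_sum / max(tree.n_accept_count, 1)
    return q_new, logp_new, grad_new, accept_prob, tree.divergent, depth


def _adaptation_windows(n_warmup: int):
    """Stan-style schedule: fast start, doubling slow windows (the last one
    extended to be the largest), fast tail for step size only."""
    if n_warmup < 20:
        return []
    if n_warmup >= 150:
        init, term, w = 75, 50, 25
    else:
        init = max(int(0.15 * n_warmup), 5)
        term = max(int(0.10 * n_warmup), 5)
        w = max(int(0.10 * n_warmup), 10)
    end = n_warmup - term
    boundaries = []
    pos = init
    while pos < end:
        nxt = pos + w
        if nxt + 2 * w > end:
            nxt = end
        boundaries.append(nxt)
        pos = nxt
        w *= 2
    return boundaries


def _estimate_scale(samples: np.ndarray, dense: bool):
    """Regularized covariance (dense) or variance (diagonal) from a window.

    The dense estimate is shrunk toward its own diagonal, keeping the metric
    well-conditioned when the window is not much larger than the dimension.
    """
    n, dim = samples.shape
    if n < 2:
        return np.ones(dim)
    shrink = n / (n + 5.0)
    var = np.var(samples, axis=0, ddof=1)
    var = shrink * var + (1.0 - shrink) * 1e-3
    if dense and n >= dim:
        cov = np.cov(samples.T)
        w = n / (n + dim / 2.0)
        cov = w * cov + (1.0 - w) * np.diag(var)
        return cov + 1e-8 * np.eye(dim)
    return var


def sample_chain(
    logp_grad,
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    dense_mass: bool = True,
):
    """Run one NUTS chain; returns (draws (n_draws, dim), ChainStats)."""
    q = np.asarray(q0, dtype=float).copy()
    dim = q.shape[0]
    metric = Metric(np.ones(dim))
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")

    eps = _find_reasonable_epsilon(logp_grad, q, rng, metric)
    da = _DualAveraging(eps, target_accept)
    boundaries = set(_adaptation_windows(n_warmup))
    window_samples: list[np.ndarray] = []
    stats = ChainStats()
    accepts = []

    for i in range(n_warmup):
        q, logp, grad, aprob, div, depth = _nuts_step(
            logp_grad, q, logp, grad, eps, metric, rng, max_treedepth
        )
        eps = da.update(aprob)
        window_samples.append(q.copy())
        if (i + 1) in boundaries:
            w = np.asarray(window_samples)
            metric = Metric(_estimate_scale(w, dense_mass))
            eps = _find_reasonable_epsilon(logp_grad, q, rng, metric)
            da = _DualAveraging(eps, target_accept)
            window_samples = []

    eps = da.adapted if n_warmup > 0 else eps
    stats.step_size = eps

    draws = np.empty((n_draws, dim))
    for i in range(n_draws):
        q, logp, grad, aprob, div, depth = _nuts_step(
            logp_grad, q, logp, grad, eps, metric, rng, max_treedepth
        )
        draws[i] = q
        accepts.append(aprob)
        stats.treedepths.append(depth)
        if div:
            stats.divergences += 1
    stats.mean_accept = float(np.mean(accepts)) if accepts else float("nan")
    return draws, stats
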