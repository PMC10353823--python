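"""Rate-update kernels: adaptive Metropolis-Hastings and Strang-split HMC.

Both kernels operate on the *log* of the free rates.  In log space the
log-normal rate prior is Gaussian, which makes one half of the split
Hamiltonian exactly integrable (a harmonic rotation) and removes the
positivity constraint from the proposal geometry.  Both kernels accept a
temperature weight ``omega``: the chain targets
``(likelihood * prior) ** omega``, so prior and likelihood energies are
both scaled by ``omega``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AMHState",
    "HMCConfig",
    "HMCTarget",
    "amh_propose",
    "mh_accept",
    "update_covariance",
    "hamiltonian",
    "strang_trajectory",
    "hmc_update",
    "DEFAULT_JITTER",
]

#: diagonal jitter guaranteeing an invertible proposal covariance
DEFAULT_JITTER = 3.7508e-17


@dataclass
class AMHState:
    """Running mean/covariance of the sampled log-rate history.

    The proposal covariance is the empirical covariance of all past
    samples (scaled by the standard ``2.38^2 / d`` factor) plus a small
    diagonal jitter; before ``warmup`` samples have accumulated a fixed
    diagonal covariance of variance ``warmup_scale`` is used instead.
    """

    dim: int
    jitter: float = DEFAULT_JITTER
    warmup: int = 200
    warmup_scale: float = 0.01
    n_samples: int = 0
    history_mean: np.ndarray = field(default=None)
    _m2: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.history_mean is None:
            self.history_mean = np.zeros(self.dim)
        if self._m2 is None:
            self._m2 = np.zeros((self.dim, self.dim))

    @property
    def history_cov(self) -> np.ndarray:
        """Sample covariance (ddof=1) of the full history."""
        if self.n_samples < 2:
            return np.zeros((self.dim, self.dim))
        return self._m2 / (self.n_samples - 1)

    @property
    def adapted(self) -> bool:
        return self.n_samples > self.warmup

    def copy(self) -> "AMHState":
        return AMHState(
            self.dim,
            self.jitter,
            self.warmup,
            self.warmup_scale,
            self.n_samples,
            self.history_mean.copy(),
            self._m2.copy(),
        )


def update_covariance(amh: AMHState, new_log_rates: np.ndarray) -> AMHState:
    """Rank-1 (Welford) update of the running mean and covariance.

    Mutates and returns ``amh``; after ``n`` updates ``history_cov``
    equals the batch sample covariance of all ``n`` vectors.
    """
    x = np.asarray(new_log_rates, dtype=float)
    if x.shape != (amh.dim,):
        raise ValueError(f"expected shape ({amh.dim},), got {x.shape}")
    amh.n_samples += 1
    delta = x - amh.history_mean
    amh.history_mean = amh.history_mean + delta / amh.n_samples
    amh._m2 = amh._m2 + np.outer(delta, x - amh.history_mean)
    return amh


def amh_propose(
    current_log_rates: np.ndarray,
    amh: AMHState,
    rng: np.random.Generator,
    subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Symmetric Gaussian proposal around the current log-rates.

    After warm-up the covariance is ``(2.38^2 / d) * Sigma + jitter * I``
    built from the adapted history (restricted to ``subset`` coordinates
    when the active model spans fewer dimensions than the history).
    """
    x = np.asarray(current_log_rates, dtype=float)
    idx = np.arange(amh.dim) if subset is None else np.asarray(subset, dtype=int)
    d = idx.size
    if x.shape != (d,):
        raise ValueError("current_log_rates shape does not match subset")
    if not amh.adapted:
        sd = np.sqrt(amh.warmup_scale)
        return x + sd * rng.standard_normal(d)
    cov = amh.history_cov[np.ix_(idx, idx)] * (2.38**2 / d)
    cov = cov + amh.jitter * np.eye(d)
    try:
        chol = np.linalg.cholesky(cov)
        return x + chol @ rng.standard_normal(d)
    except np.linalg.LinAlgError:
        sd = np.sqrt(np.maximum(np.diag(cov), amh.jitter))
        return x + sd * rng.standard_normal(d)


def mh_accept(
    log_post_old: float,
    log_post_new: float,
    log_q_forward: float,
    log_q_backward: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis-Hastings accept/reject decision.

    Accepts with probability
    ``min(1, exp(log_post_new - log_post_old + log_q_backward - log_q_forward))``.
    A ``-inf`` proposal log-posterior always rejects.
    """
    if not np.isfinite(log_post_old):
        raise ValueError("current log-posterior must be finite")
    if log_post_new == -np.inf:
        return False
    log_r = log_post_new - log_post_old + log_q_backward - log_q_forward
    if log_r >= 0:
        return True
    return bool(np.log(rng.random()) < log_r)


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo with Strang splitting
# ---------------------------------------------------------------------------


@dataclass
class HMCConfig:
    """HMC settings: diagonal mass, Strang step, trajectory length, cadence."""

    step_size: float = 0.05
    n_steps: int = 20
    hmc_period: int = 10
    mass: np.ndarray | None = None  # diagonal of W; identity if None

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.hmc_period < 1:
            raise ValueError("hmc_period must be >= 1")
        if self.mass is not None:
            self.mass = np.asarray(self.mass, dtype=float)
            if np.any(self.mass <= 0):
                raise ValueError("mass diagonal must be positive")

    def mass_diag(self, dim: int) -> np.ndarray:
        if self.mass is None:
            return np.ones(dim)
        if self.mass.shape != (dim,):
            raise ValueError("mass diagonal dimension mismatch")
        return self.mass


@dataclass
class HMCTarget:
    """Energy terms of the sampled target over log-rates.

    ``neg_log_lik(x)`` is the *untempered* negative log-likelihood;
    ``grad_neg_log_lik(x)`` its gradient.  The Gaussian prior over
    log-rates has per-coordinate location ``prior_mu`` and scale
    ``prior_sigma``.  The temperature weight ``omega`` multiplies the
    likelihood energy only (the prior stays untempered in every chain, so
    tempered targets remain proper).
    """

    neg_log_lik: Callable[[np.ndarray], float]
    grad_neg_log_lik: Callable[[np.ndarray], np.ndarray]
    prior_mu: float = 0.0
    prior_sigma: float = 2.0
    omega: float = 1.0

    def prior_energy(self, x: np.ndarray) -> float:
        z = (x - self.prior_mu) / self.prior_sigma
        return 0.5 * float(z @ z)

    def likelihood_energy(self, x: np.ndarray) -> float:
        return self.omega * float(self.neg_log_lik(x))

    def likelihood_energy_grad(self, x: np.ndarray) -> np.ndarray:
        return self.omega * np.asarray(self.grad_neg_log_lik(x), dtype=float)


def hamiltonian(
    log_rates: np.ndarray,
    p: np.ndarray,
    target: HMCTarget,
    mass_diag: np.ndarray | None = None,
) -> float:
    """Total energy ``H = L(x) + V(x) + T(p)`` (up to additive constants).

    ``L`` is the (tempered) prior energy, ``V`` the (tempered) likelihood
    energy and ``T(p) = p^T W^-1 p / 2`` the kinetic energy.
    """
    x = np.asarray(log_rates, dtype=float)
    p = np.asarray(p, dtype=float)
    w = np.ones_like(p) if mass_diag is None else np.asarray(mass_diag, float)
    T = 0.5 * float(p @ (p / w))
    V = target.likelihood_energy(x)
    if not np.isfinite(V):
        return np.inf
    return target.prior_energy(x) + V + T


def _rotate_prior_kinetic(x, p, target: HMCTarget, w, dt):
    """Exact flow of ``H2 = L(x) + T(p)``: per-coordinate harmonic rotation."""
    alpha = np.sqrt(1.0 / (target.prior_sigma**2 * w))
    u = x - target.prior_mu
    c, s = np.cos(alpha * dt), np.sin(alpha * dt)
    u_new = u * c + p / (w * alpha) * s
    p_new = p * c - w * alpha * u * s
    return u_new + target.prior_mu, p_new


def strang_trajectory(
    log_rates: np.ndarray,
    p0: np.ndarray,
    cfg: HMCConfig,
    target: HMCTarget,
):
    """Integrate the split Hamiltonian for ``n_steps`` Strang steps.

    Per step: half-step momentum kick from ``H1 = V`` (likelihood energy),
    exact full-step rotation of ``H2 = L + T`` (Gaussian prior plus
    Gaussian kinetic energy), second half-step kick.  The map is
    time-reversible and volume-preserving.

    Returns ``(log_rates, p, ok)``; ``ok`` is False when a non-finite
    gradient aborted the trajectory (callers treat that as a rejection).
    """
    x = np.asarray(log_rates, dtype=float).copy()
    p = np.asarray(p0, dtype=float).copy()
    w = cfg.mass_diag(x.size)
    dt = cfg.step_size
    for _ in range(cfg.n_steps):
        g = target.likelihood_energy_grad(x)
        if not np.all(np.isfinite(g)):
            return x, p, False
        p = p - 0.5 * dt * g
        x, p = _rotate_prior_kinetic(x, p, target, w, dt)
        g = target.likelihood_energy_grad(x)
        if not np.all(np.isfinite(g)):
            return x, p, False
        p = p - 0.5 * dt * g
    return x, p, True


def hmc_update(
    log_rates: np.ndarray,
    cfg: HMCConfig,
    target: HMCTarget,
    rng: np.random.Generator,
):
    """One HMC proposal: sample momenta, integrate, Metropolis-correct.

    Returns ``(log_rates_next, accepted)``.
    """
    x0 = np.asarray(log_rates, dtype=float)
    w = cfg.mass_diag(x0.size)
    p0 = rng.standard_normal(x0.size) * np.sqrt(w)
    if cfg.n_steps == 0:
        return x0.copy(), True
    h_old = hamiltonian(x0, p0, target, w)
    if not np.isfinite(h_old):
        return x0.copy(), False
    x1, p1, ok = strang_trajectory(x0, p0, cfg, target)
    if not ok:
        return x0.copy(), False
    h_new = hamiltonian(x1, p1, target, w)
    log_r = h_old - h_new
    if log_r >= 0 or np.log(rng.random()) < log_r:
        return x1, True
    return x0.copy(), False
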