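"""Priors: shared log-normal rate priors and the Beta-Bernoulli process.

Every rate entering the generator gets the same log-normal prior (broad,
to span possible scale separation between rates).  The number of active
states is controlled by a Beta-Bernoulli process over ``L`` candidates:

    q_l ~ Beta(zeta / L, (L - 1) / L),    b_l | q_l ~ Bernoulli(q_l)

conditioned on at least one active load (``N >= 1``), since the likelihood
is undefined for an empty network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network_model import NetworkState, Rates, active_states

__all__ = [
    "PriorConfig",
    "log_prior_rates",
    "log_prior_load",
    "log_prior_q",
    "sample_bb_prior",
    "sample_rates_prior",
    "log_prior_joint",
]


@dataclass
class PriorConfig:
    """Hyperparameters of the joint prior.

    Defaults are artifact choices (broad log-normal; moderate expected
    number of active states), all configurable.
    """

    log_mu: float = 0.0
    log_sigma: float = 2.0
    zeta: float = 2.0
    L: int = 10

    def __post_init__(self) -> None:
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.L < 1:
            raise ValueError("L must be at least 1")

    @property
    def beta_shapes(self) -> tuple:
        """(a, b) shape parameters of the success-probability Beta prior."""
        return self.zeta / self.L, (self.L - 1) / self.L

    @property
    def p_active(self) -> float:
        """Marginal prior inclusion probability zeta / (zeta + L - 1)."""
        a, b = self.beta_shapes
        return a / (a + b)


def _lognorm_logpdf(x: np.ndarray, cfg: PriorConfig) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    z = (np.log(x) - cfg.log_mu) / cfg.log_sigma
    return -np.log(x) - np.log(cfg.log_sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * z * z


def log_prior_rates(rates: Rates, active, cfg: PriorConfig) -> float:
    """Sum of log-normal log-densities over rates entering the generator.

    Active switching rates (both directions for every active ordered
    pair), active production rates, and gamma; inactive-state rates are
    carried by the model but excluded here.
    """
    active = np.asarray(active, dtype=int)
    vals = [rates.beta[active], np.array([rates.gamma])]
    if active.size > 1:
        sub = rates.k[np.ix_(active, active)]
        vals.append(sub[~np.eye(active.size, dtype=bool)])
    allv = np.concatenate(vals)
    if np.any(allv <= 0) or not np.all(np.isfinite(allv)):
        return -np.inf
    return float(_lognorm_logpdf(allv, cfg).sum())


def log_normal_logpdf_logspace(x: np.ndarray, cfg: PriorConfig) -> np.ndarray:
    """Gaussian log-density of log-rates ``x`` (the log-normal prior seen
    from log space, Jacobian included)."""
    x = np.asarray(x, dtype=float)
    z = (x - cfg.log_mu) / cfg.log_sigma
    return -np.log(cfg.log_sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * z * z


def log_prior_q(q: float, cfg: PriorConfig) -> float:
    """Beta log-pdf of one success probability; -inf at the boundary."""
    if not 0.0 < q < 1.0:
        return -np.inf
    a, b = cfg.beta_shapes
    return float(stats.beta.logpdf(q, a, b))


def log_prior_load(b: int, q: float) -> float:
    """Bernoulli log-pmf of one load given its success probability."""
    if not 0.0 < q < 1.0:
        return -np.inf
    return float(np.log(q) if b else np.log1p(-q))


def sample_bb_prior(cfg: PriorConfig, rng: np.random.Generator):
    """Draw (success_probs, loads) from the Beta-Bernoulli prior, N >= 1.

    Redraws until at least one load is active (the all-zero configuration
    has zero support in this artifact).
    """
    if cfg.L < 2:
        raise ValueError("nonparametric mode requires L >= 2")
    a, b = cfg.beta_shapes
    while True:
        q = rng.beta(a, b, size=cfg.L)
        # guard against numerically degenerate draws at the boundary
        q = np.clip(q, 1e-12, 1.0 - 1e-12)
        loads = (rng.random(cfg.L) < q).astype(int)
        if loads.any():
            return q, loads


def sample_rates_prior(
    cfg: PriorConfig, rng: np.random.Generator, omega: float = 1.0
) -> Rates:
    """Draw a full candidate-rate set from the (possibly tempered) prior.

    Raising a log-normal prior to the power ``omega`` widens its log-scale
    to ``log_sigma / sqrt(omega)``; ``omega = 1`` recovers the prior.
    """
    sd = cfg.log_sigma / np.sqrt(omega)
    L = cfg.L
    k = np.exp(rng.normal(cfg.log_mu, sd, size=(L, L)))
    np.fill_diagonal(k, 1.0)  # diagonal unused
    beta = np.exp(rng.normal(cfg.log_mu, sd, size=L))
    gamma = float(np.exp(rng.normal(cfg.log_mu, sd)))
    return Rates(k, beta, gamma)


def log_prior_joint(
    state: NetworkState, cfg: PriorConfig, include_inactive: bool = False
) -> float:
    """Joint log-prior of the full latent state (additive in its parts).

    Rate terms, Bernoulli load terms, Beta terms for the success
    probabilities, and the uniform categorical prior over the initial gene
    state among the ``N`` active states.

    With ``include_inactive=False`` only rates entering the generator are
    counted (the reporting convention).  The samplers use
    ``include_inactive=True``: every candidate rate keeps its prior term
    whether or not its state is active, a constant-dimension
    parametrization with an identical posterior over the active part
    (inactive prior factors integrate to one) that keeps load flips and
    tempered-chain swaps dimension-consistent.
    """
    act = active_states(state)
    if include_inactive:
        r = state.rates
        offdiag = r.k[~np.eye(state.L, dtype=bool)]
        allv = np.concatenate([r.beta, offdiag, [r.gamma]])
        if np.any(allv <= 0) or not np.all(np.isfinite(allv)):
            return -np.inf
        total = float(_lognorm_logpdf(allv, cfg).sum())
    else:
        total = log_prior_rates(state.rates, act, cfg)
    for b, q in zip(state.loads, state.success_probs):
        total += log_prior_load(int(b), float(q))
        total += log_prior_q(float(q), cfg)
    total += -np.log(act.size)  # sigma* uniform over active states
    return float(total)
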