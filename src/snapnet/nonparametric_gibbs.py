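"""One full Gibbs sweep over loads, success probabilities, initial gene
state and rates.

The sweep targets the joint posterior over the constant-dimension latent
state: every candidate rate keeps a prior term whether or not its state
is active, so load flips never change the parameter dimension, and
inactive-state rates (refreshed from their prior each sweep) make
reactivation proposals draws from the prior.

Tempered chains raise the *likelihood* to the power ``omega``; the prior
is untempered in every chain.  (Tempering the full product makes the hot
chains' targets nearly flat over log-rates, so they diverge into
numerically infeasible stiffness; flattening the likelihood alone
preserves the easier-exploration purpose of tempering while keeping every
chain's target proper.)  Prior terms then cancel from the swap ratio,
which involves only log-likelihoods.

Within a sweep the rates are frozen until the final rate block, so
likelihood evaluations are cached by (loads, initial state); flipping a
load on and off revisits cached configurations at no cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import betaln

from .cme_likelihood import (
    SnapshotDataset,
    default_truncation,
    get_log_rates,
    log_likelihood,
    log_likelihood_gradient,
    rate_coordinates,
    set_log_rates,
)
from .network_model import NetworkState, active_states
from .priors import PriorConfig, log_normal_logpdf_logspace
from .rate_samplers import (
    AMHState,
    HMCConfig,
    HMCTarget,
    amh_propose,
    hmc_update,
    mh_accept,
    update_covariance,
)

__all__ = [
    "SamplerSettings",
    "SweepResult",
    "GibbsSampler",
    "all_rate_coordinates",
]


@dataclass
class SamplerSettings:
    """Rate-kernel settings shared by all chains.

    ``mode='adaptive'`` is the full method (AMH with adapted covariance
    plus intermittent HMC); ``mode='fixed'`` is the fixed-proposal
    ablation (diagonal Gaussian proposals, no adaptation, no HMC).
    """

    mode: str = "adaptive"
    use_hmc: bool = True
    hmc: HMCConfig = field(default_factory=HMCConfig)
    #: per-coordinate variance of the fixed-proposal ablation.  Fixed
    #: proposals are Gaussian steps on the *natural* rate scale (a single
    #: a-priori step size cannot serve rates separated by orders of
    #: magnitude — the failure mode the adaptive/log-space kernels exist
    #: to fix); negative proposals fall outside the support and reject.
    fixed_scale: float = 1.0
    q_concentration: float = 50.0
    amh_warmup: int = 200
    amh_warmup_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive", "fixed"):
            raise ValueError("mode must be 'adaptive' or 'fixed'")
        if self.mode == "fixed":
            self.use_hmc = False


@dataclass
class SweepResult:
    """Outcome of one Gibbs sweep."""

    state: NetworkState
    log_posterior: float  # tempered log-posterior at sweep end
    log_joint: float  # untempered log(likelihood * prior)
    log_lik: float
    accept_flags: dict


def _beta_logpdf(x, a, b):
    """Beta log-density (vectorized; faster than the scipy.stats object)."""
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)


def all_rate_coordinates(L: int, fixed: Iterable[str] = ()) -> list:
    """Fixed-order labels of every candidate log-rate coordinate."""
    fixed = set(fixed)
    coords = []
    if "k" not in fixed:
        coords.extend(
            ("k", i, j) for i in range(L) for j in range(L) if i != j
        )
    if "beta" not in fixed:
        coords.extend(("beta", i) for i in range(L))
    if "gamma" not in fixed:
        coords.append(("gamma",))
    return coords


class GibbsSampler:
    """Bundles data, priors and kernel settings; performs Gibbs sweeps."""

    def __init__(
        self,
        data: SnapshotDataset | None,
        prior: PriorConfig,
        sampler: SamplerSettings | None = None,
        truncation: int | None = None,
        fixed_rates: Iterable[str] = (),
        nonparametric: bool = True,
    ):
        if data is not None:
            data.validate()
        self.data = data
        self.prior = prior
        self.sampler = sampler if sampler is not None else SamplerSettings()
        if truncation is not None:
            self.truncation = int(truncation)
        elif data is not None:
            self.truncation = default_truncation(np.concatenate(data.counts))
        else:
            self.truncation = 10
        self.fixed_rates = frozenset(fixed_rates)
        self.nonparametric = nonparametric
        self.full_coords = all_rate_coordinates(prior.L, self.fixed_rates)
        self._coord_index = {c: i for i, c in enumerate(self.full_coords)}

    # -- posterior pieces ---------------------------------------------------

    def loglik(self, state: NetworkState, cache: dict | None = None) -> float:
        if self.data is None:
            return 0.0  # prior-only sampling (no observations)
        if cache is None:
            return log_likelihood(
                self.data, state, self.truncation, validate=False
            )
        key = (state.loads.tobytes(), state.initial_state)
        if key not in cache:
            cache[key] = log_likelihood(
                self.data, state, self.truncation, validate=False
            )
        return cache[key]

    def log_prior_log_space(self, state: NetworkState) -> float:
        """Log-prior of the latent state with rates parametrized in log
        space (Gaussian terms): active-rate terms, Beta-Bernoulli terms
        and the uniform sigma* term.  Identical in every chain (the prior
        is never tempered)."""
        cfg = self.prior
        x = get_log_rates(state, rate_coordinates(state, self.fixed_rates))
        total = float(log_normal_logpdf_logspace(x, cfg).sum())
        if self.nonparametric:
            a, b = cfg.beta_shapes
            q = state.success_probs
            if np.any((q <= 0) | (q >= 1)):
                return -np.inf
            total += float(_beta_logpdf(q, a, b).sum())
            total += float(
                np.sum(np.where(state.loads == 1, np.log(q), np.log1p(-q)))
            )
        total += -np.log(state.N)  # uniform sigma* prior over active states
        return total

    def log_joint(self, state: NetworkState, ll: float | None = None) -> float:
        """Untempered log(likelihood x prior); the quantity exchanged-on in
        parallel-tempering swaps."""
        if ll is None:
            ll = self.loglik(state)
        return ll + self.log_prior_log_space(state)

    def make_amh_state(self) -> AMHState:
        return AMHState(
            dim=len(self.full_coords),
            warmup=self.sampler.amh_warmup,
            warmup_scale=self.sampler.amh_warmup_scale,
        )

    # -- individual Gibbs blocks -------------------------------------------

    def refresh_inactive_rates(
        self, state: NetworkState, rng: np.random.Generator
    ) -> None:
        """Redraw rates not entering the generator from their prior, in
        place.  They remain well-defined for reactivation.  The prior is
        untempered in every chain (inactive rates sit outside the tempered
        block of the target), which keeps hot-chain reactivation proposals
        numerically tame."""
        cfg = self.prior
        sd = cfg.log_sigma
        act = active_states(state)
        mask = np.zeros(state.L, dtype=bool)
        mask[act] = True
        for i in range(state.L):
            for j in range(state.L):
                if i != j and not (mask[i] and mask[j]):
                    state.rates.k[i, j] = np.exp(rng.normal(cfg.log_mu, sd))
        for i in range(state.L):
            if not mask[i]:
                state.rates.beta[i] = np.exp(rng.normal(cfg.log_mu, sd))

    def sample_load(
        self,
        ell: int,
        state: NetworkState,
        rng: np.random.Generator,
        omega: float = 1.0,
        cache: dict | None = None,
    ) -> NetworkState:
        """Draw load ``b_ell`` from its exact two-point conditional.

        The initial gene state's load is held at 1 (its conditional is a
        point mass there), as is the last remaining active load.
        """
        if ell == state.initial_state:
            return state
        if state.loads[ell] == 1 and state.N == 1:
            return state
        q = float(state.success_probs[ell])
        lls = {}
        priors_ = {}
        for b in (0, 1):
            trial = state.copy()
            trial.loads[ell] = b
            lls[b] = self.loglik(trial, cache)
            priors_[b] = (np.log(q) if b else np.log1p(-q)) - np.log(trial.N)
        if lls[0] == -np.inf and lls[1] == -np.inf:
            return state  # keep current value; nothing is admissible
        if lls[1] == -np.inf:
            logit = -np.inf
        elif lls[0] == -np.inf:
            logit = np.inf
        else:
            # likelihood tempered, prior terms untempered; candidate-rate
            # prior terms are identical under both branches (constant
            # dimension) and cancel
            logit = omega * (lls[1] - lls[0]) + (priors_[1] - priors_[0])
        if logit >= 0:
            p1 = 1.0 / (1.0 + np.exp(-logit))
        else:
            e = np.exp(logit)
            p1 = e / (1.0 + e)
        new = state.copy()
        new.loads[ell] = 1 if rng.random() < p1 else 0
        return new

    def sample_success_prob(
        self,
        ell: int,
        state: NetworkState,
        rng: np.random.Generator,
        omega: float = 1.0,
    ) -> tuple:
        """Metropolis-Hastings update of ``q_ell`` with a mean-preserving
        Beta proposal; the conditional involves no data (and, being pure
        prior, is the same in every tempered chain)."""
        c = self.sampler.q_concentration
        a, b = self.prior.beta_shapes
        q = float(state.success_probs[ell])
        bl = int(state.loads[ell])
        qp = rng.beta(c * q, c * (1.0 - q))
        if not 0.0 < qp < 1.0:
            return state, False

        def target(v: float) -> float:
            return _beta_logpdf(v, a, b) + (
                np.log(v) if bl else np.log1p(-v)
            )

        log_fwd = _beta_logpdf(qp, c * q, c * (1.0 - q))
        log_bwd = _beta_logpdf(q, c * qp, c * (1.0 - qp))
        t_old, t_new = target(q), target(qp)
        if not np.isfinite(t_old):
            accept = np.isfinite(t_new)
        else:
            accept = mh_accept(t_old, t_new, log_fwd, log_bwd, rng)
        if accept:
            new = state.copy()
            new.success_probs[ell] = qp
            return new, True
        return state, False

    def sample_initial_state(
        self,
        state: NetworkState,
        rng: np.random.Generator,
        omega: float = 1.0,
        cache: dict | None = None,
    ) -> NetworkState:
        """Draw sigma* from its categorical conditional over active states."""
        act = active_states(state)
        if act.size == 1:
            return state
        lls = np.empty(act.size)
        for i, s in enumerate(act):
            trial = state.copy()
            trial.initial_state = int(s)
            lls[i] = self.loglik(trial, cache)
        if np.all(lls == -np.inf):
            return state
        w = omega * lls
        w -= w.max()
        probs = np.exp(w)
        probs /= probs.sum()
        new = state.copy()
        new.initial_state = int(rng.choice(act, p=probs))
        return new

    # -- rate block ---------------------------------------------------------

    def _coord_subset(self, coords) -> np.ndarray:
        return np.array([self._coord_index[c] for c in coords], dtype=int)

    def _tempered_rate_score(self, ll: float, x: np.ndarray, omega: float) -> float:
        """Tempered likelihood plus untempered log-space rate prior."""
        if ll == -np.inf:
            return -np.inf
        return omega * ll + float(log_normal_logpdf_logspace(x, self.prior).sum())

    def sample_rates_amh(
        self,
        state: NetworkState,
        amh: AMHState,
        rng: np.random.Generator,
        omega: float = 1.0,
        ll: float | None = None,
    ) -> tuple:
        """One (adaptive or fixed) Metropolis rate update on log-rates."""
        coords = rate_coordinates(state, self.fixed_rates)
        x = get_log_rates(state, coords)
        if ll is None:
            ll = self.loglik(state)
        if self.sampler.mode == "fixed":
            # fixed diagonal steps on the natural rate scale
            theta = np.exp(x)
            theta_p = theta + np.sqrt(self.sampler.fixed_scale) * rng.standard_normal(
                x.size
            )
            if np.any(theta_p <= 0):
                return state, ll, False  # outside the support
            xp = np.log(theta_p)
        else:
            xp = amh_propose(x, amh, rng, subset=self._coord_subset(coords))
        trial = set_log_rates(state, coords, xp)
        llp = self.loglik(trial)
        s_old = self._tempered_rate_score(ll, x, omega)
        s_new = self._tempered_rate_score(llp, xp, omega)
        if self.sampler.mode == "fixed" and np.isfinite(s_new):
            # symmetric in theta-space: convert the log-space target
            # density to the natural scale (Jacobian 1/theta per coord)
            s_old = s_old - float(x.sum())
            s_new = s_new - float(xp.sum())
        if not np.isfinite(s_old):
            accept = np.isfinite(s_new)
        else:
            accept = mh_accept(s_old, s_new, 0.0, 0.0, rng)
        if accept:
            return trial, llp, True
        return state, ll, False

    def sample_rates_hmc(
        self,
        state: NetworkState,
        rng: np.random.Generator,
        omega: float = 1.0,
        ll: float | None = None,
    ) -> tuple:
        """One Strang-split HMC rate update on log-rates."""
        coords = rate_coordinates(state, self.fixed_rates)
        x0 = get_log_rates(state, coords)

        def nll(x: np.ndarray) -> float:
            return -self.loglik(set_log_rates(state, coords, x))

        def grad_nll(x: np.ndarray) -> np.ndarray:
            trial = set_log_rates(state, coords, x)
            return -log_likelihood_gradient(
                self.data, trial, self.truncation, coords
            )

        target = HMCTarget(
            nll,
            grad_nll,
            prior_mu=self.prior.log_mu,
            prior_sigma=self.prior.log_sigma,
            omega=omega,
        )
        cfg = self.sampler.hmc
        try:
            x1, accepted = hmc_update(x0, cfg, target, rng)
        except Exception:
            return state, ll if ll is not None else self.loglik(state), False
        if accepted and not np.array_equal(x1, x0):
            new = set_log_rates(state, coords, x1)
            return new, self.loglik(new), True
        return state, ll if ll is not None else self.loglik(state), accepted

    # -- the sweep ----------------------------------------------------------

    def gibbs_sweep(
        self,
        state: NetworkState,
        amh: AMHState,
        rng: np.random.Generator,
        omega: float = 1.0,
        sweep_index: int = 0,
    ) -> SweepResult:
        """Loads, then success probabilities, then sigma*, then one rate
        update (HMC on the configured cadence, AMH otherwise)."""
        state = state.copy()
        cache: dict = {}
        flags: dict = {}
        if self.nonparametric:
            self.refresh_inactive_rates(state, rng)
            n_flips = 0
            for ell in range(state.L):
                before = int(state.loads[ell])
                state = self.sample_load(ell, state, rng, omega, cache)
                n_flips += int(state.loads[ell] != before)
            flags["load_flips"] = n_flips
            n_q = 0
            for ell in range(state.L):
                state, acc = self.sample_success_prob(ell, state, rng, omega)
                n_q += int(acc)
            flags["q_accepts"] = n_q
            state = self.sample_initial_state(state, rng, omega, cache)
        ll = self.loglik(state, cache)
        use_hmc = (
            self.sampler.use_hmc
            and self.sampler.hmc.hmc_period > 0
            and (sweep_index + 1) % self.sampler.hmc.hmc_period == 0
            and np.isfinite(ll)
        )
        if use_hmc:
            state, ll, acc = self.sample_rates_hmc(state, rng, omega, ll)
            flags["hmc_accept"] = acc
        else:
            state, ll, acc = self.sample_rates_amh(state, amh, rng, omega, ll)
            flags["rate_accept"] = acc
        if self.sampler.mode == "adaptive":
            update_covariance(amh, get_log_rates(state, self.full_coords))
        lp = self.log_prior_log_space(state)
        log_joint = ll + lp
        tempered = omega * ll + lp
        return SweepResult(
            state=state,
            log_posterior=tempered if np.isfinite(tempered) else -np.inf,
            log_joint=log_joint,
            log_lik=ll,
            accept_flags=flags,
        )
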