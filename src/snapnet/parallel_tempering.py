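"""Adaptive parallel tempering around the Gibbs sweep.

``H`` chains target ``(likelihood * prior) ** omega_h`` with
``omega_h = 1 / T_h`` and ``T_1 = 1`` (the cold chain is the inference
target).  After each round of sweeps, chains are paired uniformly at
random and their full latent states are exchanged with the Metropolis
swap probability; the temperature ladder (all temperatures except
``T_1``) is adapted by stochastic approximation on the log-gaps toward a
target swap acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .cme_likelihood import SnapshotDataset
from .diagnostics import TraceStore
from .network_model import NetworkState
from .nonparametric_gibbs import GibbsSampler, SamplerSettings
from .priors import PriorConfig, sample_bb_prior, sample_rates_prior
from .rate_samplers import AMHState

__all__ = [
    "TemperatureLadder",
    "PTConfig",
    "ChainState",
    "tempered_log_posterior",
    "swap_round",
    "adapt_ladder",
    "initialize_chain",
    "run_pt",
]


@dataclass
class TemperatureLadder:
    """Temperatures of the chain ensemble; ``temps[0] == 1`` always."""

    temps: np.ndarray
    adapt_target: float = 0.234
    adapt_decay: float = 0.6
    adaptation_step: int = 0
    swap_attempts: np.ndarray = field(default=None)
    swap_accepts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        if self.temps[0] != 1.0:
            raise ValueError("the first temperature must be exactly 1")
        if np.any(np.diff(self.temps) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        n_gaps = max(self.H - 1, 0)
        if self.swap_attempts is None:
            self.swap_attempts = np.zeros(n_gaps)
        if self.swap_accepts is None:
            self.swap_accepts = np.zeros(n_gaps)

    @property
    def H(self) -> int:
        return self.temps.size

    @property
    def omegas(self) -> np.ndarray:
        return 1.0 / self.temps

    @classmethod
    def geometric(cls, n_chains: int, t_max: float = 50.0, **kw) -> "TemperatureLadder":
        if n_chains == 1:
            return cls(np.array([1.0]), **kw)
        return cls(np.geomspace(1.0, t_max, n_chains), **kw)

    def swap_rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.swap_attempts > 0, self.swap_accepts / np.maximum(self.swap_attempts, 1), np.nan
            )


@dataclass
class PTConfig:
    """Ensemble settings."""

    n_chains: int = 5
    sweeps_per_round: int = 10
    t_max_init: float = 50.0
    adapt_target: float = 0.234
    adapt_decay: float = 0.6
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.sweeps_per_round < 1:
            raise ValueError("sweeps_per_round must be >= 1")


@dataclass
class ChainState:
    """One tempered chain: model state plus its sampler bookkeeping."""

    state: NetworkState
    amh: AMHState
    rng: np.random.Generator
    log_joint: float = -np.inf
    log_lik: float = -np.inf
    sweep_index: int = 0


def tempered_log_posterior(
    sampler: GibbsSampler, state: NetworkState, omega: float
) -> float:
    """``omega * (log likelihood + joint log prior)``."""
    if not 0.0 < omega <= 1.0:
        raise ValueError("omega must lie in (0, 1]")
    lj = sampler.log_joint(state)
    return omega * lj if np.isfinite(lj) else -np.inf


def swap_round(
    chains: list,
    ladder: TemperatureLadder,
    rng: np.random.Generator,
) -> list:
    """Pair chains at random and propose full-state exchanges.

    For a pair at temperature indices ``(h1 < h2)`` the swap is accepted
    with probability ``min(1, exp((omega_1 - omega_2) * (ll_2 - ll_1)))``
    where ``ll`` are the chains' untempered log-likelihoods (the prior is
    untempered in every chain's target, so its terms cancel from the
    ratio).  Returns the list of attempted swaps as ``(h1, h2, accepted)``.
    """
    H = len(chains)
    if H < 2:
        return []
    omegas = ladder.omegas
    order = rng.permutation(H)
    outcomes = []
    for i in range(0, H - 1, 2):
        h1, h2 = sorted((int(order[i]), int(order[i + 1])))
        ca, cb = chains[h1], chains[h2]
        log_r = (omegas[h1] - omegas[h2]) * (cb.log_lik - ca.log_lik)
        if np.isnan(log_r):
            accepted = False
        else:
            accepted = log_r >= 0 or np.log(rng.random()) < log_r
        if accepted:
            ca.state, cb.state = cb.state, ca.state
            ca.log_joint, cb.log_joint = cb.log_joint, ca.log_joint
            ca.log_lik, cb.log_lik = cb.log_lik, ca.log_lik
        for g in range(h1, h2):
            ladder.swap_attempts[g] += 1
            ladder.swap_accepts[g] += int(accepted)
        outcomes.append((h1, h2, accepted))
    return outcomes


def adapt_ladder(ladder: TemperatureLadder, swap_outcomes: Iterable) -> TemperatureLadder:
    """Stochastic-approximation update of the log temperature gaps.

    ``rho_g = log(T_{g+1} - T_g)`` moves by ``n^-decay * (A - target)``
    for every adjacent gap spanned by an attempted swap; gaps stay
    positive so monotonicity is preserved and ``T_1`` never changes.
    """
    outcomes = list(swap_outcomes)
    if not outcomes or ladder.H < 2:
        return ladder
    ladder.adaptation_step += 1
    gamma_n = ladder.adaptation_step ** (-ladder.adapt_decay)
    rho = np.log(np.diff(ladder.temps))
    for h1, h2, accepted in outcomes:
        delta = gamma_n * (float(accepted) - ladder.adapt_target)
        rho[h1:h2] += delta
    ladder.temps = np.concatenate(([1.0], 1.0 + np.cumsum(np.exp(rho))))
    return ladder


def initialize_chain(
    sampler: GibbsSampler,
    rng: np.random.Generator,
    loads: np.ndarray | None = None,
    initial_state: int | None = None,
    fixed_rate_values: dict | None = None,
) -> ChainState:
    """Draw a chain's starting state from the prior.

    In parametric mode pass explicit ``loads`` (e.g. a single active
    state); otherwise loads and success probabilities come from the
    Beta-Bernoulli prior.
    """
    cfg = sampler.prior
    if loads is None:
        q, b = sample_bb_prior(cfg, rng)
    else:
        # parametric mode: loads are fixed and q is inert
        b = np.asarray(loads, dtype=int)
        q = np.full(cfg.L, 0.5)
    rates = sample_rates_prior(cfg, rng)
    act = np.flatnonzero(b)
    sigma = (
        int(act[rng.integers(act.size)]) if initial_state is None else initial_state
    )
    state = NetworkState(b, q, rates, sigma)
    if fixed_rate_values:
        if "gamma" in fixed_rate_values:
            state.rates.gamma = float(fixed_rate_values["gamma"])
    state.validate()
    chain = ChainState(state=state, amh=sampler.make_amh_state(), rng=rng)
    chain.log_lik = sampler.loglik(state)
    chain.log_joint = sampler.log_joint(state, chain.log_lik)
    return chain


def _write_checkpoint(path, done, seed, chains, ladder, error) -> None:
    """Dump ensemble state (all chains + ladder) for inspection/resume.

    Runs are bit-reproducible from their seed, so the checkpoint carries
    the states and progress rather than raw RNG internals.
    """
    import json
    from pathlib import Path

    payload = {
        "sweeps_completed": int(done),
        "seed": int(seed),
        "error": error,
        "temps": ladder.temps.tolist(),
        "chains": [
            {
                "state": json.loads(c.state.to_json()),
                "log_joint": float(c.log_joint),
                "log_lik": float(c.log_lik),
                "sweep_index": int(c.sweep_index),
            }
            for c in chains
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _record(
    trace: TraceStore, chain: ChainState, ladder, omega: float, flags: dict
) -> None:
    import json

    st = chain.state
    trace.add(
        accepts=json.dumps(flags),
        iteration=chain.sweep_index - 1,
        N=st.N,
        loads=st.loads.copy(),
        success_probs=st.success_probs.copy(),
        initial_state=st.initial_state,
        beta=st.rates.beta.copy(),
        gamma=st.rates.gamma,
        k=st.rates.k.copy(),
        log_joint=chain.log_joint,
        log_posterior=omega * chain.log_joint,
        log_lik=chain.log_lik,
        temps=ladder.temps.copy(),
    )


def run_pt(
    data: SnapshotDataset,
    *,
    prior: PriorConfig,
    sampler_settings: SamplerSettings | None = None,
    pt: PTConfig | None = None,
    total_sweeps: int = 1000,
    seed: int = 0,
    nonparametric: bool = True,
    fixed_rates: Iterable[str] = (),
    truncation: int | None = None,
    parametric_loads: np.ndarray | None = None,
    fixed_rate_values: dict | None = None,
    callback: Callable | None = None,
    record_ladder: bool = False,
    checkpoint_path=None,
) -> TraceStore:
    """Run the full tempered ensemble and return the cold-chain trace.

    Fully reproducible from ``seed``: a master seed sequence spawns one
    independent stream per chain plus one for initialization and swaps.
    ``callback(iteration, trace)`` (if given) is polled after every swap
    round and may return True to stop early.  With ``n_chains=1`` no swap
    rounds occur (the no-PT ablation).
    """
    pt = pt if pt is not None else PTConfig()
    sampler_settings = sampler_settings if sampler_settings is not None else SamplerSettings()
    fixed_rates = set(fixed_rates) | set(fixed_rate_values or {})
    sampler = GibbsSampler(
        data,
        prior,
        sampler_settings,
        truncation=truncation,
        fixed_rates=fixed_rates,
        nonparametric=nonparametric,
    )
    H = pt.n_chains
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(H + 1)]
    swap_rng = streams[-1]
    ladder = TemperatureLadder.geometric(
        H, pt.t_max_init, adapt_target=pt.adapt_target, adapt_decay=pt.adapt_decay
    )
    if nonparametric:
        parametric_loads = None
    chains = [
        initialize_chain(
            sampler,
            streams[h],
            loads=parametric_loads,
            fixed_rate_values=fixed_rate_values,
        )
        for h in range(H)
    ]
    trace = TraceStore(meta={"seed": seed, "n_chains": H})
    ladder_trace = TraceStore(meta={"seed": seed}) if record_ladder else None
    done = 0
    try:
        while done < total_sweeps:
            block = min(pt.sweeps_per_round, total_sweeps - done)
            for h, chain in enumerate(chains):
                omega = ladder.omegas[h]
                for _ in range(block):
                    res = sampler.gibbs_sweep(
                        chain.state,
                        chain.amh,
                        chain.rng,
                        omega=omega,
                        sweep_index=chain.sweep_index,
                    )
                    chain.state = res.state
                    chain.log_joint = res.log_joint
                    chain.log_lik = res.log_lik
                    chain.sweep_index += 1
                    if h == 0:
                        _record(trace, chain, ladder, omega, res.accept_flags)
            done += block
            if H > 1:
                outcomes = swap_round(chains, ladder, swap_rng)
                if pt.adapt:
                    adapt_ladder(ladder, outcomes)
                assert ladder.temps[0] == 1.0
            if ladder_trace is not None:
                ladder_trace.add(iteration=done, temps=ladder.temps.copy())
            if callback is not None and callback(done, trace):
                break
    except Exception as exc:
        if checkpoint_path is not None:
            _write_checkpoint(checkpoint_path, done, seed, chains, ladder, str(exc))
        raise
    if checkpoint_path is not None:
        _write_checkpoint(checkpoint_path, done, seed, chains, ladder, None)
    trace.meta["ladder"] = ladder.temps.tolist()
    trace.meta["swap_rate"] = ladder.swap_rate().tolist()
    if record_ladder:
        trace.meta["ladder_trace"] = ladder_trace
    return trace
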