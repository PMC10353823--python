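"""Gene-state reaction network model and truncated generator construction.

A network consists of ``L`` candidate gene states.  Each candidate state
``l`` carries a binary *load* ``b_l`` saying whether it participates in the
model, a *success probability* ``q_l`` (its prior inclusion probability), a
per-state RNA production rate ``beta_l``, transition rates ``k[l, l']`` to
every other candidate state, and there is one global per-molecule
degradation rate ``gamma``.  Only the ``N = sum(b)`` active states enter the
dynamics: the composite state space is ``(active gene state, RNA count)``
with the count axis truncated at ``M`` (finite state projection).

Indexing conventions: candidate states and counts are 0-based; the
composite index of (active position ``a``, count ``m``) is
``a * (M + 1) + m``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Rates",
    "NetworkState",
    "GeneratorMatrix",
    "InvalidModelError",
    "active_states",
    "build_generator",
    "permute_states",
    "canonicalize",
    "default_truncation",
]


class InvalidModelError(ValueError):
    """Raised when a network state violates its structural invariants."""


@dataclass
class Rates:
    """All dynamical rates of the candidate network.

    Parameters
    ----------
    k
        ``(L, L)`` matrix of gene-state transition rates; entry ``k[i, j]``
        is the rate of the switch ``i -> j``.  The diagonal is unused.
    beta
        Length-``L`` vector of per-state RNA production rates.
    gamma
        Global per-molecule RNA degradation rate.
    """

    k: np.ndarray
    beta: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = float(self.gamma)
        L = self.beta.shape[0]
        if self.k.shape != (L, L):
            raise InvalidModelError(
                f"k must be ({L}, {L}) to match beta; got {self.k.shape}"
            )

    @property
    def L(self) -> int:
        return self.beta.shape[0]

    def validate(self) -> None:
        offdiag = self.k[~np.eye(self.L, dtype=bool)]
        for name, arr in (("k", offdiag), ("beta", self.beta)):
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise InvalidModelError(f"{name} entries must be positive and finite")
        if not np.isfinite(self.gamma) or self.gamma <= 0:
            raise InvalidModelError("gamma must be positive and finite")

    def copy(self) -> "Rates":
        return Rates(self.k.copy(), self.beta.copy(), self.gamma)

    def to_dict(self) -> dict:
        return {
            "k": self.k.tolist(),
            "beta": self.beta.tolist(),
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rates":
        return cls(np.array(d["k"], float), np.array(d["beta"], float), d["gamma"])


@dataclass
class NetworkState:
    """Full latent model: loads, success probabilities, rates, initial state."""

    loads: np.ndarray
    success_probs: np.ndarray
    rates: Rates
    initial_state: int

    def __post_init__(self) -> None:
        self.loads = np.asarray(self.loads, dtype=int)
        self.success_probs = np.asarray(self.success_probs, dtype=float)
        self.initial_state = int(self.initial_state)

    @property
    def L(self) -> int:
        return self.loads.shape[0]

    @property
    def N(self) -> int:
        return int(self.loads.sum())

    def validate(self) -> None:
        if self.loads.shape != (self.L,) or not np.all(
            (self.loads == 0) | (self.loads == 1)
        ):
            raise InvalidModelError("loads must be a binary vector")
        if self.N < 1:
            raise InvalidModelError("at least one load must be active (N >= 1)")
        if not (0 <= self.initial_state < self.L):
            raise InvalidModelError("initial_state out of range")
        if self.loads[self.initial_state] != 1:
            raise InvalidModelError("initial_state must index an active state")
        if self.success_probs.shape != (self.L,) or np.any(
            (self.success_probs <= 0) | (self.success_probs >= 1)
        ):
            raise InvalidModelError("success_probs must lie strictly in (0, 1)")
        if self.rates.L != self.L:
            raise InvalidModelError("rates dimension mismatch")
        self.rates.validate()

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.loads.copy(),
            self.success_probs.copy(),
            self.rates.copy(),
            self.initial_state,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "loads": self.loads.tolist(),
                "success_probs": self.success_probs.tolist(),
                "rates": self.rates.to_dict(),
                "initial_state": self.initial_state,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NetworkState":
        d = json.loads(s)
        return cls(
            np.array(d["loads"], int),
            np.array(d["success_probs"], float),
            Rates.from_dict(d["rates"]),
            d["initial_state"],
        )


@dataclass
class GeneratorMatrix:
    """Truncated CME generator over composite (gene state, count) space.

    ``matrix[i, j]`` is the rate of the jump from composite state ``j`` to
    ``i``; diagonals carry total outflow, including the production jump
    dropped at the count boundary ``m = M`` (so boundary columns sum to
    ``-beta`` and probability mass may leak there, which is monitored
    downstream).  ``beta_active``, ``k_active`` and ``gamma`` retain the
    block structure so solvers can apply the generator without assembling
    the dense matrix, which is therefore built lazily.
    """

    truncation: int
    active: tuple
    beta_active: np.ndarray
    k_active: np.ndarray
    gamma: float
    _matrix: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return len(self.active)

    @property
    def dim(self) -> int:
        return self.n_states * (self.truncation + 1)

    @property
    def uniformization_rate(self) -> float:
        """Upper bound on total outflow from any composite state."""
        kout = self.k_active.sum(axis=1) - np.diag(self.k_active)
        return float(
            np.max(self.beta_active + self.gamma * self.truncation + kout)
        )

    def index(self, active_pos: int, m: int) -> int:
        return active_pos * (self.truncation + 1) + m

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = self._assemble_dense()
        return self._matrix

    def _assemble_dense(self) -> np.ndarray:
        M = self.truncation
        N = self.n_states
        n = M + 1
        A = np.zeros((self.dim, self.dim))
        m = np.arange(n)
        for a in range(N):
            lo = a * n
            block = A[lo : lo + n, lo : lo + n]
            # production: column m feeds row m+1
            block[np.arange(1, n), np.arange(n - 1)] = self.beta_active[a]
            # degradation: column m feeds row m-1 at gamma*m
            block[np.arange(n - 1), np.arange(1, n)] = self.gamma * m[1:]
            for b in range(N):
                if b == a:
                    continue
                idx = np.arange(n)
                A[b * n + idx, lo + idx] = self.k_active[a, b]
        out = -A.sum(axis=0)
        for a in range(N):
            out[a * n + M] -= self.beta_active[a]
        A[np.diag_indices(self.dim)] = out
        return A


def active_states(state: NetworkState) -> np.ndarray:
    """Indices ``l`` with ``b_l = 1``, ascending.  Length equals ``N``."""
    state_loads = np.asarray(state.loads)
    if not state_loads.any():
        raise InvalidModelError("all-zero load vector: no active states")
    return np.flatnonzero(state_loads)


def default_truncation(counts: Sequence[int]) -> int:
    """Count-axis truncation bound from observed data.

    ``M = max(count) + ceil(4 * sqrt(max(count) + 1)) + 10`` — generous
    headroom above the largest observation so that leaked probability mass
    is negligible for models compatible with the data.
    """
    cmax = int(np.max(counts)) if len(counts) else 0
    return cmax + int(np.ceil(4.0 * np.sqrt(cmax + 1.0))) + 10


def build_generator(
    state: NetworkState, truncation: int, validate: bool = True
) -> GeneratorMatrix:
    """Assemble the truncated generator for the active states of ``state``.

    Jumps encoded for each active state ``s_i`` (position ``a``) and count
    ``m``:

    * production ``(s_i, m) -> (s_i, m + 1)`` at rate ``beta_i`` (``m < M``);
    * degradation ``(s_i, m) -> (s_i, m - 1)`` at rate ``gamma * m``;
    * switching ``(s_i, m) -> (s_j, m)`` at rate ``k[s_i, s_j]`` for every
      ordered pair of distinct active states (fully connected — no topology
      is assumed).
    """
    M = int(truncation)
    if M < 1:
        raise ValueError(f"truncation must be >= 1, got {M}")
    if validate:
        state.validate()
    act = active_states(state)
    return GeneratorMatrix(
        truncation=M,
        active=tuple(int(x) for x in act),
        beta_active=state.rates.beta[act].copy(),
        k_active=state.rates.k[np.ix_(act, act)].copy(),
        gamma=state.rates.gamma,
    )


def permute_states(state: NetworkState, permutation: Sequence[int]) -> NetworkState:
    """Relabel candidate states by ``permutation`` (old label -> new label).

    The permutation must map the active set onto itself and the inactive
    set onto itself; the likelihood is invariant under this relabeling.
    """
    perm = np.asarray(permutation, dtype=int)
    L = state.L
    if perm.shape != (L,) or sorted(perm.tolist()) != list(range(L)):
        raise ValueError("permutation must be a permutation of range(L)")
    act = set(active_states(state).tolist())
    for old in range(L):
        if (old in act) != (perm[old] in act):
            raise ValueError("permutation must not mix active and inactive states")
    inv = np.empty(L, dtype=int)
    inv[perm] = np.arange(L)
    new_rates = Rates(
        state.rates.k[np.ix_(inv, inv)],
        state.rates.beta[inv],
        state.rates.gamma,
    )
    return NetworkState(
        state.loads[inv],
        state.success_probs[inv],
        new_rates,
        int(perm[state.initial_state]),
    )


def canonicalize(state: NetworkState) -> NetworkState:
    """Return an equivalent model whose active states are sorted by beta.

    Resolves label switching when summarizing posterior samples: active
    labels are re-assigned in order of increasing production rate, leaving
    inactive labels untouched.
    """
    act = active_states(state)
    order = act[np.argsort(state.rates.beta[act], kind="stable")]
    perm = np.arange(state.L)
    perm[order] = act
    return permute_states(state, perm)
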