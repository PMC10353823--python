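"""Chemical master equation propagation and snapshot-data likelihood.

The CME ``dP/dt = A P`` is solved over the truncated composite state space
by applying the matrix exponential of the generator to the initial
probability vector.  For a dataset of (time, count) snapshots the
likelihood is the product over times and cells of the count marginal of
``P(t_k)`` (cells are i.i.d. at each time), so a single propagation per
distinct time suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from ._uniformization import uniformized_action
from .network_model import (
    GeneratorMatrix,
    NetworkState,
    active_states,
    build_generator,
    default_truncation,
)

__all__ = [
    "ProbabilityVector",
    "SnapshotDataset",
    "PropagationError",
    "initial_vector",
    "propagate",
    "propagate_times",
    "count_marginal",
    "log_likelihood",
    "log_likelihood_gradient",
    "rate_coordinates",
    "get_log_rates",
    "set_log_rates",
]

#: propagated entries may undershoot zero by at most this much before we
#: declare the propagation numerically broken
_NEGATIVITY_TOL = 1e-10


class PropagationError(RuntimeError):
    """CME propagation failed (stiffness blow-up / non-finite result).

    Carries the offending model so callers can treat the proposal as having
    zero likelihood instead of crashing.
    """

    def __init__(self, message: str, state: NetworkState | None = None):
        super().__init__(message)
        self.state = state


@dataclass
class ProbabilityVector:
    """Probability vector over composite (gene state, count) states."""

    values: np.ndarray
    time: float
    truncation: int

    @property
    def n_states(self) -> int:
        return self.values.shape[0] // (self.truncation + 1)

    def leak(self) -> float:
        """Probability mass lost at the truncation boundary."""
        return 1.0 - float(self.values.sum())


@dataclass
class SnapshotDataset:
    """Grouped snapshot observations: counts from fixed cells at each time."""

    times: np.ndarray
    counts: list

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = [np.asarray(c, dtype=int) for c in self.counts]

    def validate(self) -> None:
        if len(self.times) != len(self.counts):
            raise ValueError("times and count groups must align")
        if len(self.times) == 0:
            raise ValueError("dataset must contain at least one time point")
        if np.any(self.times <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        for c in self.counts:
            if c.size < 1:
                raise ValueError("each time point needs at least one cell")
            if np.any(c < 0):
                raise ValueError("counts must be non-negative integers")

    @property
    def n_per_time(self) -> np.ndarray:
        return np.array([c.size for c in self.counts])

    @property
    def n_cells(self) -> int:
        return int(self.n_per_time.sum())

    @property
    def max_count(self) -> int:
        return int(max(c.max() for c in self.counts))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(t, m) for t, grp in zip(self.times, self.counts) for m in grp]
        return pd.DataFrame(rows, columns=["time", "count"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SnapshotDataset":
        if not {"time", "count"} <= set(df.columns):
            raise ValueError("expected columns 'time' and 'count'")
        times = np.sort(df["time"].unique())
        counts = [
            df.loc[df["time"] == t, "count"].to_numpy(dtype=int) for t in times
        ]
        ds = cls(times, counts)
        ds.validate()
        return ds

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SnapshotDataset":
        return cls.from_dataframe(pd.read_csv(path))

    def to_json_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "counts": [c.tolist() for c in self.counts],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SnapshotDataset":
        ds = cls(np.array(d["times"], float), [np.array(c, int) for c in d["counts"]])
        ds.validate()
        return ds


def initial_vector(state: NetworkState, truncation: int) -> ProbabilityVector:
    """Unit mass at (initial gene state, zero molecules)."""
    act = active_states(state)
    pos = np.flatnonzero(act == state.initial_state)
    if pos.size == 0:
        raise ValueError("initial_state is not active")
    n = truncation + 1
    v = np.zeros(act.size * n)
    v[int(pos[0]) * n] = 1.0
    return ProbabilityVector(v, 0.0, truncation)


def _check_vector(v: np.ndarray, state: NetworkState | None) -> np.ndarray:
    if not np.all(np.isfinite(v)):
        raise PropagationError("non-finite CME solution", state)
    if v.min() < -_NEGATIVITY_TOL:
        raise PropagationError(
            f"CME solution entry below -{_NEGATIVITY_TOL:g}: {v.min():g}", state
        )
    return np.clip(v, 0.0, 1.0)


#: uniformization is used while its predicted work (jump budget times
#: per-matvec cost) stays below this many flops; beyond it an
#: eigendecomposition (stiffness-independent cost) is attempted, then a
#: dense expm, before the model is declared numerically infeasible
_UNIFORMIZATION_WORK_CAP = 6e7

#: eig / dense-expm fallbacks are affordable only for moderate dimensions
_EXPM_MAX_DIM = 260


def propagate(
    gen: GeneratorMatrix,
    p0: ProbabilityVector,
    t: float,
    state: NetworkState | None = None,
) -> ProbabilityVector:
    """Apply ``exp(A t)`` to ``p0``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if p0.values.shape[0] != gen.dim:
        raise ValueError("vector/generator dimension mismatch")
    if t == 0:
        return ProbabilityVector(p0.values.copy(), p0.time, gen.truncation)
    out = propagate_times(gen, p0, [t], state)[0]
    out.time = p0.time + t
    return out


def propagate_times(
    gen: GeneratorMatrix,
    p0: ProbabilityVector,
    times: Sequence[float],
    state: NetworkState | None = None,
) -> list:
    """Propagate ``p0`` to several increasing times, reusing intermediates.

    Consecutive gaps are bridged by structured uniformization; stiff
    generators (uniformized jump budget above the cap) fall back to one
    eigendecomposition shared by all times, then to dense ``expm``, and
    finally to a flagged propagation error carrying the model so callers
    can treat it as having zero likelihood.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be non-negative and non-decreasing")
    lam = gen.uniformization_rate
    vs = None
    work = lam * times.max() * gen.dim * (gen.n_states + 4)
    if work <= _UNIFORMIZATION_WORK_CAP:
        vs = []
        v = p0.values
        prev = 0.0
        for t in times:
            v = uniformized_action(gen, v, t - prev) if t > prev else v.copy()
            vs.append(v)
            prev = t
    if vs is None and gen.dim <= _EXPM_MAX_DIM:
        vs = _eig_solutions(gen.matrix, p0.values, times)
    if vs is None:
        if gen.dim > _EXPM_MAX_DIM:
            raise PropagationError(
                f"stiffness budget exceeded (lambda*t = {lam * times.max():.3g}, "
                f"dim = {gen.dim})",
                state,
            )
        vs = []
        v = p0.values
        prev = 0.0
        for t in times:
            v = (
                _dense_expm_apply(gen.matrix, v, t - prev, state)
                if t > prev
                else v.copy()
            )
            vs.append(v)
            prev = t
    out = []
    for t, v in zip(times, vs):
        out.append(ProbabilityVector(_check_vector(v, state), t, gen.truncation))
    return out


def _eig_solutions(A, v0, times):
    """CME solutions at all times via eigendecomposition, or None when the
    decomposition is too ill-conditioned to trust."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam, V = np.linalg.eig(A)
            c = np.linalg.solve(V, v0.astype(complex))
    except np.linalg.LinAlgError:
        return None
    sols = []
    for t in times:
        with np.errstate(over="ignore", invalid="ignore"):
            v = (V * np.exp(lam * t)) @ c
        v = v.real if np.iscomplexobj(v) else v
        if (
            not np.all(np.isfinite(v))
            or v.min() < -_NEGATIVITY_TOL
            or v.sum() > 1.0 + 1e-9
        ):
            return None
        sols.append(v)
    return sols


def _dense_expm_apply(A, v, t, state):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = scipy.linalg.expm(A * t) @ v
    except Exception as exc:  # pragma: no cover - defensive
        raise PropagationError(f"expm failed: {exc}", state) from exc
    if not np.all(np.isfinite(out)):
        raise PropagationError("non-finite expm result", state)
    return out


def count_marginal(p: ProbabilityVector, m: int) -> float:
    """Probability of observing ``m`` molecules, summed over gene states."""
    M = p.truncation
    if m < 0:
        raise ValueError("count must be non-negative")
    if m > M:
        warnings.warn(
            f"observation {m} exceeds truncation {M}; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    n = M + 1
    return float(p.values[m::n].sum())


def _count_marginal_vector(p: ProbabilityVector) -> np.ndarray:
    n = p.truncation + 1
    return p.values.reshape(-1, n).sum(axis=0)


def log_likelihood(
    data: SnapshotDataset,
    state: NetworkState,
    truncation: int | None = None,
    leak_tolerance: float = 1e-6,
    warn_on_leak: bool = False,
    validate: bool = True,
) -> float:
    """Log-likelihood of snapshot data under ``state``.

    One CME propagation per distinct acquisition time; cells at a time are
    conditionally i.i.d. so their log count-marginals simply add.  Returns
    ``-inf`` when a propagation fails or any observation lands on zero
    marginal probability.
    """
    M = default_truncation(np.concatenate(data.counts)) if truncation is None else truncation
    try:
        gen = build_generator(state, M, validate=validate)
        p0 = initial_vector(state, M)
        sols = propagate_times(gen, p0, data.times, state)
    except PropagationError:
        return -np.inf
    total = 0.0
    for p, grp in zip(sols, data.counts):
        if warn_on_leak and p.leak() > leak_tolerance:
            warnings.warn(
                f"leaked probability mass {p.leak():.2e} at t={p.time:g} "
                f"exceeds {leak_tolerance:g}; increase truncation",
                RuntimeWarning,
                stacklevel=2,
            )
        marg = _count_marginal_vector(p)
        vals = np.where(grp <= M, marg[np.minimum(grp, M)], 0.0)
        if np.any(vals <= 0.0):
            return -np.inf
        total += float(np.log(vals).sum())
    return total


# ---------------------------------------------------------------------------
# log-rate coordinates: the samplers operate on the log of every rate that
# enters the generator, flattened in a fixed order
# ---------------------------------------------------------------------------


def rate_coordinates(
    state: NetworkState, fixed: Iterable[str] = ()
) -> list:
    """Ordered labels of the free log-rate coordinates of the active model.

    Labels: ``("k", i, j)`` for active ordered pairs, ``("beta", i)`` for
    active states, ``("gamma",)`` — minus any in ``fixed`` (matched on the
    leading name, e.g. ``fixed={"gamma"}``).
    """
    fixed = set(fixed)
    act = active_states(state)
    coords = []
    for i in act:
        for j in act:
            if i != j and "k" not in fixed:
                coords.append(("k", int(i), int(j)))
    if "beta" not in fixed:
        coords.extend(("beta", int(i)) for i in act)
    if "gamma" not in fixed:
        coords.append(("gamma",))
    return coords


def get_log_rates(state: NetworkState, coords: Sequence[tuple]) -> np.ndarray:
    out = np.empty(len(coords))
    r = state.rates
    for n, c in enumerate(coords):
        if c[0] == "k":
            out[n] = r.k[c[1], c[2]]
        elif c[0] == "beta":
            out[n] = r.beta[c[1]]
        else:
            out[n] = r.gamma
    with np.errstate(divide="ignore"):
        return np.log(out)


def set_log_rates(
    state: NetworkState, coords: Sequence[tuple], x: np.ndarray
) -> NetworkState:
    new = state.copy()
    with np.errstate(over="ignore"):
        vals = np.exp(np.asarray(x, dtype=float))
    for n, c in enumerate(coords):
        if c[0] == "k":
            new.rates.k[c[1], c[2]] = vals[n]
        elif c[0] == "beta":
            new.rates.beta[c[1]] = vals[n]
        else:
            new.rates.gamma = vals[n]
    return new


def log_likelihood_gradient(
    data: SnapshotDataset,
    state: NetworkState,
    truncation: int | None = None,
    coords: Sequence[tuple] | None = None,
    rel_step: float = 1e-5,
) -> np.ndarray:
    """Gradient of the log-likelihood w.r.t. the free log-rates.

    Central finite differences with a relative step on each log-rate;
    deterministic for fixed inputs.  Integration error introduced here is
    corrected by the HMC acceptance step, so finite differences do not bias
    the sampler.
    """
    if coords is None:
        coords = rate_coordinates(state)
    x0 = get_log_rates(state, coords)
    center = log_likelihood(data, state, truncation)
    if not np.isfinite(center):
        raise PropagationError("non-finite log-likelihood at gradient center", state)
    g = np.empty(len(coords))
    for n in range(len(coords)):
        h = rel_step * max(1.0, abs(x0[n]))
        for sign in (+1.0, -1.0):
            x = x0.copy()
            x[n] += sign * h
            ll = log_likelihood(data, set_log_rates(state, coords, x), truncation)
            if sign > 0:
                hi = ll
            else:
                lo = ll
        g[n] = (hi - lo) / (2.0 * h)
    return g
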