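"""Trace storage, convergence and efficiency diagnostics, and summaries.

Evaluation follows three axes: accuracy of the learned posterior, burn-in
duration (log-posterior plateau detection), and sample autocorrelation
(integrated autocorrelation time).  For benchmark scoring against a known
ground truth, "convergence" is operationalized as: all active rates
simultaneously within a factor of the truth, sustained for a window of
consecutive iterations (documented artifact criterion).
"""

from __future__ import annotations

import json
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_model import NetworkState, active_states, canonicalize

__all__ = [
    "TraceStore",
    "AcfResult",
    "BurnInResult",
    "autocorrelation",
    "burn_in_iteration",
    "convergence_iteration",
    "posterior_summary",
    "ablation_report",
    "canonical_rate_vector",
]


@dataclass
class TraceStore:
    """Columnar per-iteration record of all sampled quantities."""

    columns: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add(self, **record) -> None:
        if not self.columns:
            for k in record:
                self.columns[k] = []
        if set(record) != set(self.columns):
            raise ValueError("record fields must stay consistent")
        for k, v in record.items():
            self.columns[k].append(v)

    def __len__(self) -> int:
        if not self.columns:
            return 0
        return len(next(iter(self.columns.values())))

    def get(self, name: str) -> np.ndarray:
        return np.asarray(self.columns[name])

    def to_dataframe(self) -> pd.DataFrame:
        out = {}
        for k, vals in self.columns.items():
            if vals and isinstance(vals[0], np.ndarray):
                out[k] = [json.dumps(np.asarray(v).tolist()) for v in vals]
            else:
                out[k] = vals
        return pd.DataFrame(out)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "TraceStore":
        df = pd.read_csv(path)
        store = cls()
        for k in df.columns:
            vals = df[k].tolist()
            if vals and isinstance(vals[0], str) and vals[0].startswith("["):
                vals = [np.array(json.loads(v)) for v in vals]
            store.columns[k] = vals
        return store

    def state_at(self, i: int) -> NetworkState:
        """Rebuild the sampled ``NetworkState`` at iteration ``i``."""
        from .network_model import Rates

        return NetworkState(
            np.asarray(self.columns["loads"][i], dtype=int),
            np.asarray(self.columns["success_probs"][i], dtype=float),
            Rates(
                np.asarray(self.columns["k"][i], dtype=float),
                np.asarray(self.columns["beta"][i], dtype=float),
                float(self.columns["gamma"][i]),
            ),
            int(self.columns["initial_state"][i]),
        )


AcfResult = namedtuple("AcfResult", ["rho", "tau", "degenerate"])
BurnInResult = namedtuple("BurnInResult", ["iteration", "converged"])


def autocorrelation(trace_values, max_lag: int) -> AcfResult:
    """Normalized empirical autocorrelation up to ``max_lag``.

    Also returns the integrated autocorrelation time
    ``tau = 1 + 2 * sum(rho_k)`` with the sum truncated at the first
    non-positive autocorrelation (initial positive sequence rule).
    Constant traces are flagged degenerate with ``rho(lag > 0) = 0``.
    """
    x = np.asarray(trace_values, dtype=float)
    n = x.size
    if n < 2 * max_lag:
        raise ValueError("need at least 2 * max_lag samples")
    x = x - x.mean()
    var = float(x @ x) / n
    rho = np.zeros(max_lag + 1)
    rho[0] = 1.0
    if var <= 0:
        return AcfResult(rho, 1.0, True)
    # FFT-based autocovariance
    m = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f))[: max_lag + 1] / n
    rho = acov / acov[0]
    tau = 1.0
    for k in range(1, max_lag + 1):
        if rho[k] <= 0:
            break
        tau += 2.0 * rho[k]
    return AcfResult(rho, tau, False)


def burn_in_iteration(
    log_posterior, delta: float = 5.0, smooth: int = 25
) -> BurnInResult:
    """First iteration after which the log-posterior stays within
    ``delta`` of its maximum for the remainder of the run.

    The trace is pre-smoothed with a centered moving median of width
    ``smooth`` so that per-iteration sampling noise (which over a long
    run can span more than ``delta`` on its own) does not mask the
    plateau; ``smooth=1`` disables smoothing.
    """
    lp = np.asarray(log_posterior, dtype=float)
    if lp.size == 0:
        raise ValueError("empty trace")
    if smooth > 1 and lp.size > smooth:
        lp = (
            pd.Series(lp)
            .rolling(smooth, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    band = lp.max() - delta
    suffix_min = np.minimum.accumulate(lp[::-1])[::-1]
    ok = suffix_min >= band
    if not ok.any():
        return BurnInResult(lp.size, False)
    return BurnInResult(int(np.argmax(ok)), True)


def canonical_rate_vector(state: NetworkState):
    """Canonical (beta-sorted) active rates: labels and values.

    Labels are ``beta_0..beta_{N-1}`` (ascending), ``k_i_j`` between
    canonical active slots, and ``gamma``.
    """
    canon = canonicalize(state)
    act = active_states(canon)
    labels, values = [], []
    for i, s in enumerate(act):
        labels.append(f"beta_{i}")
        values.append(canon.rates.beta[s])
    for i, si in enumerate(act):
        for j, sj in enumerate(act):
            if i != j:
                labels.append(f"k_{i}_{j}")
                values.append(canon.rates.k[si, sj])
    labels.append("gamma")
    values.append(canon.rates.gamma)
    return labels, np.array(values)


def convergence_iteration(
    trace: TraceStore,
    truth: NetworkState,
    factor: float = 2.0,
    window: int = 100,
    require_mode_n: bool = False,
    skip_rates=(),
) -> int | None:
    """First iteration of a sustained visit to the ground truth.

    An iteration qualifies when the sampled model has the true number of
    states and every canonical active rate lies within ``factor`` of the
    corresponding true rate; convergence is the first iteration from which
    this holds for ``window`` consecutive iterations.  With
    ``require_mode_n`` the running posterior mode over ``N`` — computed
    over the trailing ``max(2 * window, 200)`` iterations, a proxy for the
    post-burn-in posterior — must also equal the true ``N`` by the end of
    the window.  Returns None when the criterion is never met.
    """
    n_iter = len(trace)
    truth_labels, truth_vals = canonical_rate_vector(truth)
    keep = [i for i, lab in enumerate(truth_labels) if lab not in set(skip_rates)]
    truth_vals = truth_vals[keep]
    n_true = truth.N
    ok = np.zeros(n_iter, dtype=bool)
    ns = trace.get("N")
    for i in range(n_iter):
        if ns[i] != n_true:
            continue
        labels, vals = canonical_rate_vector(trace.state_at(i))
        if labels != truth_labels:
            continue
        r = vals[keep] / truth_vals
        ok[i] = bool(np.all((r >= 1.0 / factor) & (r <= factor)))
    if n_iter < window:
        return None
    # first index with `window` consecutive hits
    run = 0
    for i in range(n_iter):
        run = run + 1 if ok[i] else 0
        if run >= window:
            start = i - window + 1
            if require_mode_n:
                tail = max(2 * window, 200)
                seg = ns[max(0, i + 1 - tail) : i + 1]
                counts = np.bincount(seg.astype(int))
                if counts.argmax() != n_true:
                    continue
            return start
    return None


def posterior_summary(
    trace: TraceStore, burn_in: int, min_samples: int = 100
) -> dict:
    """Posterior summaries after burn-in.

    Canonical (beta-sorted) rates are summarized over the samples whose
    ``N`` equals the posterior mode; returns a table of central 95%
    credible intervals, means and medians, plus the posterior pmf of
    ``N``.
    """
    n_iter = len(trace)
    if n_iter - burn_in < min_samples:
        raise ValueError(
            f"only {n_iter - burn_in} post-burn-in samples; need {min_samples}"
        )
    ns = trace.get("N")[burn_in:]
    n_values = np.arange(1, int(ns.max()) + 1)
    pmf = np.array([(ns == v).mean() for v in n_values])
    mode_n = int(n_values[pmf.argmax()])
    rows = {}
    for i in range(burn_in, n_iter):
        if trace.get("N")[i] != mode_n:
            continue
        labels, vals = canonical_rate_vector(trace.state_at(i))
        for lab, v in zip(labels, vals):
            rows.setdefault(lab, []).append(v)
    recs = []
    for lab, vals in rows.items():
        v = np.asarray(vals)
        recs.append(
            {
                "parameter": lab,
                "mean": v.mean(),
                "median": float(np.median(v)),
                "ci_lo": float(np.percentile(v, 2.5)),
                "ci_hi": float(np.percentile(v, 97.5)),
                "n_samples": v.size,
            }
        )
    return {
        "table": pd.DataFrame(recs),
        "n_pmf": dict(zip(n_values.tolist(), pmf.tolist())),
        "mode_n": mode_n,
        "burn_in": burn_in,
    }


def _iact_per_parameter(trace: TraceStore, truth: NetworkState) -> dict:
    """IACT of each canonical rate over iterations at the true N."""
    labels, _ = canonical_rate_vector(truth)
    ns = trace.get("N")
    series = {lab: [] for lab in labels}
    for i in range(len(trace)):
        if ns[i] != truth.N:
            continue
        labs, vals = canonical_rate_vector(trace.state_at(i))
        if labs != labels:
            continue
        for lab, v in zip(labs, vals):
            series[lab].append(v)
    out = {}
    for lab, vals in series.items():
        v = np.asarray(vals, dtype=float)
        if v.size >= 50:
            max_lag = min(v.size // 4, 250)
            out[lab] = autocorrelation(np.log(v), max_lag).tau
        else:
            out[lab] = np.nan
    return out


def ablation_report(
    traces: dict,
    truth: NetworkState,
    factor: float = 2.0,
    window: int = 100,
    plot_dir=None,
) -> pd.DataFrame:
    """Side-by-side comparison of sampler variants on one dataset.

    ``traces`` maps method name (e.g. full / fixed_proposals / no_pt) to
    its cold-chain trace; reports burn-in, per-parameter integrated
    autocorrelation time, final log-posterior and whether the ground
    truth was reached under the sustained-factor criterion.
    """
    rows = []
    for name, trace in traces.items():
        lp = trace.get("log_joint").astype(float)
        bi = burn_in_iteration(lp)
        conv = convergence_iteration(trace, truth, factor=factor, window=window)
        iact = _iact_per_parameter(trace, truth)
        finite_iact = [v for v in iact.values() if np.isfinite(v)]
        rows.append(
            {
                "method": name,
                "burn_in": bi.iteration,
                "plateau_found": bi.converged,
                "convergence_iteration": conv,
                "recovered_truth": conv is not None,
                "mean_iact": float(np.mean(finite_iact)) if finite_iact else np.nan,
                "final_log_posterior": float(lp[-1]),
                **{f"iact_{k}": v for k, v in iact.items()},
            }
        )
    df = pd.DataFrame(rows)
    if plot_dir is not None:
        _render_ablation_plots(traces, truth, plot_dir)
    return df


def _render_ablation_plots(traces: dict, truth: NetworkState, plot_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    plot_dir = Path(plot_dir)
    plot_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, trace in traces.items():
        ax.plot(trace.get("log_joint").astype(float), label=name, lw=0.8)
    ax.set_xlabel("iteration")
    ax.set_ylabel("log joint")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plot_dir / "log_posterior.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, trace in traces.items():
        lp = trace.get("log_joint").astype(float)
        lp = lp[np.isfinite(lp)]
        if lp.size >= 40:
            acf = autocorrelation(lp, max_lag=min(lp.size // 4, 200))
            ax.plot(acf.rho, label=name, lw=0.8)
    ax.set_xlabel("lag")
    ax.set_ylabel("autocorrelation of log joint")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plot_dir / "autocorrelation.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, trace in traces.items():
        ax.plot(trace.get("gamma").astype(float), label=name, lw=0.8)
    ax.axhline(truth.rates.gamma, color="c", ls="--", label="truth")
    ax.set_xlabel("iteration")
    ax.set_ylabel("gamma")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plot_dir / "gamma_trace.png", dpi=120)
    plt.close(fig)
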