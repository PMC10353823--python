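"""Structured uniformization kernel for the truncated CME generator.

The generator over (active gene state, count) space is block tridiagonal
(production/degradation within a state) plus diagonal coupling blocks
(gene switching), so its action on a vector costs O(N * (M+1) * (N + 4))
instead of a dense matvec.  The kernel evaluates ``exp(A * dt) v`` by the
uniformized Poisson-jump sum, sub-stepping long intervals so the Poisson
weights never underflow.  Compiled with numba when available; a pure
numpy implementation provides the fallback.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


#: per-substep cap on the uniformized jump parameter (Poisson weights stay
#: representable and the term count bounded)
SUBSTEP_X = 400.0


def _apply_generator_np(beta, k, kout, gamma, v, out):
    """out <- A v for the structured generator; v, out are (N, M+1)."""
    N, n = v.shape
    m = np.arange(n)
    for a in range(N):
        acc = -(beta[a] + gamma * m + kout[a]) * v[a]
        acc[1:] += beta[a] * v[a, :-1]
        acc[:-1] += gamma * m[1:] * v[a, 1:]
        for b in range(N):
            if b != a:
                acc += k[b, a] * v[b]
        out[a] = acc
    return out


def _unif_apply_np(beta, k, kout, gamma, v, dt, lam):
    """exp(A dt) v via uniformization with sub-stepping; v is (N, M+1)."""
    x_total = lam * dt
    nsub = int(x_total / SUBSTEP_X) + 1
    x = lam * dt / nsub
    scratch = np.empty_like(v)
    for _ in range(nsub):
        coef = np.exp(-x)
        res = coef * v
        term = v.copy()
        acc = coef
        kmax = int(x + 12.0 * np.sqrt(x + 1.0) + 20)
        for kk in range(1, kmax + 1):
            _apply_generator_np(beta, k, kout, gamma, term, scratch)
            term = term + scratch / lam
            coef *= x / kk
            res = res + coef * term
            acc += coef
            if acc > 1.0 - 1e-14 and kk > x:
                break
        v = res
    return v


if HAVE_NUMBA:

    @njit(cache=False, fastmath=True)
    def _apply_generator_nb(beta, k, kout, gamma, v, out, inv_lam):
        """out <- (A v) / lam for the structured generator."""
        N, n = v.shape
        M = n - 1
        for a in range(N):
            ba = beta[a]
            for m in range(n):
                acc = -(ba + gamma * m + kout[a]) * v[a, m]
                if m >= 1:
                    acc += ba * v[a, m - 1]
                if m < M:
                    acc += gamma * (m + 1) * v[a, m + 1]
                for b in range(N):
                    if b != a:
                        acc += k[b, a] * v[b, m]
                out[a, m] = acc * inv_lam

    @njit(cache=False, fastmath=True)
    def _unif_apply_nb(beta, k, kout, gamma, v, dt, lam, substep_x):
        x_total = lam * dt
        nsub = int(x_total / substep_x) + 1
        x = lam * dt / nsub
        scratch = np.empty_like(v)
        N, n = v.shape
        inv_lam = 1.0 / lam
        for _ in range(nsub):
            coef = np.exp(-x)
            res = coef * v
            term = v.copy()
            acc = coef
            kmax = int(x + 12.0 * np.sqrt(x + 1.0) + 20)
            for kk in range(1, kmax + 1):
                _apply_generator_nb(beta, k, kout, gamma, term, scratch, inv_lam)
                coef *= x / kk
                for a in range(N):
                    for m in range(n):
                        t = term[a, m] + scratch[a, m]
                        term[a, m] = t
                        res[a, m] = res[a, m] + coef * t
                acc += coef
                if acc > 1.0 - 1e-14 and kk > x:
                    break
            v = res
        return v


def uniformized_action(gen, v, dt):
    """``exp(A dt) v`` using the structured kernel of ``gen``.

    ``gen`` is a GeneratorMatrix carrying its block structure; ``v`` is
    the flat composite-state vector.
    """
    beta = gen.beta_active
    k = gen.k_active
    gamma = gen.gamma
    N = beta.shape[0]
    n = gen.truncation + 1
    kout = np.zeros(N)
    for a in range(N):
        for b in range(N):
            if b != a:
                kout[a] += k[a, b]
    lam = float(np.max(beta + gamma * gen.truncation + kout)) * (1.0 + 1e-3)
    v2 = np.ascontiguousarray(v.reshape(N, n), dtype=np.float64)
    args = (
        np.ascontiguousarray(beta, dtype=np.float64),
        np.ascontiguousarray(k, dtype=np.float64),
        kout,
        float(gamma),
        v2,
        float(dt),
        lam,
    )
    if HAVE_NUMBA:
        out = _unif_apply_nb(*args, SUBSTEP_X)
    else:
        out = _unif_apply_np(*args)
    return np.asarray(out).reshape(-1)
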