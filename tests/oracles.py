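"""Independent reference implementations used only to check the package."""

from __future__ import annotations

import numpy as np
from scipy import stats


def blahut_arimoto(Q: np.ndarray, tol: float = 1e-12, max_iter: int = 100000):
    """Capacity of a discrete memoryless channel by the Blahut-Arimoto
    fixed point.  Returns (capacity_bits, p_opt)."""
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    p = np.full(n, 1.0 / n)
    logQ = np.where(Q > 0, np.log2(np.maximum(Q, 1e-300)), 0.0)
    for _ in range(max_iter):
        P = p @ Q
        # D(Q_u || P) per input
        d = (Q * (logQ - np.log2(np.maximum(P, 1e-300))[None, :])).sum(axis=1)
        # capacity bounds: max_u d_u upper, sum p 2^d lower
        c = p * np.exp2(d)
        new_p = c / c.sum()
        if np.max(d) - np.log2(c.sum()) < tol:
            p = new_p
            break
        p = new_p
    P = p @ Q
    d = (Q * (logQ - np.log2(np.maximum(P, 1e-300))[None, :])).sum(axis=1)
    terms = p * d
    return float(terms.sum()), p


def exact_poisson_channel_mi(means: np.ndarray, p_u: np.ndarray) -> float:
    """MI in bits of a Poisson channel by direct pmf summation (no binning)."""
    means = np.asarray(means, dtype=float)
    p_u = np.asarray(p_u, dtype=float)
    hi = int(stats.poisson(means.max()).ppf(1 - 1e-12)) + 2
    ks = np.arange(hi)
    Q = np.vstack([stats.poisson(m).pmf(ks) for m in means])
    P = p_u @ Q
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = Q * np.log2(Q / np.maximum(P, 1e-300)[None, :])
    terms[Q <= 0] = 0.0
    return float(p_u @ terms.sum(axis=1))


def mean_field_trajectory(rhs, y0, t_end, n=20000):
    """Fixed-step RK4 integration, independent of scipy's solvers."""
    y = np.asarray(y0, dtype=float).copy()
    h = t_end / n
    t = 0.0
    for _ in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y
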