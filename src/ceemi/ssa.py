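"""Gillespie stochastic simulation kernel (numba-compiled).

The direct SSA over mass-action reactions with at most bimolecular
propensities.  Networks are compiled down to three arrays: per-reaction
rate coefficients (dose multipliers already folded in), reactant species
indices (padded with -1), and the integer stoichiometry matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_ssa"]


@njit(cache=False)
def _ssa_kernel(x0s, t_end, coeffs, r_idx, stoich, seed):  # pragma: no cover
    np.random.seed(seed)
    n_reps = x0s.shape[0]
    n_rxn = coeffs.shape[0]
    n_sp = x0s.shape[1]
    out = np.empty((n_reps, n_sp), dtype=np.int64)
    props = np.empty(n_rxn)
    for rep in range(n_reps):
        x = x0s[rep].copy()
        t = 0.0
        while True:
            a0 = 0.0
            for r in range(n_rxn):
                a = coeffs[r]
                if r_idx[r, 0] >= 0:
                    a *= x[r_idx[r, 0]]
                if r_idx[r, 1] >= 0:
                    a *= x[r_idx[r, 1]]
                props[r] = a
                a0 += a
            if a0 <= 0.0:
                break
            t += -np.log(np.random.random()) / a0
            if t > t_end:
                break
            u = np.random.random() * a0
            acc = 0.0
            chosen = n_rxn - 1
            for r in range(n_rxn):
                acc += props[r]
                if u <= acc:
                    chosen = r
                    break
            for s in range(n_sp):
                x[s] += stoich[chosen, s]
        out[rep] = x
    return out


def run_ssa(
    x0: np.ndarray,
    t_end: float,
    coeffs: np.ndarray,
    reactant_idx: np.ndarray,
    stoich: np.ndarray,
    n_reps: int,
    seed: int,
) -> np.ndarray:
    """Run ``n_reps`` exact SSA trajectories; return final states.

    ``x0`` may be one initial state (replicated across reps) or a matrix
    of per-rep initial states with ``n_reps`` rows.  The other parameters
    are the compiled network arrays: ``coeffs[r]`` the rate coefficient
    (with any dose factor included), ``reactant_idx[r]`` up to two
    reactant species indices (-1 padding), ``stoich[r, s]`` the net
    copy-number change of species ``s`` by reaction ``r``.  Reproducible
    for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    x0s = np.asarray(x0, dtype=np.int64)
    if x0s.ndim == 1:
        x0s = np.repeat(x0s[None, :], n_reps, axis=0)
    elif x0s.shape[0] != n_reps:
        raise ValueError("x0 matrix must have n_reps rows")
    return _ssa_kernel(
        np.ascontiguousarray(x0s),
        float(t_end),
        np.asarray(coeffs, dtype=np.float64),
        np.asarray(reactant_idx, dtype=np.int64),
        np.asarray(stoich, dtype=np.int64),
        int(seed) % (2**32),
    )
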