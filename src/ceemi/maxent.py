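"""Maximum-entropy inference of cell-state heterogeneity.

Given single-cell snapshot data per experimental condition (dose, time),
the population distribution of biochemical parameters p(theta) is taken
to be the maximum-entropy distribution reproducing decile constraints:
for each condition a gamma distribution is fitted to the observed
single-cell histogram, its ten equal-mass percentile windows become
constraints with target fraction R_em = 0.1, and the model-predicted
window mass is psi_em(theta), the integral of the cell-specific gamma
response over the window.  The entropy-maximizing density is the
Gibbs-Boltzmann form

    p(theta) = exp(-sum_em lambda_em psi_em(theta)) / Omega

restricted to a parameter box (uniform in log10 rates).  Lagrange
multipliers are tuned by ADAM on the dual gradient R_em - <psi_em>,
with the ensemble average estimated by parallel Metropolis chains.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special

from .info_core import ResponseModel, ValidationError

__all__ = [
    "ConstraintSet",
    "ParameterBox",
    "MCMCResult",
    "FitResult",
    "build_percentile_constraints",
    "predicted_window_mass",
    "window_masses",
    "gibbs_log_weight",
    "gibbs_density",
    "mcmc_sample",
    "fit_lagrange_multipliers",
    "gamma_window_mass_batch",
]


# --------------------------------------------------------------------------
# constraints
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintSet:
    """Percentile-window constraints {R_em, (l_em, u_em)} per condition."""

    conditions: tuple[str, ...]
    edges: dict  # condition -> array of window edges, len n_windows + 1
    targets: dict  # condition -> array of target fractions

    def __post_init__(self) -> None:
        for cond in self.conditions:
            e = np.asarray(self.edges[cond], dtype=float)
            t = np.asarray(self.targets[cond], dtype=float)
            if len(e) != len(t) + 1:
                raise ValidationError("edges/targets length mismatch")
            if np.any(np.diff(e) <= 0):
                raise ValidationError("window edges must be increasing")
            if abs(t.sum() - 1.0) > 1e-9:
                raise ValidationError("window targets must sum to 1")

    @property
    def n_constraints(self) -> int:
        return sum(len(self.targets[c]) for c in self.conditions)

    def flat_targets(self) -> np.ndarray:
        return np.concatenate([np.asarray(self.targets[c]) for c in self.conditions])

    def to_json(self) -> str:
        return json.dumps(
            {
                "conditions": list(self.conditions),
                "edges": {c: list(map(float, self.edges[c])) for c in self.conditions},
                "targets": {
                    c: list(map(float, self.targets[c])) for c in self.conditions
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConstraintSet":
        d = json.loads(text)
        return cls(
            tuple(d["conditions"]),
            {c: np.asarray(v) for c, v in d["edges"].items()},
            {c: np.asarray(v) for c, v in d["targets"].items()},
        )


def build_percentile_constraints(
    samples_by_condition: dict, n_windows: int = 10, min_samples: int = 50
) -> ConstraintSet:
    """Decile constraints from snapshot data: gamma fit, equal-mass windows.

    Per condition a gamma distribution is moment-matched to the samples;
    window edges sit at its quantiles (outer edges at 0 and +inf) so the
    fitted distribution assigns exactly ``1/n_windows`` mass per window.
    """
    if n_windows < 1:
        raise ValidationError("n_windows must be >= 1")
    edges, targets = {}, {}
    for cond, samples in samples_by_condition.items():
        x = np.asarray(samples, dtype=float)
        if len(x) < min_samples:
            raise ValidationError(
                f"condition {cond!r}: need >= {min_samples} samples, got {len(x)}"
            )
        mean = float(x.mean())
        var = float(x.var(ddof=1))
        if var <= 0 or mean <= 0:
            raise ValidationError(f"condition {cond!r}: degenerate sample moments")
        shape = mean**2 / var
        scale = var / mean
        q = np.linspace(0, 1, n_windows + 1)[1:-1]
        inner = scale * special.gammaincinv(shape, q)
        edges[cond] = np.concatenate([[0.0], inner, [np.inf]])
        targets[cond] = np.full(n_windows, 1.0 / n_windows)
    conditions = tuple(samples_by_condition.keys())
    return ConstraintSet(conditions, edges, targets)


def predicted_window_mass(
    model: ResponseModel, lower: float, upper: float
) -> float:
    """psi_em(theta): response mass in (lower, upper] under the model."""
    hi = 1.0 if np.isinf(upper) else float(model.cdf(upper))
    lo = 0.0 if lower <= 0 and not model.is_discrete else float(model.cdf(lower))
    if lower < 0:
        lo = 0.0
    return float(np.clip(hi - lo, 0.0, 1.0))


def window_masses(model: ResponseModel, edges: np.ndarray) -> np.ndarray:
    """All window masses of a condition at once; sums to ~1 over a partition."""
    edges = np.asarray(edges, dtype=float)
    cdf = np.empty(len(edges))
    finite = np.isfinite(edges)
    cdf[finite] = model.cdf(edges[finite])
    cdf[~finite] = 1.0
    if not model.is_discrete:
        cdf[edges <= 0] = 0.0
    return np.clip(np.diff(cdf), 0.0, 1.0)


def gamma_window_mass_batch(
    means: np.ndarray, variances: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Vectorized gamma window masses for a batch of (mean, variance) cells.

    Returns an (n_batch, n_windows) array.  Used by fast psi evaluators
    where the forward model yields moments analytically.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    shape = means**2 / variances
    scale = variances / means
    edges = np.asarray(edges, dtype=float)
    z = edges[None, :] / scale[:, None]
    cdf = np.empty((len(means), len(edges)))
    finite = np.isfinite(edges)
    cdf[:, finite] = special.gammainc(shape[:, None], z[:, finite])
    cdf[:, ~finite] = 1.0
    cdf[:, edges <= 0] = 0.0
    return np.clip(np.diff(cdf, axis=1), 0.0, 1.0)


# --------------------------------------------------------------------------
# parameter box and Gibbs density
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterBox:
    """Per-parameter bounds, by convention in log10 space."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if len(lo) != len(self.names) or len(hi) != len(self.names):
            raise ValidationError("bounds length must match names")
        if np.any(lo >= hi):
            raise ValidationError("lower bounds must be < upper bounds")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def ndim(self) -> int:
        return len(self.names)

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lower) & (theta <= self.upper), axis=1)

    def sample_uniform(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.ndim))


PsiFn = Callable[[np.ndarray], np.ndarray]


def gibbs_log_weight(psi: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log of the unnormalized Gibbs-Boltzmann weight exp(-psi . lambda)."""
    return -np.atleast_2d(psi) @ np.asarray(lam, dtype=float)


def gibbs_density(
    theta: np.ndarray, lam: np.ndarray, psi_fn: PsiFn, box: ParameterBox
) -> np.ndarray:
    """Unnormalized maxent weight; zero outside the parameter box."""
    theta = np.atleast_2d(theta)
    w = np.zeros(len(theta))
    inside = box.contains(theta)
    if inside.any():
        w[inside] = np.exp(gibbs_log_weight(psi_fn(theta[inside]), lam))
    return w


# --------------------------------------------------------------------------
# MCMC
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCResult:
    thetas: np.ndarray  # kept samples, (n_kept, ndim)
    psis: np.ndarray  # psi at kept samples, (n_kept, M)
    psi_mean: np.ndarray
    acceptance_rate: float
    meta: dict = field(default_factory=dict)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect proposals into the box (step <= 10% width: one pass each side)."""
    x = np.where(x > hi, 2 * hi - x, x)
    x = np.where(x < lo, 2 * lo - x, x)
    return np.clip(x, lo, hi)


def mcmc_sample(
    lam: np.ndarray,
    psi_fn: PsiFn,
    box: ParameterBox,
    n_chains: int = 20,
    n_steps: int = 2000,
    burn_in: int = 1000,
    thin: int = 50,
    seed: int = 0,
    init: np.ndarray | None = None,
    max_coords: int = 5,
    step_frac: float = 0.1,
) -> MCMCResult:
    """Parallel Metropolis sampling of the Gibbs density.

    Each step perturbs between 1 and ``max_coords`` coordinates per chain
    by uniform steps of at most ``step_frac`` of each coordinate's box
    width, reflecting at the box edges.  Samples are stored every ``thin``
    steps after ``burn_in``; all chains propose/evaluate in a single batch.
    """
    if n_steps <= burn_in:
        raise ValidationError("n_steps must exceed burn_in")
    lam = np.asarray(lam, dtype=float)
    rng = np.random.default_rng(seed)
    d = box.ndim
    if init is None:
        x = box.sample_uniform(rng, n_chains)
    else:
        x = np.array(init, dtype=float).reshape(n_chains, d)
    psi_x = psi_fn(x)
    logw = -(psi_x @ lam)
    step = step_frac * box.width

    kept_t, kept_p = [], []
    n_acc = 0
    k_coords = np.minimum(max_coords, d)
    for it in range(n_steps):
        k = rng.integers(1, k_coords + 1, size=n_chains)
        ranks = np.argsort(rng.random((n_chains, d)), axis=1).argsort(axis=1)
        mask = ranks < k[:, None]
        delta = rng.uniform(-1.0, 1.0, size=(n_chains, d)) * step
        prop = _reflect(x + np.where(mask, delta, 0.0), box.lower, box.upper)
        psi_p = psi_fn(prop)
        logw_p = -(psi_p @ lam)
        accept = np.log(rng.random(n_chains)) < (logw_p - logw)
        x[accept] = prop[accept]
        psi_x[accept] = psi_p[accept]
        logw[accept] = logw_p[accept]
        n_acc += int(accept.sum())
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept_t.append(x.copy())
            kept_p.append(psi_x.copy())

    acc_rate = n_acc / (n_steps * n_chains)
    if acc_rate < 0.01:
        warnings.warn(
            f"MCMC acceptance rate {acc_rate:.3%} below 1%", RuntimeWarning
        )
    thetas = np.concatenate(kept_t, axis=0)
    psis = np.concatenate(kept_p, axis=0)
    return MCMCResult(
        thetas,
        psis,
        psis.mean(axis=0),
        acc_rate,
        meta={"seed": seed, "n_chains": n_chains, "n_steps": n_steps,
              "burn_in": burn_in, "thin": thin},
    )


# --------------------------------------------------------------------------
# Lagrange-multiplier fitting (ADAM on the dual gradient)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    lam: np.ndarray
    error_trace: np.ndarray
    ensemble: MCMCResult
    converged: bool
    n_iterations: int
    message: str = ""


def fit_lagrange_multipliers(
    constraints: ConstraintSet,
    psi_fn: PsiFn,
    box: ParameterBox,
    stop_tol: float = 0.05,
    max_iterations: int = 60,
    adam_step: float = 0.1,
    adam_beta1: float = 0.8,
    adam_beta2: float = 0.999,
    patience: int = 15,
    seed: int = 0,
    mcmc_kwargs: dict | None = None,
) -> FitResult:
    """Tune lambda so the maxent ensemble reproduces the window targets.

    Minimizes the dual L = log Omega + sum lambda_m R_m whose gradient is
    R_m - <psi_m>; the ensemble average comes from ``mcmc_sample`` at the
    current lambda, with chains warm-started from the previous ensemble.
    Stops when the mean absolute relative constraint error reaches
    ``stop_tol``.
    """
    mcmc_kwargs = dict(mcmc_kwargs or {})
    n_chains = mcmc_kwargs.pop("n_chains", 20)
    R = constraints.flat_targets()
    M = len(R)
    lam = np.zeros(M)
    m = np.zeros(M)
    v = np.zeros(M)
    rng = np.random.default_rng(seed)
    init = None
    trace = []
    best_err = np.inf
    best_iter = 0
    result = None
    converged = False
    for it in range(1, max_iterations + 1):
        result = mcmc_sample(
            lam, psi_fn, box, n_chains=n_chains,
            seed=int(rng.integers(2**31)), init=init, **mcmc_kwargs,
        )
        err = float(np.mean(np.abs(R - result.psi_mean) / R))
        trace.append(err)
        if err < best_err - 1e-12:
            best_err, best_iter = err, it
        if err <= stop_tol:
            converged = True
            break
        if it - best_iter >= patience:
            break
        g = R - result.psi_mean
        m = adam_beta1 * m + (1 - adam_beta1) * g
        v = adam_beta2 * v + (1 - adam_beta2) * g**2
        m_hat = m / (1 - adam_beta1**it)
        v_hat = v / (1 - adam_beta2**it)
        lam = lam - adam_step * m_hat / (np.sqrt(v_hat) + 1e-8)
        idx = rng.integers(len(result.thetas), size=n_chains)
        init = result.thetas[idx]
    message = "" if converged else (
        f"stopped after {len(trace)} iterations; best error {best_err:.4f}"
    )
    return FitResult(lam, np.asarray(trace), result, converged, len(trace), message)
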