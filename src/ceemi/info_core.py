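"""Discrete-channel information theory for dose-response data.

A signaling network is treated as a noisy channel from a finite set of
ligand doses (the input ``u``) to a binned intracellular abundance (the
output ``x``).  Per-dose responses are parametric (gamma, Poisson or
negative binomial, the families that describe protein/mRNA copy-number
statistics well), discretized onto a common constant-width bin grid, and
summarized by

* the cell-state-agnostic mutual information ``I_CSA`` of the pooled
  population channel,
* the cell-state-dependent mutual information ``I(theta)`` of one cell's
  conditional channel,
* their population average, the conditional mutual information ``I_Cee``,
* channel capacities of either objective, maximized over the input simplex.

All information quantities are in bits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "InputDistribution",
    "ResponseModel",
    "BinnedChannel",
    "PopulationEnsemble",
    "DegenerateDistributionError",
    "ValidationError",
    "discretize_responses",
    "pooled_channel",
    "mutual_information",
    "cell_specific_mi",
    "conditional_mi",
    "cell_state_agnostic_mi",
    "interaction_information",
    "channel_capacity",
    "maximize_over_inputs",
    "CapacityResult",
]

_LOG2_E = 1.0 / math.log(2.0)
_EPS = 1e-300


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class DegenerateDistributionError(ValidationError):
    """Raised when a response distribution has (numerically) zero spread."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InputDistribution:
    """Discrete probability distribution over a finite ligand-dose grid."""

    doses: tuple[float, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if doses.ndim != 1 or probs.ndim != 1 or len(doses) != len(probs):
            raise ValidationError("doses and probs must be 1-D and equal length")
        if len(doses) == 0:
            raise ValidationError("empty input distribution")
        if np.any(np.diff(doses) <= 0):
            raise ValidationError("doses must be strictly increasing")
        if np.any(probs < 0):
            raise ValidationError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValidationError(f"probabilities sum to {probs.sum()!r}, not 1")
        object.__setattr__(self, "doses", tuple(float(d) for d in doses))
        object.__setattr__(self, "probs", tuple(float(p) for p in probs))

    @classmethod
    def uniform(cls, doses: Sequence[float]) -> "InputDistribution":
        n = len(doses)
        return cls(tuple(doses), tuple([1.0 / n] * n))

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    def entropy(self) -> float:
        p = self.p
        nz = p > 0
        return float(-(p[nz] * np.log2(p[nz])).sum())

    def to_json(self) -> str:
        return json.dumps({"doses": list(self.doses), "probs": list(self.probs)})

    @classmethod
    def from_json(cls, text: str) -> "InputDistribution":
        d = json.loads(text)
        return cls(tuple(d["doses"]), tuple(d["probs"]))


@dataclass(frozen=True)
class ResponseModel:
    """Parametric dose-conditioned response distribution p(x | u, theta).

    ``family`` is one of ``gamma``, ``poisson``, ``negative_binomial``;
    the model is parameterized by its first two moments.  For the gamma
    family shape = mean^2/variance and scale = variance/mean; a negative
    binomial with variance within 1e-9*mean of its mean degrades gracefully
    to a Poisson.
    """

    family: str
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "poisson", "negative_binomial"):
            raise ValidationError(f"unknown family {self.family!r}")
        if not (math.isfinite(self.mean) and math.isfinite(self.variance)):
            raise ValidationError("non-finite response moments")
        if self.family == "gamma":
            if self.mean <= 0 or self.variance <= 0:
                raise ValidationError("gamma family requires mean, variance > 0")
        elif self.family == "poisson":
            if self.mean < 0:
                raise ValidationError("poisson mean must be >= 0")
            object.__setattr__(self, "variance", float(self.mean))
        else:  # negative binomial
            if self.mean <= 0:
                raise ValidationError("negative binomial mean must be > 0")
            if self.variance < self.mean * (1 - 1e-12):
                raise ValidationError(
                    "negative binomial requires variance >= mean "
                    f"(got mean={self.mean}, variance={self.variance})"
                )

    @classmethod
    def gamma(cls, mean: float, variance: float) -> "ResponseModel":
        return cls("gamma", float(mean), float(variance))

    @classmethod
    def poisson(cls, mean: float) -> "ResponseModel":
        return cls("poisson", float(mean), float(mean))

    @classmethod
    def negative_binomial(cls, mean: float, variance: float) -> "ResponseModel":
        return cls("negative_binomial", float(mean), float(variance))

    @property
    def is_discrete(self) -> bool:
        return self.family in ("poisson", "negative_binomial")

    @property
    def dist(self):
        """Frozen scipy distribution with the model's moments."""
        if self.family == "gamma":
            shape = self.mean**2 / self.variance
            scale = self.variance / self.mean
            return stats.gamma(shape, scale=scale)
        if self.family == "poisson":
            return stats.poisson(self.mean)
        overdisp = self.variance - self.mean
        if overdisp < 1e-9 * self.mean:
            return stats.poisson(self.mean)
        size = self.mean**2 / overdisp
        prob = size / (size + self.mean)
        return stats.nbinom(size, prob)

    def cdf(self, x) -> np.ndarray:
        return self.dist.cdf(x)

    def ppf(self, q) -> np.ndarray:
        return self.dist.ppf(q)

    def iqr(self) -> float:
        d = self.dist
        return float(d.ppf(0.75) - d.ppf(0.25))


@dataclass(frozen=True)
class BinnedChannel:
    """A dose x bin conditional probability matrix on a constant-width grid.

    ``row_mass`` holds the captured (pre-renormalization) probability mass
    per dose; rows of ``cond_probs`` are renormalized to sum to 1.
    """

    bin_edges: np.ndarray
    cond_probs: np.ndarray
    row_mass: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.atleast_2d(np.asarray(self.cond_probs, dtype=float))
        if probs.shape[1] != len(edges) - 1:
            raise ValidationError("cond_probs width must equal len(bin_edges)-1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "cond_probs", probs)
        object.__setattr__(self, "row_mass", np.asarray(self.row_mass, dtype=float))

    @property
    def n_doses(self) -> int:
        return self.cond_probs.shape[0]

    @property
    def n_bins(self) -> int:
        return self.cond_probs.shape[1]

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_edges": self.bin_edges.tolist(),
                "cond_probs": self.cond_probs.tolist(),
                "row_mass": self.row_mass.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BinnedChannel":
        d = json.loads(text)
        return cls(
            np.asarray(d["bin_edges"]),
            np.asarray(d["cond_probs"]),
            np.asarray(d["row_mass"]),
        )


@dataclass(frozen=True)
class PopulationEnsemble:
    """Weighted sample {theta_i} representing the cell-state distribution p(theta)."""

    thetas: tuple
    weights: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        thetas = tuple(self.thetas)
        if len(thetas) == 0:
            raise ValidationError("empty ensemble")
        if self.weights is None:
            w = np.full(len(thetas), 1.0 / len(thetas))
        else:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(thetas):
                raise ValidationError("weights length mismatch")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValidationError("weights must be non-negative, not all zero")
            w = w / w.sum()
        object.__setattr__(self, "thetas", thetas)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.thetas)


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------


def _validate_models(models: Sequence[ResponseModel]) -> None:
    if len(models) == 0:
        raise ValidationError("no response models supplied")
    for m in models:
        if not isinstance(m, ResponseModel):
            raise ValidationError(f"expected ResponseModel, got {type(m)!r}")


def _grid_from_models(
    models: Sequence[ResponseModel], bin_frac: float, coverage: float
) -> np.ndarray:
    """Constant-width bin edges covering >= ``coverage`` of every model.

    Bin width is ``bin_frac`` times the smallest interquartile range; the
    support is the union of per-model central ``coverage`` intervals,
    anchored at the global lower truncation point (widened by half a count
    for discrete families so boundary integers fall strictly inside).
    """
    if not (0 < bin_frac < 1):
        raise ValidationError("bin_frac must be in (0, 1)")
    if not (0.5 < coverage < 1):
        raise ValidationError("coverage must be in (0.5, 1)")
    iqrs = np.array([m.iqr() for m in models])
    means = np.array([abs(m.mean) for m in models])
    floor = np.maximum(1e-9 * means, 1e-300)
    if np.any(iqrs <= floor):
        raise DegenerateDistributionError(
            "a response distribution has numerically zero interquartile range"
        )
    width = bin_frac * float(iqrs.min())
    alpha = 1.0 - coverage
    lo = min(float(m.ppf(alpha / 2)) for m in models)
    hi = max(float(m.ppf(1 - alpha / 2)) for m in models)
    if any(m.is_discrete for m in models):
        lo -= 0.5
        hi += 0.5
    n_bins = max(1, int(math.ceil((hi - lo) / width)))
    return lo + width * np.arange(n_bins + 1)


def _rows_on_grid(
    models: Sequence[ResponseModel], edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    cdfs = np.vstack([m.cdf(edges) for m in models])
    raw = np.diff(cdfs, axis=1)
    np.clip(raw, 0.0, None, out=raw)
    mass = raw.sum(axis=1)
    return raw / mass[:, None], mass


def discretize_responses(
    models: Sequence[ResponseModel],
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
) -> BinnedChannel:
    """Bin per-dose response models onto a shared constant-width grid.

    The bin width equals ``bin_frac`` (default 5%) of the smallest
    interquartile range across the dose-conditioned models, and the
    truncated support captures at least ``coverage`` (default 99.95%) of
    every model's mass before rows are renormalized.
    """
    _validate_models(models)
    edges = _grid_from_models(models, bin_frac, coverage)
    rows, mass = _rows_on_grid(models, edges)
    return BinnedChannel(edges, rows, mass)


def pooled_channel(
    per_cell_models: Sequence[Sequence[ResponseModel]],
    weights: np.ndarray | None = None,
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
) -> BinnedChannel:
    """Mixture channel p(x|u) = sum_i w_i p(x|u, theta_i) on a common grid.

    The grid is built from all cells' dose-conditioned models jointly, so
    every component is resolved on the same bins before mixing.
    """
    if len(per_cell_models) == 0:
        raise ValidationError("empty ensemble")
    n_doses = len(per_cell_models[0])
    if any(len(ms) != n_doses for ms in per_cell_models):
        raise ValidationError("every cell must have a model per dose")
    if weights is None:
        weights = np.full(len(per_cell_models), 1.0 / len(per_cell_models))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    flat = [m for ms in per_cell_models for m in ms]
    _validate_models(flat)
    edges = _grid_from_models(flat, bin_frac, coverage)
    mix = np.zeros((n_doses, len(edges) - 1))
    mass = np.zeros(n_doses)
    for w, ms in zip(weights, per_cell_models):
        rows, m = _rows_on_grid(ms, edges)
        mix += w * rows
        mass += w * m
    mix /= mix.sum(axis=1)[:, None]
    return BinnedChannel(edges, mix, mass)


# --------------------------------------------------------------------------
# mutual information
# --------------------------------------------------------------------------


def _mi_bits(Q: np.ndarray, p: np.ndarray) -> float:
    """MI in bits of a row-stochastic channel Q under input weights p.

    Terms with p(x|u) = 0 or p(u) = 0 contribute zero; logs are guarded by
    a 1e-300 floor inside the logarithm only.
    """
    P = p @ Q
    ratio = Q / np.maximum(P, _EPS)[None, :]
    terms = Q * np.log2(np.maximum(ratio, _EPS))
    terms[Q <= 0] = 0.0
    return float(p @ terms.sum(axis=1))


def _mi_grad_bits(Q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """d MI / d p_u (unconstrained): D(Q_u || P) - 1/ln 2."""
    P = p @ Q
    ratio = Q / np.maximum(P, _EPS)[None, :]
    terms = Q * np.log2(np.maximum(ratio, _EPS))
    terms[Q <= 0] = 0.0
    return terms.sum(axis=1) - _LOG2_E


def mutual_information(channel: BinnedChannel, p_u: InputDistribution) -> float:
    """Mutual information (bits) between dose and binned response."""
    if channel.n_doses != len(p_u.doses):
        raise ValidationError(
            f"channel has {channel.n_doses} doses but p_u has {len(p_u.doses)}"
        )
    return _mi_bits(channel.cond_probs, p_u.p)


def cell_specific_mi(
    theta_models: Sequence[ResponseModel],
    p_u: InputDistribution,
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
) -> float:
    """I(theta): MI of one cell's conditional channel p(x | u, theta)."""
    channel = discretize_responses(theta_models, bin_frac, coverage)
    return mutual_information(channel, p_u)


Forward = Callable[[object], Sequence[ResponseModel]]


def _per_cell_models(ensemble: PopulationEnsemble, forward: Forward):
    return [forward(theta) for theta in ensemble.thetas]


def conditional_mi(
    ensemble: PopulationEnsemble,
    forward: Forward,
    p_u: InputDistribution,
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
) -> float:
    """I_Cee: weighted population average of the per-cell I(theta_i)."""
    vals = np.array(
        [
            cell_specific_mi(forward(theta), p_u, bin_frac, coverage)
            for theta in ensemble.thetas
        ]
    )
    return float(ensemble.weights @ vals)


def cell_state_agnostic_mi(
    ensemble: PopulationEnsemble,
    forward: Forward,
    p_u: InputDistribution,
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
) -> float:
    """I_CSA: MI of the population-pooled mixture channel."""
    channel = pooled_channel(
        _per_cell_models(ensemble, forward), ensemble.weights, bin_frac, coverage
    )
    return mutual_information(channel, p_u)


def interaction_information(
    ensemble: PopulationEnsemble,
    forward: Forward,
    p_u: InputDistribution,
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
) -> float:
    """I_CSA - I_Cee; non-positive when cell states are input-independent."""
    return cell_state_agnostic_mi(
        ensemble, forward, p_u, bin_frac, coverage
    ) - conditional_mi(ensemble, forward, p_u, bin_frac, coverage)


# --------------------------------------------------------------------------
# channel capacity
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CapacityResult:
    """Outcome of an input-simplex maximization."""

    p_opt: InputDistribution
    value_bits: float
    converged: bool
    n_restarts: int
    message: str = ""


def maximize_over_inputs(
    channels: Sequence[np.ndarray],
    weights: Sequence[float],
    doses: Sequence[float],
    seed: int | None = 0,
    n_restarts: int = 5,
    gtol: float = 1e-8,
) -> CapacityResult:
    """Maximize sum_i w_i MI(Q_i, p) over the input probability simplex.

    A trust-region constrained maximizer with analytic gradients, started
    from the uniform distribution plus ``n_restarts`` Dirichlet(1) draws;
    the best feasible optimum is kept.  Works for any convex combination of
    channel MIs, which covers both the pooled-channel objective (I_CSA) and
    the per-cell-average objective (I_Cee).
    """
    channels = [np.atleast_2d(np.asarray(Q, dtype=float)) for Q in channels]
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    n = channels[0].shape[0]
    if any(Q.shape[0] != n for Q in channels):
        raise ValidationError("all channels must share the dose count")

    def neg_obj(p: np.ndarray) -> float:
        return -sum(w * _mi_bits(Q, p) for w, Q in zip(weights, channels))

    def neg_grad(p: np.ndarray) -> np.ndarray:
        g = np.zeros(n)
        for w, Q in zip(weights, channels):
            g += w * _mi_grad_bits(Q, p)
        return -g

    rng = np.random.default_rng(seed)
    starts = [np.full(n, 1.0 / n)]
    starts += [rng.dirichlet(np.ones(n)) for _ in range(n_restarts)]
    constraint = optimize.LinearConstraint(np.ones((1, n)), 1.0, 1.0)
    bounds = optimize.Bounds(np.zeros(n), np.ones(n))

    best_p, best_val, any_ok = None, -np.inf, False
    for p0 in starts:
        res = optimize.minimize(
            neg_obj,
            p0,
            jac=neg_grad,
            method="trust-constr",
            constraints=[constraint],
            bounds=bounds,
            options={"gtol": gtol, "xtol": 1e-14, "maxiter": 2000, "verbose": 0},
        )
        val = -res.fun
        if val > best_val:
            best_val, best_p = val, res.x
        any_ok = any_ok or res.status in (1, 2)

    p = np.clip(best_p, 0.0, None)
    p = p / p.sum()
    uniform_val = -neg_obj(np.full(n, 1.0 / n))
    converged = bool(any_ok and best_val >= uniform_val - 1e-6)
    message = "" if converged else "optimizer did not certify convergence"
    return CapacityResult(
        InputDistribution(tuple(doses), tuple(p)),
        float(max(best_val, uniform_val)) if not converged else float(best_val),
        converged,
        n_restarts,
        message,
    )


def channel_capacity(
    objective: str,
    ensemble: PopulationEnsemble,
    forward: Forward,
    dose_grid: Sequence[float],
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
    seed: int | None = 0,
    n_restarts: int = 5,
    gtol: float = 1e-8,
) -> CapacityResult:
    """Channel capacity of I_CSA or I_Cee over a fixed dose grid.

    ``objective='ICSA'`` maximizes the MI of the pooled mixture channel;
    ``objective='ICee'`` maximizes the ensemble-weighted mean of per-cell
    MIs.  Returns the optimal input distribution and the attained value.
    """
    objective = objective.upper()
    if objective not in ("ICSA", "ICEE"):
        raise ValidationError("objective must be 'ICSA' or 'ICee'")
    per_cell = _per_cell_models(ensemble, forward)
    if objective == "ICSA":
        channel = pooled_channel(per_cell, ensemble.weights, bin_frac, coverage)
        return maximize_over_inputs(
            [channel.cond_probs], [1.0], dose_grid, seed, n_restarts, gtol
        )
    channels = [
        discretize_responses(ms, bin_frac, coverage).cond_probs for ms in per_cell
    ]
    return maximize_over_inputs(
        channels, ensemble.weights, dose_grid, seed, n_restarts, gtol
    )


def capacity_of_channel(
    channel: BinnedChannel,
    doses: Sequence[float] | None = None,
    seed: int | None = 0,
    n_restarts: int = 5,
    gtol: float = 1e-8,
) -> CapacityResult:
    """Capacity of a single prebuilt binned channel."""
    if doses is None:
        doses = list(range(channel.n_doses))
    return maximize_over_inputs(
        [channel.cond_probs], [1.0], doses, seed, n_restarts, gtol
    )
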