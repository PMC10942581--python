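"""Single-cell repeated-stimulation analysis.

Live-cell trajectories in which the same cell is driven with successive
ligand doses give direct access to the cell-specific response
distribution p(x | u, theta): the output settles to an approximate steady
state within each dose epoch, and the samples inside the steady-state
window (60-90 min by default) yield a per-cell, per-dose gamma model.
From these the pipeline computes per-cell MI, the experimental
p_CeeMI(I) at the input distribution maximizing the across-cell mean MI,
the pooled-population channel and its I_CSA, and the within-cell vs
between-cell repeatability contrast (delta vs delta0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .info_core import (
    CapacityResult,
    InputDistribution,
    ResponseModel,
    ValidationError,
    cell_specific_mi,
    discretize_responses,
    maximize_over_inputs,
    mutual_information,
)

__all__ = [
    "per_cell_response_model",
    "pooled_population_model",
    "experimental_pceemi",
    "repeatability_delta",
    "DeltaResult",
]


def per_cell_response_model(
    traj: pd.DataFrame,
    window: tuple[float, float] = (60.0, 90.0),
    min_points: int = 3,
    cell_col: str = "cell_id",
    dose_col: str = "dose",
    time_col: str = "time_min",
    value_col: str = "value",
) -> tuple[dict, list]:
    """Per-(cell, dose) gamma models from steady-state window statistics.

    Expects a long-format table (cell_id, dose, time_min, value).  Cells
    with fewer than ``min_points`` samples in the window at any dose, or a
    degenerate (zero-variance) window, are dropped entirely so every
    retained cell has a model for every dose; exclusions are returned as a
    log of (cell_id, reason).
    """
    lo, hi = window
    win = traj[(traj[time_col] >= lo) & (traj[time_col] <= hi)]
    doses = sorted(traj[dose_col].unique())
    models: dict = {}
    excluded: list = []
    for cell, g in win.groupby(cell_col):
        per_dose = {}
        reason = None
        for dose in doses:
            vals = g.loc[g[dose_col] == dose, value_col].to_numpy(dtype=float)
            if len(vals) < min_points:
                reason = f"dose {dose}: {len(vals)} points in window (<{min_points})"
                break
            mean = float(vals.mean())
            var = float(vals.var(ddof=1))
            if var <= 0 or mean <= 0:
                reason = f"dose {dose}: degenerate window statistics"
                break
            per_dose[dose] = ResponseModel.gamma(mean, var)
        if reason is None:
            models[cell] = per_dose
        else:
            excluded.append((cell, reason))
    return models, excluded


def pooled_population_model(
    cell_models: dict,
) -> tuple[dict, list]:
    """Population gamma per dose from averaged first/second moments.

    The pooled mean is the mean of per-cell means; the pooled variance is
    the exact mixture variance, mean of (variance + mean^2) minus the
    squared pooled mean.  Returns ({dose: ResponseModel}, dose order).
    """
    if len(cell_models) < 2:
        raise ValidationError("need at least 2 cells to pool")
    doses = sorted(next(iter(cell_models.values())).keys())
    pooled = {}
    for dose in doses:
        means = np.array([m[dose].mean for m in cell_models.values()])
        variances = np.array([m[dose].variance for m in cell_models.values()])
        mix_mean = float(means.mean())
        mix_var = float((variances + means**2).mean() - mix_mean**2)
        pooled[dose] = ResponseModel.gamma(mix_mean, max(mix_var, 1e-12))
    return pooled, doses


def population_icsa(
    cell_models: dict,
    p_u: InputDistribution,
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
) -> float:
    """I_CSA of the moment-pooled population channel."""
    pooled, doses = pooled_population_model(cell_models)
    channel = discretize_responses([pooled[d] for d in doses], bin_frac, coverage)
    return mutual_information(channel, p_u)


def experimental_pceemi(
    cell_models: dict,
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
    seed: int = 0,
) -> tuple[pd.DataFrame, InputDistribution, CapacityResult]:
    """p_CeeMI(I) at the input maximizing the across-cell mean MI.

    Builds each cell's binned channel, finds p*(u) maximizing the mean of
    the per-cell MIs over the input simplex, and reports each cell's MI at
    p*(u).  Returns (per-cell table, p*, optimizer result).
    """
    if len(cell_models) == 0:
        raise ValidationError("no cells")
    doses = sorted(next(iter(cell_models.values())).keys())
    cells = list(cell_models.keys())
    channels = [
        discretize_responses(
            [cell_models[c][d] for d in doses], bin_frac, coverage
        ).cond_probs
        for c in cells
    ]
    res = maximize_over_inputs(
        channels, np.full(len(cells), 1.0 / len(cells)), doses, seed=seed
    )
    rows = [
        {
            "cell_id": c,
            "i_bits": cell_specific_mi(
                [cell_models[c][d] for d in doses], res.p_opt, bin_frac, coverage
            ),
        }
        for c in cells
    ]
    return pd.DataFrame(rows), res.p_opt, res


@dataclass(frozen=True)
class DeltaResult:
    """Within-cell (delta) vs between-cell (delta0) response differences."""

    delta: np.ndarray
    delta0: np.ndarray

    @property
    def var_delta(self) -> float:
        return float(np.var(self.delta, ddof=1))

    @property
    def var_delta0(self) -> float:
        return float(np.var(self.delta0, ddof=1))

    @property
    def variance_ratio(self) -> float:
        return self.var_delta / self.var_delta0


def repeatability_delta(
    x1: np.ndarray,
    x2: np.ndarray,
    oversample: int = 10,
    seed: int = 0,
) -> DeltaResult:
    """Repeated-stimulation repeatability: p(delta) vs p(delta0).

    ``x1`` and ``x2`` are the paired responses of each cell to the same
    stimulus in two epochs.  delta = x1 - x2 within cells; delta0 pairs
    responses of distinct cells via ``oversample`` seeded random
    derangements.  Stable cell states make var(delta) < var(delta0).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) != len(x2):
        raise ValidationError("x1 and x2 must pair the same cells")
    if len(x1) < 2:
        raise ValidationError("need at least 2 cells")
    delta = x1 - x2
    rng = np.random.default_rng(seed)
    n = len(x1)
    pieces = []
    for _ in range(oversample):
        perm = rng.permutation(n)
        fixed = perm == np.arange(n)
        if fixed.any():  # swap fixed points pairwise to get a derangement
            idx = np.flatnonzero(fixed)
            if len(idx) == 1:
                other = (idx[0] + 1) % n
                perm[idx[0]], perm[other] = perm[other], perm[idx[0]]
            else:
                perm[idx] = np.roll(perm[idx], 1)
        pieces.append(x1 - x2[perm])
    return DeltaResult(delta, np.concatenate(pieces))
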