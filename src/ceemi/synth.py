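"""Synthetic single-cell data with known ground truth.

Emulates the two experimental input kinds the estimation pipeline
consumes: (a) snapshot abundance tables -- one measurement per cell and
ligand dose, drawn by pushing a known cell-state distribution p(theta)
through the forward response model; and (b) repeated-stimulation
trajectory tables -- per-cell time courses across successive dose epochs
that relax to the cell's steady state and fluctuate around it inside the
steady-state window, with the cell state held fixed across epochs (or
redrawn, for the unstable-state null).  Every draw is seeded and each
table ships with a ground-truth sidecar (theta per cell, per-cell
moments) for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .info_core import ResponseModel, ValidationError
from .toy_model import (
    ToyCellState,
    ToyPopulation,
    dose_response_models,
    steady_state_mean_bound,
)

__all__ = ["GeneratorSpec", "generate_snapshot", "generate_trajectories"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions of a synthetic data set.

    ``population`` is the ground-truth cell-state law (gamma in one toy
    parameter); ``noise_cv`` a multiplicative log-normal measurement
    noise; ``seed`` is mandatory so stored fixtures are reproducible.
    """

    population: ToyPopulation = ToyPopulation("R0", 500.0, 0.3)
    doses: tuple = (0.5, 2.0, 8.0, 32.0)
    n_cells: int = 500
    noise_cv: float = 0.05
    seed: int = 0
    # trajectory-mode time structure (minutes)
    epoch_minutes: float = 90.0
    sample_every: float = 3.0
    relax_minutes: float = 10.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if len(self.doses) < 2:
            raise ValidationError("need at least 2 doses")


def _draw_thetas(spec: GeneratorSpec, rng: np.random.Generator) -> list[ToyCellState]:
    pop = spec.population
    shape = 1.0 / pop.cv**2
    vals = rng.gamma(shape, pop.mean * pop.cv**2, size=spec.n_cells)
    return [pop.cell(v) for v in vals]


def _noise_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=size)


def _sample_response(
    model: ResponseModel, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    if model.family == "poisson":
        return rng.poisson(model.mean, size=size).astype(float)
    if model.family == "gamma":
        shape = model.mean**2 / model.variance
        return rng.gamma(shape, model.variance / model.mean, size=size)
    raise ValidationError(f"sampling not implemented for {model.family}")


def generate_snapshot(
    spec: GeneratorSpec,
) -> tuple[pd.DataFrame, dict]:
    """Cells x doses abundance table plus ground-truth sidecar.

    One value per (cell, dose): a draw from the cell's dose-conditioned
    response model times multiplicative measurement noise.  The sidecar
    carries the theta table and the noise-free per-cell response moments.
    """
    rng = np.random.default_rng(spec.seed)
    thetas = _draw_thetas(spec, rng)
    doses = list(spec.doses)
    values = np.empty((spec.n_cells, len(doses)))
    moments = []
    for i, theta in enumerate(thetas):
        models = dose_response_models(theta, doses)
        for j, m in enumerate(models):
            values[i, j] = _sample_response(m, rng, 1)[0]
            moments.append(
                {"cell": i, "dose": doses[j], "mean": m.mean, "variance": m.variance}
            )
    values *= _noise_factor(rng, spec.noise_cv, values.shape)
    table = pd.DataFrame(values, columns=[str(d) for d in doses])
    table.index.name = "cell"
    var_name = spec.population.variable_parameter
    sidecar = {
        "thetas": pd.DataFrame(
            {var_name: [getattr(t, var_name) for t in thetas]}
        ),
        "moments": pd.DataFrame(moments),
        "spec": spec,
    }
    return table, sidecar


def generate_trajectories(
    spec: GeneratorSpec,
    schedule: Sequence[float] | None = None,
    stable: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Long-format per-cell trajectories across successive dose epochs.

    Within each epoch the mean output relaxes exponentially (time scale
    ``relax_minutes``) from the previous epoch's end level to the cell's
    steady state for that dose, with gamma fluctuations at the cell's
    steady-state Fano factor plus measurement noise.  ``stable=True``
    keeps theta fixed across epochs; ``stable=False`` redraws it every
    epoch (the exchangeable null for repeatability analyses).
    """
    rng = np.random.default_rng(spec.seed)
    if schedule is None:
        schedule = list(spec.doses)
    times = np.arange(0.0, spec.epoch_minutes + 1e-9, spec.sample_every)
    thetas = _draw_thetas(spec, rng)
    rows = []
    truth = []
    for i in range(spec.n_cells):
        level = 0.0
        theta = thetas[i]
        for epoch, dose in enumerate(schedule):
            if not stable and epoch > 0:
                theta = _draw_thetas(
                    GeneratorSpec(
                        population=spec.population,
                        doses=spec.doses,
                        n_cells=1,
                        noise_cv=spec.noise_cv,
                        seed=0,
                    ),
                    rng,
                )[0]
            mu_ss = steady_state_mean_bound(theta, dose)
            fano = 1.0  # Poisson steady state of the receptor model
            mu_t = mu_ss + (level - mu_ss) * np.exp(-times / spec.relax_minutes)
            mu_t = np.maximum(mu_t, 1e-9)
            var_t = np.maximum(fano * mu_t, 1e-12)
            shape = mu_t**2 / var_t
            vals = rng.gamma(shape, var_t / mu_t)
            vals *= _noise_factor(rng, spec.noise_cv, len(vals))
            level = mu_t[-1]
            for t, v in zip(times, vals):
                rows.append(
                    {
                        "cell_id": i,
                        "epoch": epoch,
                        "dose": dose,
                        "time_min": float(t),
                        "value": float(v),
                    }
                )
            truth.append(
                {
                    "cell": i,
                    "epoch": epoch,
                    "dose": dose,
                    "theta_value": getattr(
                        theta, spec.population.variable_parameter
                    ),
                    "steady_state_mean": mu_ss,
                }
            )
    var_name = spec.population.variable_parameter
    sidecar = {
        "thetas": pd.DataFrame({var_name: [getattr(t, var_name) for t in thetas]}),
        "truth": pd.DataFrame(truth),
        "spec": spec,
    }
    return pd.DataFrame(rows), sidecar
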