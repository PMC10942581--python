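"""Population-level CeeMI summaries from a fitted cell-state ensemble.

Turns an ensemble {theta_i} and a forward model theta -> per-dose
response distributions into the distribution p_CeeMI(I) of single-cell
sensing fidelities, its joint with biochemical covariates chi(theta)
(e.g. response range, basal output level), and the optimal input
distributions for the pooled (I_CSA) and cell-conditioned (I_Cee)
objectives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .info_core import (
    CapacityResult,
    Forward,
    InputDistribution,
    PopulationEnsemble,
    ValidationError,
    cell_specific_mi,
    channel_capacity,
)

__all__ = [
    "FidelityResult",
    "pceemi",
    "joint_pceemi",
    "optimal_inputs",
    "response_range",
    "basal_output",
]


@dataclass(frozen=True)
class FidelityResult:
    """Empirical p_CeeMI(I): per-cell I(theta_i) with ensemble weights."""

    values_bits: np.ndarray
    weights: np.ndarray
    hist_edges: np.ndarray
    hist_density: np.ndarray

    @property
    def mean_bits(self) -> float:
        return float(self.weights @ self.values_bits)


def pceemi(
    ensemble: PopulationEnsemble,
    forward: Forward,
    p_u: InputDistribution,
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
    n_hist_bins: int = 30,
) -> FidelityResult:
    """Distribution of single-cell MI values across the ensemble.

    The weighted mean of the returned samples equals I_Cee by definition.
    """
    vals = np.array(
        [
            cell_specific_mi(forward(theta), p_u, bin_frac, coverage)
            for theta in ensemble.thetas
        ]
    )
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        edges = np.array([lo - 0.5, lo + 0.5])
        density = np.array([1.0])
    else:
        density, edges = np.histogram(
            vals, bins=n_hist_bins, weights=ensemble.weights, density=True
        )
    return FidelityResult(vals, ensemble.weights, edges, density)


def response_range(forward: Forward) -> Callable:
    """Covariate: |mean output at the highest dose - at the lowest dose|."""

    def chi(theta) -> float:
        models = forward(theta)
        return abs(models[-1].mean - models[0].mean)

    return chi


def basal_output(forward: Forward) -> Callable:
    """Covariate: mean output at the lowest (typically zero) dose."""

    def chi(theta) -> float:
        return forward(theta)[0].mean

    return chi


def joint_pceemi(
    ensemble: PopulationEnsemble,
    forward: Forward,
    p_u: InputDistribution,
    covariates: dict,
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
    n_trend_bins: int = 10,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Joint p_CeeMI(I, chi) samples plus correlations per covariate.

    Returns (table of per-cell (I, chi) values, per-covariate correlation
    dict with Pearson and Spearman coefficients, binned conditional means
    of I given chi -- the trend line).  A constant covariate yields
    correlation ``None`` with an explanatory message.
    """
    fid = pceemi(ensemble, forward, p_u, bin_frac, coverage)
    data = {"i_bits": fid.values_bits}
    for name, fn in covariates.items():
        data[name] = np.array([float(fn(theta)) for theta in ensemble.thetas])
    table = pd.DataFrame(data)

    corr: dict = {}
    trend_rows = []
    for name in covariates:
        chi = table[name].to_numpy()
        if np.ptp(chi) < 1e-12 * max(1.0, abs(chi[0])):
            corr[name] = {
                "pearson": None,
                "spearman": None,
                "message": "constant covariate; correlation undefined",
            }
            continue
        corr[name] = {
            "pearson": float(stats.pearsonr(chi, fid.values_bits)[0]),
            "spearman": float(stats.spearmanr(chi, fid.values_bits)[0]),
            "message": "",
        }
        cuts = pd.cut(table[name], bins=n_trend_bins)
        g = table.groupby(cuts, observed=True)["i_bits"].mean()
        mids = [iv.mid for iv in g.index]
        for mid, val in zip(mids, g.to_numpy()):
            trend_rows.append(
                {"covariate": name, "chi_mid": float(mid), "i_bits_mean": float(val)}
            )
    return table, corr, pd.DataFrame(trend_rows)


def optimal_inputs(
    ensemble: PopulationEnsemble,
    forward: Forward,
    dose_grid: Sequence[float],
    bin_frac: float = 0.05,
    coverage: float = 0.9995,
    seed: int = 0,
) -> dict:
    """Capacity-achieving inputs for both objectives on one dose grid.

    Returns the optimal p(u) and attained bits for I_CSA (pooled channel)
    and I_Cee (per-cell average); CC_ICee >= CC_ICSA always, since the
    interaction information is non-positive at every fixed input.
    """
    if len(dose_grid) < 2:
        raise ValidationError("need at least 2 doses")
    res_csa: CapacityResult = channel_capacity(
        "ICSA", ensemble, forward, dose_grid, bin_frac, coverage, seed=seed
    )
    res_cee: CapacityResult = channel_capacity(
        "ICee", ensemble, forward, dose_grid, bin_frac, coverage, seed=seed
    )
    return {
        "p_icsa": res_csa.p_opt,
        "p_icee": res_cee.p_opt,
        "cc_icsa_bits": res_csa.value_bits,
        "cc_icee_bits": res_cee.value_bits,
        "icsa_result": res_csa,
        "icee_result": res_cee,
    }
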