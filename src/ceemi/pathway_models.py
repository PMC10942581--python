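"""Stochastic biochemical models of the EGF/EGFR and IGF/FoxO networks.

Both pathways share a receptor core: receptors are produced, degraded,
bound reversibly by ligand, and phosphorylated reversibly, with activated
receptors endocytosed preferentially (rate kdeg* >= kdeg).  The FoxO
network adds receptor-catalyzed Akt phosphorylation and pAkt-catalyzed
cytoplasmic FoxO phosphorylation; only unphosphorylated FoxO shuttles into
the nucleus, so nuclear FoxO falls with ligand dose.

Per-cell response distributions p(x | u, theta) are obtained by Gaussian
moment closure of the chemical master equation (third central moments set
to zero, covariances retained in bilinear mean equations) and summarized
as a moment-matched gamma.  Exact Gillespie simulation of the same
networks serves as the accuracy reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .info_core import ResponseModel, ValidationError
from .ssa import run_ssa

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ClosureError",
    "CalibrationError",
    "MomentResult",
    "build_egfr_model",
    "build_foxo_model",
    "moment_closure_solve",
    "mean_field_steady_state",
    "response_distribution",
    "gillespie_simulate",
    "convert_units",
]


class ClosureError(RuntimeError):
    """Moment closure failed (non-convergence or unphysical variance)."""


class CalibrationError(ValidationError):
    """Unit-conversion calibration is incomplete or inconsistent."""


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction; catalysts appear in reactants and products."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: str
    dose_scaled: bool = False


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    output: tuple[str, ...]
    conserved: dict = field(default_factory=dict)
    initial_means: Callable[[dict], np.ndarray] = None

    def index(self, name: str) -> int:
        return self.species.index(name)

    def stoichiometry(self) -> np.ndarray:
        S = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        for r, rxn in enumerate(self.reactions):
            for sp in rxn.reactants:
                S[r, self.index(sp)] -= 1
            for sp in rxn.products:
                S[r, self.index(sp)] += 1
        return S

    def reactant_indices(self) -> np.ndarray:
        idx = np.full((len(self.reactions), 2), -1, dtype=np.int64)
        for r, rxn in enumerate(self.reactions):
            if len(rxn.reactants) > 2:
                raise ValidationError("at most bimolecular propensities supported")
            for j, sp in enumerate(rxn.reactants):
                idx[r, j] = self.index(sp)
        return idx

    def coefficients(self, theta: dict, dose: float) -> np.ndarray:
        if dose < 0:
            raise ValidationError("dose must be >= 0")
        coeffs = np.empty(len(self.reactions))
        for r, rxn in enumerate(self.reactions):
            k = theta.get(rxn.rate)
            if k is None:
                raise ValidationError(f"missing rate constant {rxn.rate!r}")
            if k <= 0:
                raise ValidationError(f"rate constant {rxn.rate!r} must be > 0")
            coeffs[r] = k * dose if rxn.dose_scaled else k
        return coeffs

    def output_indices(self) -> np.ndarray:
        return np.array([self.index(sp) for sp in self.output], dtype=np.int64)


def _receptor_core(p_deg_rate: str) -> tuple[Reaction, ...]:
    return (
        Reaction((), ("R",), "kprod"),
        Reaction(("R",), ("B",), "kbind", dose_scaled=True),
        Reaction(("B",), ("R",), "kunbind"),
        Reaction(("B",), ("P",), "kp"),
        Reaction(("P",), ("B",), "kdp"),
        Reaction(("R",), (), "kdeg"),
        Reaction(("B",), (), "kdeg"),
        Reaction(("P",), (), p_deg_rate),
    )


def build_egfr_model(p_degradation: str = "kdeg_star") -> ReactionNetwork:
    """Receptor-level EGF/EGFR network; output is total surface receptors.

    Species R (free), B (ligand bound), P (phosphorylated); the output
    R_T = R + B + P.  Activated receptors P are endocytosed at ``kdeg*``
    by default so the steady-state surface pool shrinks with dose.
    """

    def init(theta: dict) -> np.ndarray:
        means = np.zeros(3)
        means[0] = theta["kprod"] / theta["kdeg"]
        return means

    return ReactionNetwork(
        species=("R", "B", "P"),
        reactions=_receptor_core(p_degradation),
        output=("R", "B", "P"),
        initial_means=init,
    )


def build_foxo_model(p_degradation: str = "kdeg_star") -> ReactionNetwork:
    """IGF/FoxO network; output is nuclear unphosphorylated FoxO.

    Adds to the receptor core: P-catalyzed Akt phosphorylation (kap),
    pAkt dephosphorylation (kadp), FoxO nuclear import/export (kin, kef),
    pAkt-catalyzed cytoplasmic FoxO phosphorylation (kfp) and its reverse
    (kfdp).  Akt + pAkt and FoxOc + FoxOn + pFoxOc are conserved totals
    set by theta["Akt_total"] and theta["FoxO_total"].
    """

    def init(theta: dict) -> np.ndarray:
        means = np.zeros(8)
        means[0] = theta["kprod"] / theta["kdeg"]
        means[3] = theta["Akt_total"]
        frac = theta["kin"] / (theta["kin"] + theta["kef"])
        means[6] = theta["FoxO_total"] * frac
        means[5] = theta["FoxO_total"] * (1 - frac)
        return means

    reactions = _receptor_core(p_degradation) + (
        Reaction(("Akt", "P"), ("pAkt", "P"), "kap"),
        Reaction(("pAkt",), ("Akt",), "kadp"),
        Reaction(("FoxOc",), ("FoxOn",), "kin"),
        Reaction(("FoxOn",), ("FoxOc",), "kef"),
        Reaction(("FoxOc", "pAkt"), ("pFoxOc", "pAkt"), "kfp"),
        Reaction(("pFoxOc",), ("FoxOc",), "kfdp"),
    )
    return ReactionNetwork(
        species=("R", "B", "P", "Akt", "pAkt", "FoxOc", "FoxOn", "pFoxOc"),
        reactions=reactions,
        output=("FoxOn",),
        conserved={
            "Akt_total": ("Akt", "pAkt"),
            "FoxO_total": ("FoxOc", "FoxOn", "pFoxOc"),
        },
        initial_means=init,
    )


# --------------------------------------------------------------------------
# Gaussian moment closure
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MomentResult:
    species_means: np.ndarray
    covariance: np.ndarray
    output_mean: float
    output_variance: float
    converged: bool
    t_final: float


def _closure_rhs(net: ReactionNetwork, coeffs, r_idx, S):
    n = len(net.species)

    def rhs(t, y):
        mu = y[:n]
        C = y[n:].reshape(n, n)
        a = np.empty(len(coeffs))
        J = np.zeros((len(coeffs), n))
        for r, c in enumerate(coeffs):
            i, j = r_idx[r]
            if i < 0:
                a[r] = c
            elif j < 0:
                a[r] = c * mu[i]
                J[r, i] = c
            else:
                # bilinear: Gaussian closure keeps the covariance term in
                # the mean and drops third central moments in the gradient
                a[r] = c * (mu[i] * mu[j] + C[i, j])
                J[r, i] += c * mu[j]
                J[r, j] += c * mu[i]
        dmu = S.T @ a
        M = S.T @ J
        dC = M @ C + C @ M.T + (S.T * a) @ S
        return np.concatenate([dmu, dC.ravel()])

    return rhs


def moment_closure_solve(
    net: ReactionNetwork,
    theta: dict,
    dose: float,
    ss_tol: float = 1e-8,
    horizon: float = 1e4,
    t_horizon: float | None = None,
) -> MomentResult:
    """Integrate the closed first/second-moment ODEs to steady state.

    Starts from the deterministic zero-ligand steady state with zero
    covariances except Poisson-level variance on free receptors, and
    integrates in growing chunks until the maximum relative rate of change
    drops below ``ss_tol`` or the horizon (default 1e4 model seconds) is
    reached.  ``t_horizon`` forces a fixed-time (non-steady-state) solve.
    """
    coeffs = net.coefficients(theta, dose)
    r_idx = net.reactant_indices()
    S = net.stoichiometry().astype(float)
    n = len(net.species)
    mu0 = net.initial_means(theta)
    C0 = np.zeros((n, n))
    if "R" in net.species:
        iR = net.index("R")
        C0[iR, iR] = mu0[iR]
    y = np.concatenate([mu0, C0.ravel()])
    rhs = _closure_rhs(net, coeffs, r_idx, S)

    converged = False
    t_total = 0.0
    if t_horizon is not None:
        sol = solve_ivp(rhs, (0, t_horizon), y, method="LSODA", rtol=1e-9, atol=1e-9)
        if not sol.success:
            raise ClosureError(f"moment integration failed: {sol.message}")
        y = sol.y[:, -1]
        t_total = t_horizon
        converged = True
    else:
        chunk = 5.0
        while t_total < horizon:
            chunk = min(chunk, horizon - t_total)
            sol = solve_ivp(rhs, (0, chunk), y, method="LSODA", rtol=1e-9, atol=1e-9)
            if not sol.success:
                raise ClosureError(f"moment integration failed: {sol.message}")
            y = sol.y[:, -1]
            t_total += chunk
            dy = rhs(0.0, y)
            if np.max(np.abs(dy) / (np.abs(y) + 1.0)) < ss_tol:
                converged = True
                break
            chunk *= 4.0
        if not converged:
            raise ClosureError(
                f"no steady state within horizon {horizon} s "
                f"(residual {np.max(np.abs(rhs(0.0, y)) / (np.abs(y) + 1.0)):.2e})"
            )

    mu = y[:n]
    C = y[n:].reshape(n, n)
    C = (C + C.T) / 2
    out = net.output_indices()
    out_mean = float(mu[out].sum())
    out_var = float(C[np.ix_(out, out)].sum())
    var_floor = -1e-6 * max(1.0, out_mean**2)
    if out_var < var_floor or np.any(np.diag(C) < var_floor):
        raise ClosureError(
            f"closure produced negative variance (output var {out_var:.3e})"
        )
    out_var = max(out_var, 1e-12)
    return MomentResult(mu, C, out_mean, out_var, converged, t_total)


def mean_field_steady_state(
    net: ReactionNetwork, theta: dict, dose: float, horizon: float = 1e4
) -> np.ndarray:
    """Deterministic rate-equation steady state (no fluctuation terms)."""
    coeffs = net.coefficients(theta, dose)
    r_idx = net.reactant_indices()
    S = net.stoichiometry().astype(float)

    def rhs(t, mu):
        a = np.empty(len(coeffs))
        for r, c in enumerate(coeffs):
            i, j = r_idx[r]
            a[r] = c if i < 0 else (c * mu[i] if j < 0 else c * mu[i] * mu[j])
        return S.T @ a

    y = net.initial_means(theta).astype(float)
    t, chunk = 0.0, 5.0
    while t < horizon:
        chunk = min(chunk, horizon - t)
        sol = solve_ivp(rhs, (0, chunk), y, method="LSODA", rtol=1e-10, atol=1e-10)
        y = sol.y[:, -1]
        t += chunk
        if np.max(np.abs(rhs(0.0, y)) / (np.abs(y) + 1.0)) < 1e-10:
            break
        chunk *= 4.0
    return y


def response_distribution(
    net: ReactionNetwork, theta: dict, dose: float, **kwargs
) -> ResponseModel:
    """Gamma approximation of p(x | u, theta) with the closure moments."""
    res = moment_closure_solve(net, theta, dose, **kwargs)
    return ResponseModel.gamma(res.output_mean, res.output_variance)


def gillespie_simulate(
    net: ReactionNetwork,
    theta: dict,
    dose: float,
    t_end: float,
    n_reps: int,
    seed: int,
    initial: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact SSA; returns (output samples at t_end, final species states)."""
    coeffs = net.coefficients(theta, dose)
    if initial is None:
        initial = np.round(net.initial_means(theta)).astype(np.int64)
    finals = run_ssa(
        np.asarray(initial, dtype=np.int64),
        t_end,
        coeffs,
        net.reactant_indices(),
        net.stoichiometry(),
        n_reps,
        seed,
    )
    outputs = finals[:, net.output_indices()].sum(axis=1).astype(float)
    return outputs, finals


# --------------------------------------------------------------------------
# unit conversion
# --------------------------------------------------------------------------


def convert_units(table: pd.DataFrame, calibration: dict) -> pd.DataFrame:
    """Convert arbitrary fluorescence units to molecule counts.

    EGFR mode rescales so the zero-ligand population mean matches the
    reference surface-receptor count (2.5e5 for MCF10A).  FoxO mode
    subtracts a constant background, offsets experiments so unstimulated
    nuclear means coincide, then rescales so the unstimulated nuclear mean
    equals ``nuclear_fraction * total`` (2/3 of 710 molecules by default).
    """
    mode = calibration.get("mode")
    if mode not in ("egfr", "foxo"):
        raise CalibrationError("calibration['mode'] must be 'egfr' or 'foxo'")
    zero = calibration.get("zero_condition")
    df = table.copy()
    exp_col = calibration.get("experiment_col")
    value_cols = [c for c in df.columns if c != exp_col]
    if zero is None or zero not in value_cols:
        raise CalibrationError("zero-ligand condition missing from table")

    if mode == "egfr":
        ref = float(calibration.get("reference_mean", 2.5e5))
        scale = ref / float(df[zero].mean())
        df[value_cols] = df[value_cols] * scale
        return df

    background = float(calibration.get("background", 0.0))
    total = float(calibration.get("total", 710.0))
    frac = float(calibration.get("nuclear_fraction", 2.0 / 3.0))
    df[value_cols] = df[value_cols] - background
    if exp_col is not None:
        means = df.groupby(exp_col)[zero].transform("mean")
        df[value_cols] = df[value_cols].sub(means - float(df[zero].mean()), axis=0)
    scale = frac * total / float(df[zero].mean())
    df[value_cols] = df[value_cols] * scale
    return df
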