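"""Tests of the EGFR/FoxO networks, moment closure, SSA and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ceemi.info_core import ValidationError
from ceemi.pathway_models import (
    CalibrationError,
    ClosureError,
    Reaction,
    ReactionNetwork,
    build_egfr_model,
    build_foxo_model,
    convert_units,
    gillespie_simulate,
    mean_field_steady_state,
    moment_closure_solve,
    response_distribution,
)

EGFR_THETA = dict(
    kprod=20.0, kbind=0.1, kunbind=0.5, kp=0.2, kdp=0.1, kdeg=0.05, kdeg_star=0.2
)
FOXO_THETA = dict(
    kprod=20.0, kbind=0.02, kunbind=0.5, kp=0.2, kdp=0.1, kdeg=0.05, kdeg_star=0.2,
    kap=0.001, kadp=0.1, kin=0.04, kef=0.02, kfp=0.002, kfdp=0.1,
    Akt_total=300.0, FoxO_total=710.0,
)


def birth_death_network():
    def init(theta):
        return np.array([0.0])

    return ReactionNetwork(
        species=("R",),
        reactions=(Reaction((), ("R",), "kprod"), Reaction(("R",), (), "kdeg")),
        output=("R",),
        initial_means=init,
    )


class TestNetworkConstruction:
    def test_egfr_reaction_count_and_species(self):
        net = build_egfr_model()
        assert len(net.reactions) == 8
        assert net.species == ("R", "B", "P")
        assert net.output == ("R", "B", "P")

    def test_zero_ligand_steady_state_is_birth_death(self):
        net = build_egfr_model()
        res = moment_closure_solve(net, EGFR_THETA, 0.0)
        expect = EGFR_THETA["kprod"] / EGFR_THETA["kdeg"]
        assert res.output_mean == pytest.approx(expect, rel=1e-6)
        # Poisson stationary law: variance equals mean
        assert res.output_variance == pytest.approx(expect, rel=1e-6)

    def test_surface_receptors_decrease_with_dose(self):
        """Preferential endocytosis of activated receptors (kdeg* > kdeg)
        depletes the steady-state surface pool as ligand rises."""
        net = build_egfr_model()
        means = [
            mean_field_steady_state(net, EGFR_THETA, L).sum() for L in (0.0, 0.5, 5.0)
        ]
        assert means[0] > means[1] > means[2]

    def test_foxo_nuclear_fraction_without_stimulation(self):
        net = build_foxo_model()
        res = moment_closure_solve(net, FOXO_THETA, 0.0)
        # kin/(kin+kef) = 2/3 of total FoxO in the nucleus at L=0
        assert res.output_mean == pytest.approx(710.0 * 2 / 3, rel=1e-4)

    def test_foxo_nuclear_level_falls_with_dose(self):
        net = build_foxo_model()
        mf = [
            mean_field_steady_state(net, FOXO_THETA, L)[net.index("FoxOn")]
            for L in (0.0, 5.0, 50.0)
        ]
        assert mf[0] > mf[1] > mf[2]

    def test_foxo_conservation_along_ssa_trajectory(self):
        net = build_foxo_model()
        _, finals = gillespie_simulate(net, FOXO_THETA, 10.0, 50.0, 200, seed=3)
        akt = finals[:, net.index("Akt")] + finals[:, net.index("pAkt")]
        foxo = (
            finals[:, net.index("FoxOc")]
            + finals[:, net.index("FoxOn")]
            + finals[:, net.index("pFoxOc")]
        )
        assert np.all(akt == 300)
        assert np.all(foxo == 710)

    def test_p_degradation_rate_selectable(self):
        net = build_foxo_model(p_degradation="kdeg")
        rates = [r.rate for r in net.reactions]
        assert "kdeg_star" not in rates


class TestMomentClosure:
    def test_birth_death_closure_is_exact_poisson(self):
        theta = dict(kprod=7.0, kdeg=0.35)
        res = moment_closure_solve(birth_death_network(), theta, 0.0)
        assert res.output_mean == pytest.approx(20.0, rel=1e-7)
        assert res.output_variance == pytest.approx(20.0, rel=1e-6)

    def test_egfr_closure_vs_gillespie(self):
        net = build_egfr_model()
        res = moment_closure_solve(net, EGFR_THETA, 1.0)
        out, _ = gillespie_simulate(net, EGFR_THETA, 1.0, 300.0, 600, seed=11)
        sem = out.std(ddof=1) / np.sqrt(len(out))
        assert res.output_mean == pytest.approx(out.mean(), abs=3 * sem)
        assert res.output_variance == pytest.approx(out.var(ddof=1), rel=0.25)

    def test_foxo_closure_mean_matches_ode_at_zero_ligand(self):
        net = build_foxo_model()
        res = moment_closure_solve(net, FOXO_THETA, 0.0)
        mf = mean_field_steady_state(net, FOXO_THETA, 0.0)
        assert res.output_mean == pytest.approx(mf[net.index("FoxOn")], rel=0.01)

    def test_closure_means_match_mean_field_for_linear_network(self):
        # all propensities linear at L=0 in the EGFR model
        net = build_egfr_model()
        res = moment_closure_solve(net, EGFR_THETA, 0.0)
        mf = mean_field_steady_state(net, EGFR_THETA, 0.0)
        assert np.allclose(res.species_means, mf, rtol=0.01, atol=1e-6)

    def test_nonconvergence_raises_with_diagnostics(self):
        with pytest.raises(ClosureError, match="horizon"):
            moment_closure_solve(
                birth_death_network(), dict(kprod=1.0, kdeg=1e-7), 0.0, horizon=10.0
            )


class TestResponseDistribution:
    def test_gamma_moment_matching_arithmetic(self):
        net = birth_death_network()
        m = response_distribution(net, dict(kprod=10.0, kdeg=0.1), 0.0)
        assert m.family == "gamma"
        assert m.mean == pytest.approx(100.0, rel=1e-6)
        assert m.variance == pytest.approx(100.0, rel=1e-6)
        shape = m.mean**2 / m.variance
        assert shape == pytest.approx(100.0, rel=1e-5)

    def test_gamma_fits_ssa_samples(self):
        """KS distance between the closure gamma and SSA samples < 0.1 at
        mid-dose on the EGFR network."""
        net = build_egfr_model()
        m = response_distribution(net, EGFR_THETA, 0.5)
        out, _ = gillespie_simulate(net, EGFR_THETA, 0.5, 300.0, 800, seed=21)
        ks = stats.kstest(out, m.dist.cdf).statistic
        assert ks < 0.1


class TestGillespie:
    def test_all_rates_zero_keeps_state(self):
        net = birth_death_network()
        with pytest.raises(ValidationError):
            net.coefficients(dict(kprod=0.0, kdeg=0.0), 0.0)

    def test_stationary_mean_matches_analytic(self):
        net = birth_death_network()
        out, _ = gillespie_simulate(net, dict(kprod=8.0, kdeg=0.2), 0.0, 100.0,
                                    600, seed=5)
        sem = out.std(ddof=1) / np.sqrt(len(out))
        assert out.mean() == pytest.approx(40.0, abs=3 * sem)

    def test_equal_seeds_identical_runs(self):
        net = build_egfr_model()
        a, _ = gillespie_simulate(net, EGFR_THETA, 1.0, 50.0, 50, seed=42)
        b, _ = gillespie_simulate(net, EGFR_THETA, 1.0, 50.0, 50, seed=42)
        assert np.array_equal(a, b)


class TestConvertUnits:
    def test_egfr_scaling(self):
        df = pd.DataFrame({"0": [900.0, 1100.0], "1": [500.0, 700.0]})
        out = convert_units(df, {"mode": "egfr", "zero_condition": "0"})
        assert out["0"].mean() == pytest.approx(2.5e5)
        assert out["1"].mean() == pytest.approx(600.0 * 250.0)

    def test_foxo_unstimulated_mean_calibrated(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"0": rng.normal(1000, 30, 200), "125": rng.normal(400, 30, 200)}
        )
        out = convert_units(
            df, {"mode": "foxo", "zero_condition": "0", "background": 100.0}
        )
        assert out["0"].mean() == pytest.approx(710.0 * 2 / 3)

    def test_experiment_offsets_equalized(self):
        df = pd.DataFrame(
            {
                "exp": ["a"] * 100 + ["b"] * 100,
                "0": [1000.0] * 100 + [1050.0] * 100,
                "125": [400.0] * 100 + [450.0] * 100,
            }
        )
        out = convert_units(
            df,
            {"mode": "foxo", "zero_condition": "0", "experiment_col": "exp"},
        )
        means = out.groupby("exp")["0"].mean()
        assert means["a"] == pytest.approx(means["b"])

    def test_missing_zero_condition_raises(self):
        df = pd.DataFrame({"1": [1.0, 2.0]})
        with pytest.raises(CalibrationError):
            convert_units(df, {"mode": "egfr", "zero_condition": "0"})
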