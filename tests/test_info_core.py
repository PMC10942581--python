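"""Unit and property tests for the discrete-channel information core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ceemi.info_core import (
    BinnedChannel,
    DegenerateDistributionError,
    InputDistribution,
    PopulationEnsemble,
    ResponseModel,
    ValidationError,
    capacity_of_channel,
    cell_specific_mi,
    cell_state_agnostic_mi,
    conditional_mi,
    discretize_responses,
    interaction_information,
    maximize_over_inputs,
    mutual_information,
    pooled_channel,
)

from oracles import blahut_arimoto


def H2(p):
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def bsc(flip):
    return BinnedChannel(
        np.array([0.0, 1.0, 2.0]),
        np.array([[1 - flip, flip], [flip, 1 - flip]]),
        np.array([1.0, 1.0]),
    )


UNIFORM2 = InputDistribution((0.0, 1.0), (0.5, 0.5))


class TestInputDistribution:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            InputDistribution((1.0, 0.5), (0.5, 0.5))  # not increasing
        with pytest.raises(ValidationError):
            InputDistribution((0.0, 1.0), (0.6, 0.6))  # sums to 1.2
        with pytest.raises(ValidationError):
            InputDistribution((0.0, 1.0), (-0.1, 1.1))

    def test_json_roundtrip(self):
        p = InputDistribution.uniform([0.0, 1.0, 5.0])
        assert InputDistribution.from_json(p.to_json()) == p


class TestResponseModel:
    def test_family_constraints(self):
        with pytest.raises(ValidationError):
            ResponseModel.gamma(0.0, 1.0)
        with pytest.raises(ValidationError):
            ResponseModel.negative_binomial(10.0, 5.0)  # underdispersed
        assert ResponseModel.poisson(5.0).variance == 5.0

    def test_gamma_moment_matching(self):
        m = ResponseModel.gamma(100.0, 25.0)
        assert m.dist.mean() == pytest.approx(100.0)
        assert m.dist.var() == pytest.approx(25.0)

    def test_negative_binomial_moments_and_poisson_fallback(self):
        m = ResponseModel.negative_binomial(50.0, 80.0)
        assert m.dist.mean() == pytest.approx(50.0)
        assert m.dist.var() == pytest.approx(80.0)
        near = ResponseModel.negative_binomial(50.0, 50.0 + 1e-12)
        assert near.dist.dist.name == "poisson"


class TestDiscretize:
    def test_bin_width_is_fraction_of_smallest_iqr(self):
        a = ResponseModel.gamma(1000.0, 15.0**2)
        b = ResponseModel.gamma(2000.0, 30.0**2)
        ch = discretize_responses([a, b], bin_frac=0.05)
        assert ch.bin_width == pytest.approx(0.05 * min(a.iqr(), b.iqr()))

    def test_coverage_captured_before_renormalization(self):
        models = [
            ResponseModel.gamma(100.0, 400.0),
            ResponseModel.gamma(300.0, 900.0),
        ]
        ch = discretize_responses(models, coverage=0.9995)
        assert np.all(ch.row_mass >= 0.9995 - 1e-12)
        assert np.allclose(ch.cond_probs.sum(axis=1), 1.0)

    def test_poisson_bins_match_pmf_summation(self):
        m = ResponseModel.poisson(5.0)
        ref = ResponseModel.poisson(8.0)
        ch = discretize_responses([m, ref])
        ks = np.arange(0, 60)
        pmf = stats.poisson(5.0).pmf(ks)
        # aggregate pmf into the channel's bins and compare row 0
        idx = np.digitize(ks, ch.bin_edges) - 1
        ok = (idx >= 0) & (idx < ch.n_bins)
        agg = np.bincount(idx[ok], weights=pmf[ok], minlength=ch.n_bins)
        assert np.abs(agg / agg.sum() - ch.cond_probs[0]).max() < 1e-9

    def test_degenerate_iqr_raises(self):
        good = ResponseModel.gamma(100.0, 25.0)
        degen = ResponseModel.gamma(100.0, 100.0 * 100.0 * 1e-22)
        with pytest.raises(DegenerateDistributionError):
            discretize_responses([good, degen])

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValidationError):
            ResponseModel.gamma(float("nan"), 1.0)


class TestMutualInformation:
    def test_identical_rows_give_zero(self):
        ch = BinnedChannel(
            np.array([0.0, 1.0, 2.0]),
            np.array([[0.4, 0.6], [0.4, 0.6]]),
            np.ones(2),
        )
        assert mutual_information(ch, UNIFORM2) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_deterministic_rows_give_one_bit(self):
        ch = BinnedChannel(
            np.array([0.0, 1.0, 2.0]),
            np.array([[1.0, 0.0], [0.0, 1.0]]),
            np.ones(2),
        )
        assert mutual_information(ch, UNIFORM2) == pytest.approx(1.0)

    def test_binary_symmetric_channel_closed_form(self):
        assert mutual_information(bsc(0.25), UNIFORM2) == pytest.approx(
            1 - H2(0.25), abs=1e-12
        )

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValidationError):
            mutual_information(bsc(0.1), InputDistribution.uniform([0, 1, 2]))

    @given(
        st.integers(2, 5),
        st.integers(2, 8),
        st.integers(0, 10_000),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounds_and_permutation_invariance(self, n_doses, n_bins, seed):
        """MI is within [0, min(log2 #doses, H(X))] and invariant under any
        relabeling of the output bins."""
        r = np.random.default_rng(seed)
        Q = r.dirichlet(np.ones(n_bins), size=n_doses)
        p = r.dirichlet(np.ones(n_doses))
        edges = np.arange(n_bins + 1, dtype=float)
        ch = BinnedChannel(edges, Q, np.ones(n_doses))
        pu = InputDistribution(tuple(np.arange(n_doses, dtype=float)), tuple(p))
        mi = mutual_information(ch, pu)
        P = p @ Q
        hx = -(P[P > 0] * np.log2(P[P > 0])).sum()
        assert -1e-12 <= mi <= min(math.log2(n_doses), hx) + 1e-9
        perm = r.permutation(n_bins)
        ch2 = BinnedChannel(edges, Q[:, perm], np.ones(n_doses))
        assert mutual_information(ch2, pu) == pytest.approx(mi, abs=1e-12)

    def test_bin_refinement_stability(self, toy_input):
        """Halving the bin width moves MI by < 0.02 bits on gamma channels."""
        models = [
            ResponseModel.gamma(m, (0.3 * m) ** 2) for m in (50.0, 150.0, 450.0)
        ]
        pu = InputDistribution.uniform([1.0, 2.0, 3.0])
        mi1 = mutual_information(discretize_responses(models, bin_frac=0.05), pu)
        mi2 = mutual_information(discretize_responses(models, bin_frac=0.025), pu)
        assert abs(mi1 - mi2) < 0.02


class TestEnsembleQuantities:
    def _fwd(self, doses):
        from ceemi.toy_model import dose_response_models

        return lambda th: dose_response_models(th, doses)

    def test_identical_cells_icee_equals_icsa(self, toy_input):
        from ceemi.toy_model import ToyCellState

        ens = PopulationEnsemble(tuple([ToyCellState(R0=500.0)] * 4))
        fwd = self._fwd(toy_input.doses)
        icee = conditional_mi(ens, fwd, toy_input)
        icsa = cell_state_agnostic_mi(ens, fwd, toy_input)
        assert icee == pytest.approx(icsa, abs=1e-6)
        assert interaction_information(ens, fwd, toy_input) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_icee_is_weighted_mean_of_cell_mis(self, toy_input):
        from ceemi.toy_model import ToyCellState, dose_response_models

        thetas = [ToyCellState(R0=r) for r in (200.0, 500.0, 900.0)]
        w = np.array([0.2, 0.5, 0.3])
        ens = PopulationEnsemble(tuple(thetas), w)
        fwd = self._fwd(toy_input.doses)
        per_cell = [
            cell_specific_mi(dose_response_models(t, toy_input.doses), toy_input)
            for t in thetas
        ]
        assert conditional_mi(ens, fwd, toy_input) == pytest.approx(
            float(w @ per_cell), abs=1e-12
        )

    def test_heterogeneous_ensemble_interaction_nonpositive(
        self, toy_ensemble_cv03, toy_input
    ):
        fwd = self._fwd(toy_input.doses)
        ii = interaction_information(toy_ensemble_cv03, fwd, toy_input)
        assert ii < 0

    def test_single_cell_ensemble_matches_cell_specific(self, toy_input):
        from ceemi.toy_model import ToyCellState, dose_response_models

        theta = ToyCellState(R0=400.0)
        ens = PopulationEnsemble((theta,))
        fwd = self._fwd(toy_input.doses)
        direct = cell_specific_mi(
            dose_response_models(theta, toy_input.doses), toy_input
        )
        assert cell_state_agnostic_mi(ens, fwd, toy_input) == pytest.approx(
            direct, abs=1e-9
        )

    def test_mixture_can_fall_below_every_cell(self):
        """Well-separated per-cell responses whose pooled rows overlap
        across doses drive I_CSA below the worst single cell."""
        doses = [1.0, 2.0]
        # cell 1: responds 100 -> 300; cell 2: responds 300 -> 100 (swapped)
        cells = [
            [ResponseModel.gamma(100.0, 25.0), ResponseModel.gamma(300.0, 25.0)],
            [ResponseModel.gamma(300.0, 25.0), ResponseModel.gamma(100.0, 25.0)],
        ]
        pu = InputDistribution.uniform(doses)
        per_cell = [cell_specific_mi(ms, pu) for ms in cells]
        pooled = pooled_channel(cells)
        icsa = mutual_information(pooled, pu)
        assert icsa < min(per_cell)
        assert np.allclose(pooled.cond_probs.sum(axis=1), 1.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValidationError):
            PopulationEnsemble(())


class TestCapacity:
    def test_flat_channel_capacity_zero(self):
        ch = BinnedChannel(
            np.array([0.0, 1.0, 2.0]),
            np.array([[0.3, 0.7], [0.3, 0.7], [0.3, 0.7]]),
            np.ones(3),
        )
        res = capacity_of_channel(ch, seed=0)
        assert res.value_bits == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("flip", [0.1, 0.25])
    def test_bsc_capacity_closed_form(self, flip):
        res = capacity_of_channel(bsc(flip), seed=0)
        assert res.value_bits == pytest.approx(1 - H2(flip), abs=1e-6)
        assert res.p_opt.p == pytest.approx([0.5, 0.5], abs=1e-4)
        assert res.converged

    def test_random_channels_match_blahut_arimoto(self):
        r = np.random.default_rng(7)
        for _ in range(15):
            Q = r.dirichlet(np.ones(8), size=4)
            cap, _ = blahut_arimoto(Q)
            res = maximize_over_inputs([Q], [1.0], [0, 1, 2, 3], seed=1)
            assert res.value_bits == pytest.approx(cap, abs=1e-4)

    def test_simplex_feasibility(self):
        r = np.random.default_rng(3)
        Q = r.dirichlet(np.ones(16), size=6)
        res = maximize_over_inputs([Q], [1.0], list(range(6)), seed=2)
        p = res.p_opt.p
        assert np.all(p >= -1e-8)
        assert p.sum() == pytest.approx(1.0, abs=1e-8)
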