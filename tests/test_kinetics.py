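"""Unit and property tests for the reaction networks and forward simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetylkinetics import (
    ConfigurationError,
    GGM_SPECIES,
    PhProfile,
    RateConstants,
    TRISACCHARIDE_SPECIES,
    build_rate_matrix,
    constants_preset,
    equilibrium_O2_fraction,
    oh_correction_factor,
    simulate,
    simulate_closed_form,
    species_for,
    species_rates,
    transformed_time,
)

HYPOTHESIS_SETTINGS = settings(max_examples=30, deadline=None, derandomize=True)

rate_constants_strategy = st.builds(
    RateConstants,
    *(st.floats(min_value=0.0, max_value=2.0, allow_nan=False) for _ in range(5)),
)


def random_simplex(rng, n):
    raw = rng.dirichlet(np.ones(n))
    return raw


# ---------------------------------------------------------------------------
# pH correction and transformed time
# ---------------------------------------------------------------------------

class TestOhCorrectionFactor:
    def test_identity_at_reference_ph(self):
        assert oh_correction_factor(8.0) == 1.0

    def test_ph_drop_from_795_to_775_reduces_rates_by_37_percent(self):
        ratio = oh_correction_factor(7.75) / oh_correction_factor(7.95)
        assert ratio == pytest.approx(10 ** -0.2, rel=1e-12)
        assert 100 * (1 - ratio) == pytest.approx(36.90, abs=0.01)

    def test_direct_evaluation(self):
        assert oh_correction_factor(7.95) == pytest.approx(0.8912509381, rel=1e-9)

    @pytest.mark.parametrize("ph", [-0.1, 14.2])
    def test_rejects_ph_outside_physical_range(self, ph):
        with pytest.raises(ValueError):
            oh_correction_factor(ph)

    @given(st.floats(min_value=0.0, max_value=13.9))
    @HYPOTHESIS_SETTINGS
    def test_strictly_increasing_in_ph(self, ph):
        assert oh_correction_factor(ph + 0.1) > oh_correction_factor(ph)


class TestTransformedTime:
    def test_constant_reference_ph_is_identity(self):
        profile = PhProfile.constant(8.0)
        assert transformed_time(profile, 100.0) == pytest.approx(100.0, rel=1e-12)

    def test_constant_ph7_scales_time_by_tenth(self):
        profile = PhProfile.constant(7.0)
        assert transformed_time(profile, 10.0) == pytest.approx(1.0, rel=1e-12)

    def test_linear_drift_matches_fine_grid_quadrature(self):
        profile = PhProfile.from_points([(0.0, 7.95), (672.0, 7.75)])
        grid = np.linspace(0.0, 672.0, 200_001)
        oracle = np.trapezoid(10.0 ** (np.interp(grid, profile.times, profile.ph) - 8.0), grid)
        assert transformed_time(profile, 672.0) == pytest.approx(oracle, rel=1e-9)

    def test_zero_at_origin_and_monotone(self):
        profile = PhProfile.from_points([(0.0, 7.95), (100.0, 7.5), (300.0, 7.8)])
        taus = transformed_time(profile, np.linspace(0, 400, 50))
        assert taus[0] == 0.0
        assert np.all(np.diff(taus) > 0)

    def test_empty_profile_is_rejected(self):
        with pytest.raises(ConfigurationError):
            PhProfile(times=np.array([]), ph=np.array([]))

    def test_negative_time_is_rejected(self):
        with pytest.raises(ValueError):
            transformed_time(PhProfile.constant(8.0), -1.0)


# ---------------------------------------------------------------------------
# Rate matrix and derivatives
# ---------------------------------------------------------------------------

class TestRateMatrix:
    @given(rate_constants_strategy, st.sampled_from(["trisaccharide", "ggm"]))
    @HYPOTHESIS_SETTINGS
    def test_columns_sum_to_zero(self, constants, kind):
        K = build_rate_matrix(constants, kind)
        assert np.abs(K.sum(axis=0)).max() < 1e-12
        off_diag = K - np.diag(np.diag(K))
        assert np.all(off_diag >= 0)

    def test_trisaccharide_entries_from_published_constants(self, tri_truth):
        K = build_rate_matrix(tri_truth, "trisaccharide")
        i = {s: k for k, s in enumerate(TRISACCHARIDE_SPECIES)}
        assert K[i["1b"], i["1a"]] == pytest.approx(2.06e-3)
        # 1a loses k_O2_O6 plus two secondary-hydrolysis channels
        assert K[i["1a"], i["1a"]] == pytest.approx(-(2.06e-3 + 2 * 1.56e-3))

    def test_ggm_entries_from_published_constants(self, ggm_truth_2mg):
        K = build_rate_matrix(ggm_truth_2mg, "ggm")
        i = {s: k for k, s in enumerate(GGM_SPECIES)}
        assert K[i["B"], i["A"]] == pytest.approx(1.60)
        assert K[i["A"], i["B"]] == pytest.approx(1.00)

    def test_unknown_model_kind(self, tri_truth):
        with pytest.raises(ConfigurationError):
            build_rate_matrix(tri_truth, "disaccharide")


class TestSpeciesRates:
    def test_pure_1a_derivatives(self, tri_truth):
        state = np.zeros(7)
        state[0] = 1.0
        rates = species_rates(state, tri_truth, 1.0, "trisaccharide")
        expected = np.array([-5.18e-3, 2.06e-3, 0.0, 1.56e-3, 1.56e-3, 0.0, 0.0])
        np.testing.assert_allclose(rates, expected, atol=1e-15)

    def test_ggm_equilibrium_mixture_derivatives(self, ggm_truth_2mg):
        rates = species_rates(np.array([0.39, 0.61, 0.0, 0.0]), ggm_truth_2mg, 1.0, "ggm")
        np.testing.assert_allclose(
            rates, [-0.0141014, 0.0129264, 9.15e-4, 2.60e-4], rtol=1e-10
        )

    @given(rate_constants_strategy, st.sampled_from(["trisaccharide", "ggm"]), st.integers(0, 2**31 - 1))
    @HYPOTHESIS_SETTINGS
    def test_derivatives_conserve_mass(self, constants, kind, seed):
        state = random_simplex(np.random.default_rng(seed), len(species_for(kind)))
        rates = species_rates(state, constants, 0.7, kind)
        assert abs(rates.sum()) < 1e-12

    def test_state_length_mismatch(self, tri_truth):
        with pytest.raises(ValueError):
            species_rates(np.zeros(4), tri_truth, 1.0, "trisaccharide")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_null_dynamics_is_constant(self):
        constants = RateConstants(0, 0, 0, 0, 0)
        c0 = np.array([0.3, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1])
        traj = simulate(constants, c0, PhProfile.constant(8.0), [0.0, 10.0, 500.0], "trisaccharide")
        np.testing.assert_allclose(traj.states, np.tile(c0, (3, 1)), atol=1e-9)

    def test_matches_matrix_exponential_oracle(self, tri_truth):
        c0 = np.eye(7)[0]
        profile = PhProfile.constant(8.0)
        times = np.geomspace(0.1, 1000.0, 30)
        bdf = simulate(tri_truth, c0, profile, times, "trisaccharide")
        exact = simulate_closed_form(tri_truth, c0, profile, times, "trisaccharide")
        assert np.abs(bdf.states - exact.states).max() < 1e-6

    def test_deacetylated_product_is_absorbing(self, tri_truth):
        c0 = np.eye(7)[0]
        traj = simulate(tri_truth, c0, PhProfile.constant(8.0), [1e5], "trisaccharide")
        assert traj.states[0, -1] == pytest.approx(1.0, abs=1e-4)

    def test_mass_conserved_to_1e8_over_1000_hours(self, tri_truth, ggm_truth_2mg):
        profile = PhProfile.from_points([(0.0, 7.95), (672.0, 7.75)])
        times = np.linspace(0.0, 1000.0, 40)
        tri = simulate(tri_truth, np.eye(7)[0], profile, times, "trisaccharide")
        ggm = simulate(
            ggm_truth_2mg, np.array([0.39, 0.61, 0.0, 0.0]), profile, times, "ggm"
        )
        for traj, total in ((tri, 1.0), (ggm, 1.0)):
            assert np.abs(traj.states.sum(axis=1) - total).max() < 1e-8

    def test_deacetylated_fraction_is_monotone(self, tri_truth, ggm_truth_2mg):
        profile = PhProfile.constant(7.9)
        times = np.linspace(0.0, 1000.0, 60)
        tri = simulate(tri_truth, np.eye(7)[1], profile, times, "trisaccharide")
        assert np.all(np.diff(tri.states[:, -1]) >= -1e-10)
        ggm = simulate(ggm_truth_2mg, np.array([0.39, 0.61, 0, 0.0]), profile, times, "ggm")
        assert np.all(np.diff(ggm.states[:, -1]) >= -1e-10)


class TestSimulateClosedForm:
    def test_time_zero_returns_initial_state(self, tri_truth):
        c0 = np.array([0.5, 0.5, 0, 0, 0, 0, 0.0])
        traj = simulate_closed_form(tri_truth, c0, PhProfile.constant(8.0), [0.0], "trisaccharide")
        np.testing.assert_array_equal(traj.states[0], c0)

    def test_time_reparametrization_invariance(self, tri_truth):
        """A uniformly lower pH only rescales the time axis, not the path."""
        c0 = np.eye(7)[0]
        times = np.geomspace(1.0, 500.0, 12)
        ref = simulate_closed_form(tri_truth, c0, PhProfile.constant(8.0), times, "trisaccharide")
        slow_profile = PhProfile.constant(7.7)
        # at pH 7.7 the same states are reached at t / 10^-0.3
        stretched = times / 10 ** (7.7 - 8.0)
        slow = simulate_closed_form(tri_truth, c0, slow_profile, stretched, "trisaccharide")
        np.testing.assert_allclose(slow.states, ref.states, atol=1e-10)

    def test_agrees_with_fine_step_euler(self, tri_truth):
        c0 = np.eye(7)[1]
        profile = PhProfile.constant(8.0)
        K = build_rate_matrix(tri_truth, "trisaccharide")
        step = 1e-3
        state = c0.astype(float)
        for _ in range(int(10.0 / step)):
            state = state + step * (K @ state)
        exact = simulate_closed_form(tri_truth, c0, profile, [10.0], "trisaccharide")
        np.testing.assert_allclose(exact.states[0], state, atol=1e-5)

    @given(st.integers(0, 2**31 - 1))
    @HYPOTHESIS_SETTINGS
    def test_oracle_equivalence_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        constants = RateConstants(*rng.uniform(0.0, 2.0, 5))
        kind = "trisaccharide" if rng.random() < 0.5 else "ggm"
        c0 = random_simplex(rng, len(species_for(kind)))
        t_end = rng.uniform(10.0, 300.0)
        profile = PhProfile.from_points(
            [(0.0, rng.uniform(7.5, 8.2)), (t_end, rng.uniform(7.3, 8.0))]
        )
        times = np.linspace(0.0, t_end, 7)
        bdf = simulate(constants, c0, profile, times, kind)
        exact = simulate_closed_form(constants, c0, profile, times, kind)
        assert np.abs(bdf.states - exact.states).max() < 1e-6


class TestEquilibriumO2Fraction:
    def test_symmetric_constants_give_half(self):
        constants = RateConstants(0, 1.3, 1.3, 0, 0)
        assert equilibrium_O2_fraction(constants) == pytest.approx(0.5)

    def test_published_trisaccharide_ratio_is_65_35(self, tri_truth):
        assert equilibrium_O2_fraction(tri_truth) == pytest.approx(0.6505, abs=5e-4)

    def test_published_ggm_ratio(self, ggm_truth_2mg):
        assert equilibrium_O2_fraction(ggm_truth_2mg) == pytest.approx(0.6154, abs=5e-4)

    def test_undefined_without_migration(self):
        with pytest.raises(ValueError):
            equilibrium_O2_fraction(RateConstants(1e-3, 0, 0, 1e-3, 1e-3))

    def test_fast_exchange_limit_reaches_equilibrium_ratio(self):
        constants = RateConstants(1e-3, 50.0, 30.0, 1e-3, 1e-3)
        c0 = np.eye(7)[1]  # start in 1b, all acetyl on O3 side
        t_eq = 10.0 / (constants.k_O3_O2 + constants.k_O2_O3)
        traj = simulate_closed_form(
            constants, c0, PhProfile.constant(8.0), [t_eq, 2 * t_eq], "trisaccharide"
        )
        target = equilibrium_O2_fraction(constants)
        for row in traj.states:
            c_1b, c_1c = row[1], row[2]
            assert c_1c / (c_1b + c_1c) == pytest.approx(target, abs=0.01)


class TestRateConstantsValidation:
    def test_negative_constant_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(-1e-3, 1, 1, 1e-3, 1e-3)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(math.nan, 1, 1, 1e-3, 1e-3)

    def test_preset_round_trip(self):
        preset = constants_preset("table2-10mg")
        assert RateConstants.from_dict(preset.as_dict()) == preset
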