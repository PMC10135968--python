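"""Unit and property tests for the two-state co-agonist model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coagonist.model import (
    ActivationPair,
    EnergyContext,
    ModulatorParams,
    efficacy_from_activation,
    efficacy_from_free_energy,
    fold_potentiation_curve,
    free_energy,
    saturating_state_function,
    state_function,
)

K_R = 1e-6  # a typical micromolar dissociation constant


def params(c, N=2, K_R=K_R):
    return ModulatorParams(name="test", K_R=K_R, c=c, N=N)


class TestStateFunction:
    def test_zero_concentration_is_identity(self):
        assert state_function(0.05, 0.0, params(c=0.1)) == pytest.approx(0.05)

    def test_neutral_efficacy_leaves_activity_unchanged(self):
        assert state_function(0.30, 50 * K_R, params(c=1.0)) == pytest.approx(0.30)

    def test_saturating_limit_matches_hand_value(self):
        # 1 / (1 + 19 * 0.01) at p_bg = 0.05, c = 0.1, N = 2
        got = state_function(0.05, 1000 * K_R, params(c=0.1))
        assert got == pytest.approx(0.8403, abs=2e-3)

    @pytest.mark.parametrize("c,increasing", [(0.3, True), (3.0, False)])
    def test_monotone_in_concentration(self, c, increasing):
        concs = np.geomspace(1e-9, 1e-3, 50)
        values = [state_function(0.1, conc, params(c=c)) for conc in concs]
        diffs = np.diff(values)
        assert np.all(diffs > 0) if increasing else np.all(diffs < 0)

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            state_function(1.2, 0.0, params(c=0.5))

    def test_rejects_nonpositive_efficacy(self):
        with pytest.raises(ValueError):
            params(c=0.0)

    def test_thousandfold_kr_approximates_saturation(self):
        # the occupancy bracket approaches c at rate ~|1 - c|/1000, so
        # 1000x K_R is within 1e-3 of the limit for potentiator efficacies
        for c in (0.05, 0.1, 0.5, 0.9):
            full = state_function(0.07, 1000 * K_R, params(c=c))
            limit = saturating_state_function(0.07, c, 2)
            assert full == pytest.approx(limit, rel=1e-3)
        # for c > 1 the convergence is correspondingly slower
        full = state_function(0.07, 1000 * K_R, params(c=2.0))
        limit = saturating_state_function(0.07, 2.0, 2)
        assert full == pytest.approx(limit, rel=5e-3)


class TestSaturatingStateFunction:
    @pytest.mark.parametrize(
        "p_bg,c,N,expected",
        [
            (0.05, 0.1, 2, 0.8403),  # 1/(1 + 19*0.01)
            (0.5, 1.0, 2, 0.5),
            (0.25, 2.161, 2, 0.0666),  # 1/(1 + 3*2.161^2), inhibitory direction
        ],
    )
    def test_hand_evaluated_values(self, p_bg, c, N, expected):
        assert saturating_state_function(p_bg, c, N) == pytest.approx(expected, abs=1e-4)

    def test_vectorized_over_background(self):
        grid = np.array([0.05, 0.1, 0.5])
        out = saturating_state_function(grid, 0.1, 2)
        assert out.shape == grid.shape
        assert out[0] == pytest.approx(0.8403, abs=1e-4)


class TestEfficacyInversion:
    def test_published_group_mean_recovered(self):
        # background 0.08, modulated 0.10 -> c close to the reported 0.883;
        # the small residual reflects per-cell averaging in the report
        c = efficacy_from_activation(ActivationPair(0.08, 0.10), N=2)
        assert c == pytest.approx(0.883, abs=0.01)

    def test_no_modulation_gives_unit_efficacy(self):
        assert efficacy_from_activation(ActivationPair(0.2, 0.2), N=2) == pytest.approx(1.0)

    def test_requires_saturating_flag(self):
        pair = ActivationPair(0.1, 0.3, concentration=1e-6, saturating=False)
        with pytest.raises(ValueError, match="saturating"):
            efficacy_from_activation(pair, N=2)

    @given(
        p_bg=st.floats(0.001, 0.999),
        c=st.floats(0.01, 100.0),
        N=st.sampled_from([1, 2, 4]),
    )
    def test_round_trip_inverts_saturating_state_function(self, p_bg, c, N):
        p_mod = saturating_state_function(p_bg, c, N)
        pair = ActivationPair(p_bg, p_mod)
        recovered = efficacy_from_activation(pair, N=N)
        if 1e-7 < p_mod < 1.0 - 1e-7:
            # exact inversion wherever the modulated probability is
            # representable away from saturation
            assert recovered == pytest.approx(c, rel=1e-9)
        else:
            # within ~1e-7 of 0/1 the float64 spacing around 1 caps the
            # recoverable precision at ~eps / (N * (1 - p_mod))
            assert recovered == pytest.approx(c, rel=1e-3)


class TestFreeEnergy:
    @pytest.mark.parametrize(
        "c,N,expected",
        [(0.100, 2, -2.72), (0.302, 4, -2.84)],
    )
    def test_published_energies(self, c, N, expected):
        assert free_energy(c, N) == pytest.approx(expected, abs=0.02)

    def test_neutral_efficacy_has_zero_energy(self):
        for N in (1, 2, 4):
            assert free_energy(1.0, N) == 0.0

    def test_sign_follows_stabilization(self):
        assert free_energy(0.5, 2) < 0 < free_energy(2.0, 2)

    @given(c1=st.floats(0.01, 100), c2=st.floats(0.01, 100))
    def test_log_additivity_at_single_site(self, c1, c2):
        total = free_energy(c1 * c2, N=1)
        assert total == pytest.approx(free_energy(c1, 1) + free_energy(c2, 1), abs=1e-9)

    def test_inverse(self):
        ctx = EnergyContext()
        dG = free_energy(0.3, 2, ctx)
        assert efficacy_from_free_energy(dG, 2, ctx) == pytest.approx(0.3, rel=1e-12)

    def test_rejects_nonpositive_efficacy(self):
        with pytest.raises(ValueError):
            free_energy(0.0, 2)

    def test_custom_rt(self):
        ctx = EnergyContext(RT=0.6)
        assert free_energy(0.1, 2, ctx) == pytest.approx(2 * 0.6 * math.log(0.1))


class TestFoldPotentiation:
    def test_low_background_fold_matches_hand_value(self):
        table = fold_potentiation_curve(0.1, 2, [0.05])
        assert table["fold"].iloc[0] == pytest.approx(16.81, abs=0.01)

    def test_neutral_compound_has_unit_fold_everywhere(self):
        table = fold_potentiation_curve(1.0, 2, np.linspace(0.05, 0.95, 10))
        assert np.allclose(table["fold"], 1.0)

    def test_fold_decreases_with_background_for_potentiator(self):
        grid = np.linspace(0.01, 0.99, 100)
        table = fold_potentiation_curve(0.1, 2, grid)
        assert np.all(np.diff(table["fold"]) < 0)

    def test_ceiling_effect(self):
        table = fold_potentiation_curve(0.1, 2, [0.999])
        assert table["fold"].iloc[0] == pytest.approx(1.0, abs=2e-3)

    def test_rejects_boundary_grid(self):
        with pytest.raises(ValueError):
            fold_potentiation_curve(0.1, 2, [0.0, 0.5])
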