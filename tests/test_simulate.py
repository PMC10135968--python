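"""Tests for the synthetic-experiment generator and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from coagonist.analysis import analyze_profiles
from coagonist.cycle import mutant_cycle_report
from coagonist.model import free_energy, saturating_state_function
from coagonist.normalize import normalize_amplitude
from coagonist.presets import SIM_PRESETS, WILDTYPE
from coagonist.simulate import (
    SimSpec,
    additive_mutant_efficacies,
    mutant_efficacy,
    simulate_amplitudes,
    simulate_cells,
    simulate_study,
)


def spec(**kwargs):
    base = dict(
        receptor="wt", compound="NS-1738", n_cells=10,
        p_background_mean=0.05, p_background_sd=0.03, c_true=0.561, N=2, seed=42,
    )
    base.update(kwargs)
    return SimSpec(**base)


class TestSimulateCells:
    def test_noise_free_degenerate_case(self):
        s = spec(p_background_sd=0.0, measurement_cv=0.0)
        cells = simulate_cells(s)
        expected = saturating_state_function(0.05, 0.561, 2)
        assert np.allclose(cells.p_modulated, expected)
        assert cells.p_background.nunique() == 1

    def test_same_seed_reproduces_table(self):
        a = simulate_cells(spec())
        b = simulate_cells(spec())
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = simulate_cells(spec(seed=1))
        b = simulate_cells(spec(seed=2))
        assert not a.p_background.equals(b.p_background)

    def test_high_constitutive_cells_get_direct_activation(self):
        s = spec(p_constitutive_mean=0.25, p_constitutive_sd=0.05)
        cells = simulate_cells(s)
        assert (cells.protocol == "direct_activation").all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            spec(n_cells=1)
        with pytest.raises(ValueError):
            spec(c_true=-0.5)

    def test_parameter_recovery_wildtype_conditions(self):
        s = spec(n_cells=200, measurement_cv=0.05, seed=7)
        per_cell, _ = analyze_profiles(simulate_cells(s))
        assert per_cell["c"].mean() == pytest.approx(0.561, abs=0.1)

    @pytest.mark.parametrize("c_true", [0.1, 0.3, 0.56, 0.72, 1.0, 2.0])
    def test_recovery_is_unbiased_across_efficacies(self, c_true):
        s = spec(n_cells=200, c_true=c_true, measurement_cv=0.05, seed=11)
        per_cell, _ = analyze_profiles(simulate_cells(s))
        assert per_cell["c"].mean() == pytest.approx(c_true, rel=0.05)


class TestSimulateAmplitudes:
    def test_noise_free_round_trip(self):
        s = spec(measurement_cv=0.0, p_background_sd=0.0)
        amps = simulate_amplitudes(s, full_anchor=-5000.0, zero_anchor=-50.0)
        cells = simulate_cells(s)
        mod = amps[amps.condition == "modulated"].reset_index(drop=True)
        recovered = [
            normalize_amplitude(a, -50.0, -5000.0) for a in mod.amplitude_nA
        ]
        assert np.allclose(recovered, cells.p_modulated)

    def test_affine_shifted_anchors_give_identical_probabilities(self):
        s = spec(measurement_cv=0.0)
        a = simulate_amplitudes(s, full_anchor=-5000.0, zero_anchor=-50.0)
        b = simulate_amplitudes(s, full_anchor=-4950.0, zero_anchor=0.0)
        pa = [
            normalize_amplitude(x, -50.0, -5000.0)
            for x in a[a.condition == "background"].amplitude_nA
        ]
        pb = [
            normalize_amplitude(x, 0.0, -4950.0)
            for x in b[b.condition == "background"].amplitude_nA
        ]
        assert np.allclose(pa, pb)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            simulate_amplitudes(spec(), full_anchor=-50.0, zero_anchor=-50.0)


def ns1738_study_specs(seed):
    specs = [
        SimSpec(receptor=WILDTYPE, compound="NS-1738", seed=seed,
                **SIM_PRESETS[(WILDTYPE, "NS-1738")])
    ]
    for i, receptor in enumerate(["b2(F289T)", "a1(Y293C)", "g2L(F304C)"]):
        specs.append(
            SimSpec(receptor=receptor, compound="NS-1738", seed=seed + i + 1,
                    **SIM_PRESETS[(receptor, "NS-1738")])
        )
    return specs


class TestSimulateStudy:
    def test_minimum_n_smoke(self):
        specs = [
            SimSpec(receptor=r, compound="X", n_cells=2, p_background_mean=0.05,
                    p_background_sd=0.02, c_true=c, seed=3)
            for r, c in [("wt", 0.5), ("mut", 1.5)]
        ]
        study = simulate_study(specs)
        assert len(study.group_summaries) == 2
        table, verdict = mutant_cycle_report(study.group_summaries, "wt")
        assert np.isfinite(table.se).all()

    def test_nonadditive_ground_truth_detected(self):
        study = simulate_study(ns1738_study_specs(99))
        _, verdict = mutant_cycle_report(study.group_summaries, WILDTYPE)
        assert not verdict.additive

    def test_additive_ground_truth_mostly_accepted(self):
        c_wt = 0.561
        cs = additive_mutant_efficacies(c_wt, 3)
        accepted = 0
        reps = 50
        for rep in range(reps):
            specs = [
                SimSpec(receptor="wt", compound="X", n_cells=25,
                        p_background_mean=0.05, p_background_sd=0.03,
                        c_true=c_wt, seed=7000 + rep * 10)
            ]
            for i, c in enumerate(cs):
                specs.append(
                    SimSpec(receptor=f"mut{i}", compound="X", n_cells=5,
                            p_background_mean=0.06, p_background_sd=0.03,
                            c_true=c, seed=7001 + rep * 10 + i)
                )
            study = simulate_study(specs)
            _, verdict = mutant_cycle_report(study.group_summaries, "wt")
            accepted += verdict.additive
        assert accepted / reps >= 0.8

    def test_additive_construction_sums_to_wildtype_energy(self):
        c_wt = 0.561
        cs = additive_mutant_efficacies(c_wt, 3)
        dG_wt = free_energy(c_wt, 2)
        total_ddg = sum(free_energy(c, 2) - dG_wt for c in cs)
        assert total_ddg == pytest.approx(-dG_wt, abs=1e-12)

    def test_estimated_ddg_unbiased(self):
        """ddG from simulated mutant/wild-type pairs is unbiased."""
        c_wt, c_mut = 0.561, 1.5
        true_ddg = free_energy(c_mut, 2) - free_energy(c_wt, 2)
        estimates = []
        for rep in range(300):
            specs = [
                SimSpec(receptor="wt", compound="X", n_cells=10,
                        p_background_mean=0.05, p_background_sd=0.03,
                        c_true=c_wt, seed=20_000 + 3 * rep),
                SimSpec(receptor="mut", compound="X", n_cells=10,
                        p_background_mean=0.06, p_background_sd=0.03,
                        c_true=c_mut, seed=20_001 + 3 * rep),
            ]
            study = simulate_study(specs)
            by_receptor = {s.receptor: s for s in study.group_summaries}
            estimates.append(
                by_receptor["mut"].mean_dG - by_receptor["wt"].mean_dG
            )
        assert abs(np.mean(estimates) - true_ddg) < 0.05

    def test_mutant_efficacy_inverts_energy_shift(self):
        c_mut = mutant_efficacy(0.561, 1.92, N=2)
        shift = free_energy(c_mut, 2) - free_energy(0.561, 2)
        assert shift == pytest.approx(1.92, abs=1e-12)
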