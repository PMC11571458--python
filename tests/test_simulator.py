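import math
from dataclasses import replace

import numpy as np
import pytest

from foamimpact import (
    FoamParams,
    FoamState,
    SimulationError,
    StudyConfig,
    degrade,
    foam_force,
    generate_dataset,
    simulate_drop,
)
from foamimpact import TestCondition as Condition


def _cond(height=0.50, layers=1, rep=1, sid="t"):
    return Condition(height, layers, sid, rep)


class TestFoamForce:
    def test_zero_strain_gives_zero_force(self, default_params):
        assert foam_force(0.0, default_params, FoamState()) == 0.0

    def test_loading_closed_form(self):
        p = FoamParams(a_f=100.0, b_f=5.0, c_d=0.0)
        f = foam_force(0.5, p, FoamState())
        assert f == pytest.approx(100.0 * (math.exp(2.5) - 1.0), rel=1e-12)
        assert f == pytest.approx(1118.2, abs=0.1)

    def test_loading_monotone_through_densification(self, default_params):
        strains = np.linspace(0.01, 0.95, 200)
        forces = [foam_force(s, default_params, FoamState()) for s in strains]
        assert np.all(np.diff(forces) > 0)

    def test_stiffness_multiplier_scales_loading(self, default_params):
        damaged = FoamState(
            cumulative_plastic_energy=10.0, stiffness_multiplier=1.5
        )
        f0 = foam_force(0.4, default_params, FoamState())
        f1 = foam_force(0.4, default_params, damaged)
        assert f1 == pytest.approx(1.5 * f0, rel=1e-12)

    def test_unloading_below_loading_and_continuous_at_peak(self, default_params):
        ctx = (0.6, 0.2)
        at_peak = foam_force(0.6, default_params, FoamState(), "unloading", ctx)
        assert at_peak == pytest.approx(
            foam_force(0.6, default_params, FoamState()), rel=1e-12
        )
        for s in np.linspace(0.21, 0.59, 20):
            fu = foam_force(s, default_params, FoamState(), "unloading", ctx)
            fl = foam_force(s, default_params, FoamState())
            assert 0.0 <= fu <= fl
        assert foam_force(0.1, default_params, FoamState(), "unloading", ctx) == 0.0

    def test_full_compaction_rejected(self, default_params):
        with pytest.raises(SimulationError):
            foam_force(1.0, default_params, FoamState())


class TestSimulateDrop:
    def test_linear_limit_matches_spring_energy_balance(self, config):
        # b_f -> 0 with k = a_f*b_f/h held fixed, elastic, no noise:
        # m g (h_drop + x_pk) = 1/2 k x_pk^2 and F_pk = k x_pk
        k = 2.0e5  # N/m
        h = config.layer_thickness
        b_f = 1e-3
        p = FoamParams(
            a_f=k * h / b_f,
            b_f=b_f,
            c_d=0.0,
            n_u=1.0 + 1e-9,
            kappa=0.0,
            noise_force_sd=0.0,
            noise_disp_sd=0.0,
            specimen_cv=0.0,
        )
        m, g, h_drop = config.impactor_mass, config.gravity, 0.15
        trace, _ = simulate_drop(_cond(h_drop), p, FoamState(), config, seed=0)
        # closed-form positive root of 1/2 k x^2 - m g x - m g h_drop = 0
        x_pk = (m * g + math.sqrt((m * g) ** 2 + 2 * k * m * g * h_drop)) / k
        assert trace.truth.peak_displacement == pytest.approx(x_pk, rel=5e-3)
        assert trace.truth.peak_force == pytest.approx(k * x_pk, rel=5e-3)

    def test_zero_drop_settles_at_static_equilibrium(self, config, noise_free_params):
        trace, _ = simulate_drop(
            _cond(height=0.0), noise_free_params, FoamState(), config, seed=0
        )
        mg = config.impactor_mass * config.gravity
        assert trace.truth.peak_force == pytest.approx(mg, rel=0.01)

    def test_energy_bookkeeping_balances_drop_energy(self, config, noise_free_params):
        # absorbed energy at the peak equals m g (h_drop + x_pk): all kinetic
        # plus potential energy released up to the turning point
        for layers, h_drop in [(1, 0.15), (2, 0.25), (3, 0.50)]:
            trace, _ = simulate_drop(
                _cond(h_drop, layers), noise_free_params, FoamState(), config, seed=0
            )
            t = trace.truth
            expected = config.impactor_mass * config.gravity * (
                h_drop + t.peak_displacement
            )
            assert t.absorbed_energy == pytest.approx(expected, rel=0.01)
            assert 0.0 <= t.elastic_energy <= t.absorbed_energy
            assert t.plastic_energy >= 0.0

    def test_peak_force_decreases_with_layer_count(self, config, noise_free_params):
        for h_drop in config.drop_heights:
            peaks = []
            for layers in config.layer_counts:
                trace, _ = simulate_drop(
                    _cond(h_drop, layers),
                    noise_free_params,
                    FoamState(),
                    config,
                    seed=0,
                )
                peaks.append(trace.truth.peak_force)
            assert peaks[0] > peaks[1] > peaks[2]

    def test_repeated_strikes_leave_permanent_set_and_plastic_energy(
        self, config, noise_free_params
    ):
        state = FoamState()
        for rep in (1, 2, 3):
            trace, state = simulate_drop(
                _cond(0.50, 1, rep), noise_free_params, state, config, seed=0
            )
        assert state.permanent_set > 0.0
        assert state.cumulative_plastic_energy > 0.0
        assert state.stiffness_multiplier > 1.0


class TestDegrade:
    def test_zero_increment_without_crush_leaves_state_unchanged(self, default_params):
        s0 = FoamState()
        assert degrade(s0, 0.0, default_params) == s0

    def test_multiplier_formula(self):
        p = FoamParams(kappa=0.01)
        s = degrade(FoamState(), 20.0, p)
        assert s.stiffness_multiplier == pytest.approx(1.2)

    def test_multiplier_non_decreasing_over_cycles(self, default_params):
        s = FoamState()
        mults = []
        for _ in range(5):
            s = degrade(s, 3.0, default_params, crush_depth=0.012)
            mults.append(s.stiffness_multiplier)
        assert np.all(np.diff(mults) >= 0)

    def test_negative_increment_rejected(self, default_params):
        with pytest.raises(ValueError):
            degrade(FoamState(), -1.0, default_params)


class TestGenerateDataset:
    def test_default_design_yields_126_traces(self, config, default_params):
        traces, manifest = generate_dataset(config, default_params, seed=7)
        assert len(traces) == 126
        assert len(manifest) == 126

    def test_same_seed_reproduces_manifest_and_signals(self, config, default_params):
        t1, m1 = generate_dataset(config, default_params, seed=3)
        t2, m2 = generate_dataset(config, default_params, seed=3)
        assert m1.equals(m2)
        np.testing.assert_array_equal(t1[0].force, t2[0].force)
        np.testing.assert_array_equal(t1[-1].disp_a, t2[-1].disp_a)

    def test_no_variability_makes_specimens_identical(self, config, noise_free_params):
        cfg = StudyConfig(
            drop_heights=(0.25,),
            layer_counts=(2,),
            specimens_per_condition=2,
            repetitions_standard=1,
            extra_specimens_50cm=0,
        )
        traces, _ = generate_dataset(cfg, noise_free_params, seed=1)
        assert len(traces) == 2
        np.testing.assert_allclose(traces[0].force, traces[1].force)
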