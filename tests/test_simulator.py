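"""Coupled-system orchestration: wiring, determinism, dose response,
calibration."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import rosvgic.electrophysiology as ep
from rosvgic.expression import (
    ca_expression_rhs, k_expression_rhs, na_expression_rhs,
)
from rosvgic.phenotype import p_of_vm
from rosvgic.presets import get_preset
from rosvgic.signaling import (
    calcium_rhs, mrna_rhs_scenario1, mutation_rhs, ros_int_rhs, tf_rhs,
)
from rosvgic.simulator import (
    CalibrationError,
    K_IROS,
    ROS_HALF,
    ROS_SLOPE,
    SolverOptions,
    TRAJECTORY_COLUMNS,
    calibrate_preset,
    dose_response,
    plateau_vm,
    resting_vm,
    run_open_loop,
    slow_rhs,
)
from rosvgic.stressors import StressProtocol, ros_external, standard_protocol, zero_stress_protocol


class TestRhsWiring:
    def test_slow_rhs_matches_composed_module_operations(self):
        """The optimized RHS closure must agree with composing the public
        per-module rate operations according to the documented wiring."""
        preset = get_preset("HELA")
        proto = standard_protocol()
        opts = SolverOptions()
        rng = np.random.default_rng(3)
        exp_p, sig, phe, mem = (preset.expression, preset.signaling,
                                preset.phenotype, preset.membrane)
        for _ in range(20):
            t = float(rng.uniform(0, 48))
            y = np.array([
                rng.uniform(0, exp_p.g_Na_max), rng.uniform(0, exp_p.g_Ca_max),
                rng.uniform(0, exp_p.g_K_max), 0.0, rng.uniform(0, 0.01),
                rng.uniform(0, 50), rng.uniform(0, 5), rng.uniform(0, 0.05),
                rng.uniform(0, 0.2), rng.uniform(0, 1), rng.uniform(0, 1),
            ])
            got = slow_rhs(t, y, preset, proto, opts)

            g_na, g_ca, g_k = y[0], y[1], y[2]
            ros = ros_external(t, proto)
            act = ep.trpv_activation(ros, ros_half=ROS_HALF, ros_slope=ROS_SLOPE)
            v_rest = (preset.vm_initial - ep.LINEAR_VM_INTERCEPT) + ep.linear_vm(
                g_na / exp_p.g_Na_max, g_k / exp_p.g_K_max,
                mem.alpha_vm, mem.beta_vm)
            g_s = mem.g_TRPV * act
            v_gate = (mem.g_L * v_rest + g_s * mem.E_Ca + K_IROS * ros) / (mem.g_L + g_s)
            r_tot = ros + y[7]
            i_ca = max(0.0, ep.trpv_current(v_rest, act, mem.g_TRPV, mem.E_Ca))

            expected = [
                na_expression_rhs(g_na, r_tot, v_gate, exp_p),
                ca_expression_rhs(g_ca, r_tot, v_gate, exp_p),
                k_expression_rhs(g_k, r_tot, v_gate, exp_p),
                0.0,
                tf_rhs(y[4], r_tot, v_rest, sig),
                mrna_rhs_scenario1(y[5], g_na, g_ca, g_k, sig),
                mutation_rhs(y[5], sig),
                ros_int_rhs(y[7], g_na + g_ca + g_k, y[8], sig),
                calcium_rhs(y[8], i_ca, sig),
                p_of_vm(v_rest, phe) * y[4],
                y[7],
            ]
            np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-14)


class TestOpenLoop:
    def test_zero_stress_healthy_cell_is_homeostatic(self):
        traj = run_open_loop(get_preset("MCF10A"), zero_stress_protocol())
        vm = traj.frame["Vm_mV"].to_numpy()
        assert np.all(np.abs(vm - (-70.0)) < 1.0)
        prolif = traj.frame["proliferation"].to_numpy()
        assert np.all(np.abs(prolif - prolif[0]) < 0.01)

    def test_trajectory_schema_and_invariants(self, hela_standard_run):
        traj = hela_standard_run
        assert list(traj.frame.columns) == TRAJECTORY_COLUMNS
        assert np.all(np.diff(traj.times) > 0)
        assert len(traj.times) == len(traj.frame)
        st0 = traj.state(0)
        assert st0.Vm == pytest.approx(-60.0)
        assert st0.phase == 0

    def test_all_states_nonnegative(self, hela_standard_run):
        f = hela_standard_run.frame
        for col in ["g_Na", "g_K", "g_Ca", "TF", "mRNA", "mutation",
                    "ROS_int", "Ca_int", "proliferation"]:
            assert np.all(f[col].to_numpy() >= -1e-9), col

    def test_mutation_load_non_decreasing(self, hela_standard_run):
        mut = hela_standard_run.frame["mutation"].to_numpy()
        assert np.all(np.diff(mut) >= -1e-12)

    def test_determinism_bit_identical_output(self, tmp_path):
        from rosvgic.io import write_trajectory

        preset = get_preset("MCF10A")
        proto = standard_protocol(duration=6.0)
        paths = []
        for i in range(2):
            traj = run_open_loop(preset, proto)
            path = tmp_path / f"run{i}.csv"
            write_trajectory(traj, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_solver_tolerance_convergence(self, calibrated_hela):
        """Tightening tolerances and halving the step cap moves the final
        potential by less than 0.1 mV."""
        proto = standard_protocol()
        loose = run_open_loop(calibrated_hela, proto, SolverOptions())
        tight = run_open_loop(
            calibrated_hela, proto,
            SolverOptions(rtol=1e-8, atol=1e-11, max_step=0.0625),
        )
        assert abs(loose.final_vm - tight.final_vm) < 0.1

    def test_scenario2_dna_damage_pathway(self):
        opts = SolverOptions(scenario="dna_first")
        traj = run_open_loop(get_preset("HELA"), standard_protocol(duration=12.0), opts)
        f = traj.frame
        assert f["mRNA"].iloc[-1] > 0
        assert f["mutation"].iloc[-1] > 0
        # literal constant-rate variant accumulates VGIC faster from rest
        lit = run_open_loop(get_preset("HELA"), standard_protocol(duration=12.0),
                            replace(opts, eq13_literal=True))
        assert not np.allclose(lit.frame["ROS_int"], f["ROS_int"])

    def test_scenario1_no_stress_no_mutation(self):
        """ROS -> expression -> mRNA -> mutation: with zero external ROS and
        zero initial conductance the whole cascade stays silent."""
        traj = run_open_loop(get_preset("MCF10A"), zero_stress_protocol())
        assert traj.frame["mutation"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert traj.frame["mRNA"].iloc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_ghk_vm_model_runs_and_stays_in_reversal_range(self):
        opts = SolverOptions(vm_model="ghk_weighted")
        traj = run_open_loop(get_preset("HELA"), standard_protocol(duration=12.0), opts)
        vm = traj.frame["Vm_mV"].to_numpy()
        assert np.all(vm >= -90.0) and np.all(vm <= 60.0)

    def test_michaelis_menten_expression_model_runs(self):
        opts = SolverOptions(expression_model="michaelis_menten")
        traj = run_open_loop(get_preset("MCF10A"), standard_protocol(duration=12.0), opts)
        assert traj.frame["g_Na"].iloc[-1] > 0


class TestDoseResponse:
    def test_vm_ladder_monotone_depolarizing(self, calibrated_mcf10a):
        table = dose_response(calibrated_mcf10a, [0, 1, 2, 3, 5])
        assert np.all(np.diff(table["final_vm"]) > 0)

    def test_proliferation_monotone_for_single_target_lines(self, calibrated_mda):
        table = dose_response(calibrated_mda, [0, 1, 2, 5])
        assert np.all(np.diff(table["final_proliferation"]) >= 0)

    def test_zero_multiplier_reduces_to_unscaled_run(self):
        preset = get_preset("MCF10A")
        t0 = dose_response(preset, [0.0], duration=6.0)
        ref = run_open_loop(preset, replace(standard_protocol(duration=6.0),
                                            dose_multiplier=0.0))
        assert t0["final_vm"].iloc[0] == pytest.approx(ref.final_vm)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            dose_response(get_preset("MCF10A"), [-1.0])


class TestCrossLineComparison:
    def test_proliferation_ordering_under_shared_protocol(
            self, calibrated_fibroblast, calibrated_mcf10a, calibrated_gbm,
            calibrated_mda):
        """Stress-resistant stroma proliferates least; the aggressive
        sodium-dominant lines most."""
        finals = {}
        for preset in (calibrated_fibroblast, calibrated_mcf10a,
                       calibrated_gbm, calibrated_mda):
            traj = run_open_loop(preset, standard_protocol(1.0))
            finals[preset.name] = traj.final_proliferation
        assert finals["FIBROBLAST"] < finals["MCF10A"]
        assert finals["MCF10A"] < finals["GBM"]
        assert finals["GBM"] <= finals["MDA_MB_231"]


class TestCalibration:
    def test_idempotence(self, calibrated_hela):
        again = calibrate_preset(calibrated_hela)
        assert again.expression.expression_gain == pytest.approx(
            calibrated_hela.expression.expression_gain, rel=0.01)
        assert again.phenotype.alpha_P == pytest.approx(
            calibrated_hela.phenotype.alpha_P, rel=0.01)

    def test_parameter_recovery_after_perturbation(self, calibrated_hela):
        """Perturbing the fitted gain and recalibrating to the same targets
        recovers the original value."""
        perturbed = replace(
            calibrated_hela,
            expression=replace(calibrated_hela.expression,
                               expression_gain=1.7 * calibrated_hela.expression.expression_gain),
        )
        recovered = calibrate_preset(perturbed)
        assert recovered.expression.expression_gain == pytest.approx(
            calibrated_hela.expression.expression_gain, rel=0.01)

    def test_infeasible_baseline_names_stage(self):
        with pytest.raises(CalibrationError, match="stage 1"):
            calibrate_preset(get_preset("HELA"),
                             {"vm_baseline": -80.0, "vm_metric": "endpoint"})

    def test_plateau_above_map_maximum_names_stage(self):
        with pytest.raises(CalibrationError, match="stage 2"):
            calibrate_preset(get_preset("MCF10A"),
                             {"vm_baseline": -62.0, "vm_plateau": 100.0,
                              "vm_metric": "endpoint"})

    def test_fit_residuals_below_tolerance(self, calibrated_hela):
        traj = run_open_loop(calibrated_hela, standard_protocol(1.0),
                             SolverOptions(sample_dt=0.05))
        assert abs(plateau_vm(traj) - (-30.0)) < 1e-3


class TestSolverOptionsValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(vm_model="bogus"), dict(expression_model="bogus"),
        dict(scenario="bogus"), dict(sample_dt=0.0),
    ])
    def test_invalid_options_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverOptions(**kwargs)
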