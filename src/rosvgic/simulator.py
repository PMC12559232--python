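"""Coupled slow-system simulation, presets, experiments and calibration.

The transformation loop evolves on the hour timescale.  State vector
(order fixed):

    [g_Na, g_Ca, g_K, g_VGIC, TF, mRNA, mutation, ROS_int, Ca_int, A, B]

where A = int P(Vm) TF dt and B = int ROS_int dt are the proliferation
quadrature states (the index itself is max(0, alpha_P A - beta_P B),
exactly linear in the two growth gains because proliferation does not
feed back into the dynamics).

Two membrane potentials play distinct roles:

* the resting potential ``Vm`` — the slow, expression-determined value
  (linear map by default), which is what the trajectory reports and what
  the proliferation/cycle/TF tiers read;
* the instantaneous gating potential — the resting value superposed with
  the fast TRPV and ROS inward currents through the chord-conductance
  rule.  During a ROS pulse the TRPV conductance transiently depolarizes
  this potential past the transcriptional thresholds, which is how a
  hyperpolarized cell ever starts expressing sodium channels; between
  pulses it relaxes back to the resting value.

Calibration fits, per cell line, (1) the expression-gain multiplier so the
baseline-dose endpoint matches the line's documented value, (2) the
sodium voltage gain ``alpha_vm`` so the high-dose/plateau value matches,
and (3) the two growth gains by an exact 2x2 linear solve on the
quadrature integrals.  Stages 1-2 interact and are iterated (nested
bisection); everything is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import electrophysiology as ep
from .expression import ExpressionParams
from .phenotype import PhenotypeParams, cycle_phases_over
from .presets import CellLinePreset, default_calibration_targets, get_preset
from .signaling import SignalingParams
from .stressors import StressProtocol, dose_scaled, ros_external, standard_protocol, thermal_ros_drive

__all__ = [
    "SolverOptions",
    "SystemState",
    "Trajectory",
    "SimulationError",
    "CalibrationError",
    "run_open_loop",
    "dose_response",
    "calibrate_preset",
    "slow_rhs",
    "resting_vm",
    "plateau_vm",
    "TRAJECTORY_COLUMNS",
]

#: ROS-induced inward current gain (uA/cm2 per uM extracellular ROS)
K_IROS = 10.0
#: TRPV half-activation (uM) and logistic slope (uM); the edge is kept
#: sharp so sub-threshold baseline ROS produces essentially no activation
ROS_HALF = 0.02
ROS_SLOPE = ROS_HALF / 32.0
#: antioxidant scavenging gain of the controller's negative arm, 1/(uM.h);
#: strong enough that a full negative command effectively silences the
#: intracellular pool (otherwise channel-driven ROS feedback keeps the
#: expression ratchet creeping past any depolarized setpoint)
K_SCAV = 1000.0

TRAJECTORY_COLUMNS = [
    "t_h", "Vm_mV", "g_Na", "g_K", "g_Ca", "G_Na_norm", "G_K_norm",
    "TF", "mRNA", "mutation", "ROS_ext", "ROS_int", "Ca_int",
    "proliferation", "phase",
]

N_STATES = 11
(I_GNA, I_GCA, I_GK, I_GV, I_TF, I_MRNA, I_MUT, I_RI, I_CA, I_A, I_B) = range(N_STATES)


class SimulationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverOptions:
    """Integrator and model-wiring options for the slow system."""

    method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-9
    sample_dt: float = 0.01
    max_step: float = 0.125
    vm_model: str = "linear"              # linear | ghk_weighted | hh_full
    expression_model: str = "gated"       # gated | michaelis_menten
    scenario: str = "ros_first"           # ros_first | dna_first
    eq13_literal: bool = False

    def __post_init__(self):
        if self.vm_model not in ("linear", "ghk_weighted", "hh_full"):
            raise ValueError("vm_model must be linear | ghk_weighted | hh_full")
        if self.expression_model not in ("gated", "michaelis_menten"):
            raise ValueError("expression_model must be gated | michaelis_menten")
        if self.scenario not in ("ros_first", "dna_first"):
            raise ValueError("scenario must be ros_first | dna_first")
        if self.sample_dt <= 0 or self.max_step <= 0:
            raise ValueError("sample_dt and max_step must be > 0")


@dataclass
class SystemState:
    """Full dynamical state at one time point (convenience view)."""

    t: float
    Vm: float
    g_Na: float
    g_K: float
    g_Ca: float
    G_Na_norm: float
    G_K_norm: float
    TF: float
    mRNA: float
    mutation_load: float
    ROS_ext: float
    ROS_int: float
    Ca_int: float
    proliferation: float
    phase: int


@dataclass
class Trajectory:
    """Time-indexed simulation output.

    ``frame`` holds the fixed 15-column table; ``growth_integral_A`` /
    ``growth_integral_B`` are the proliferation quadrature states, kept so
    the index can be re-evaluated exactly for any growth gains.
    """

    times: np.ndarray
    frame: pd.DataFrame
    preset_name: str
    protocol: StressProtocol
    solver_meta: dict = field(default_factory=dict)
    growth_integral_A: np.ndarray | None = None
    growth_integral_B: np.ndarray | None = None

    def __post_init__(self):
        if len(self.times) != len(self.frame):
            raise ValueError("times and frame length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def state(self, i: int) -> SystemState:
        r = self.frame.iloc[i]
        return SystemState(
            t=r["t_h"], Vm=r["Vm_mV"], g_Na=r["g_Na"], g_K=r["g_K"],
            g_Ca=r["g_Ca"], G_Na_norm=r["G_Na_norm"], G_K_norm=r["G_K_norm"],
            TF=r["TF"], mRNA=r["mRNA"], mutation_load=r["mutation"],
            ROS_ext=r["ROS_ext"], ROS_int=r["ROS_int"], Ca_int=r["Ca_int"],
            proliferation=r["proliferation"], phase=int(r["phase"]),
        )

    @property
    def final_vm(self) -> float:
        return float(self.frame["Vm_mV"].iloc[-1])

    @property
    def final_proliferation(self) -> float:
        return float(self.frame["proliferation"].iloc[-1])


def plateau_vm(traj: Trajectory, window: float = 4.0) -> float:
    """Mean resting potential over the final ``window`` hours."""
    t = traj.frame["t_h"]
    mask = t >= t.iloc[-1] - window
    return float(traj.frame.loc[mask, "Vm_mV"].mean())


def initial_state_vector(preset: CellLinePreset, options: SolverOptions) -> np.ndarray:
    """All-zero initial state: no expressed channels, quiescent signaling."""
    return np.zeros(N_STATES)


def resting_vm(y, preset: CellLinePreset, options: SolverOptions):
    """Resting membrane potential for a state vector (or stacked states)."""
    y = np.asarray(y)
    g_Na, g_K = y[I_GNA], y[I_GK]
    mem = preset.membrane
    exp_p = preset.expression
    if options.vm_model == "linear":
        offset = preset.vm_initial - ep.LINEAR_VM_INTERCEPT
        return offset + ep.linear_vm(
            np.clip(g_Na / exp_p.g_Na_max, 0, 1),
            np.clip(g_K / exp_p.g_K_max, 0, 1),
            mem.alpha_vm, mem.beta_vm,
        )
    if options.vm_model == "ghk_weighted":
        return ep.quasi_steady_vm(g_Na, g_K, mem.g_L, mem.E_Na, mem.E_K, preset.vm_initial)
    # hh_full: steady-state HH current balance with the expressed maxima
    if np.ndim(g_Na) == 0:
        return ep.hh_rest_potential(mem, float(g_Na), float(g_K))
    return np.array([
        ep.hh_rest_potential(mem, float(a), float(b)) for a, b in zip(g_Na, g_K)
    ])


def _make_rhs(preset: CellLinePreset, protocol: StressProtocol,
              options: SolverOptions, u: float = 0.0):
    """Build a fast scalar RHS closure for the slow system.

    The closure re-expresses the per-module rate operations with local
    floats for speed; `tests` assert its equivalence to composing the
    public operations.
    """
    mem, exp_p, sig = preset.membrane, preset.expression, preset.signaling
    phe = preset.phenotype
    g_L, E_Na, E_K, E_Ca, g_TRPV = mem.g_L, mem.E_Na, mem.E_K, mem.E_Ca, mem.g_TRPV
    alpha_vm, beta_vm = mem.alpha_vm, mem.beta_vm
    vm0 = preset.vm_initial
    gain = exp_p.expression_gain
    kNa, kCa_e, kK = exp_p.k_ROS_Na, exp_p.k_ROS_Ca, exp_p.k_ROS_K
    gNam, gCam, gKm, gVm = exp_p.g_Na_max, exp_p.g_Ca_max, exp_p.g_K_max, exp_p.g_VGIC_max
    thNa, thCl, thCh, thK = exp_p.theta_Na, exp_p.theta_Ca_low, exp_p.theta_Ca_high, exp_p.theta_K
    eps = exp_p.gate_smoothness_eps
    a_mm, b_mm, K_mm = exp_p.alpha_Na_mm, exp_p.beta_Na_mm, exp_p.K_mm
    kVm = exp_p.k_VGIC_mRNA
    kTF, dTF = sig.k_TF, sig.d_TF
    f_lo, f_mid, f_hi = sig.f_minimal, sig.f_moderate, sig.f_rapid
    kRNA, dRNA, kmut, aDNA = sig.k_RNA, sig.d_RNA, sig.k_mut, sig.alpha_DNA
    kRi, dRi, gam, kCaR, kCaF = (
        sig.k_ROS_int, sig.d_ROS_int, sig.gamma_Ca, sig.k_Ca_ROS, sig.k_Ca_flux
    )
    vm_half, vm_slope = phe.vm_half, phe.vm_slope

    base = protocol.ros_baseline
    amp = protocol.pulse_amplitude * protocol.dose_multiplier
    tau2 = 2.0 * protocol.pulse_width_tau**2
    tn = np.asarray(protocol.pulse_times, dtype=float)
    tau = protocol.pulse_width_tau
    has_pulses = len(tn) > 0 and amp > 0.0
    temp_fn = protocol.temperature if protocol.temperature_trace is not None else None

    linear = options.vm_model == "linear"
    ghk = options.vm_model == "ghk_weighted"
    gated = options.expression_model == "gated"
    ros_first = options.scenario == "ros_first"
    literal13 = options.eq13_literal
    u_pos = max(u, 0.0)
    u_neg = max(-u, 0.0)

    def rhs(t, y):
        gNa = min(max(y[I_GNA], 0.0), gNam)
        gCa = min(max(y[I_GCA], 0.0), gCam)
        gK = min(max(y[I_GK], 0.0), gKm)
        gV = min(max(y[I_GV], 0.0), gVm)
        TF = max(y[I_TF], 0.0)
        mRNA = max(y[I_MRNA], 0.0)
        Ri = max(y[I_RI], 0.0)
        Ca = max(y[I_CA], 0.0)

        ros = base
        if has_pulses:
            ros += amp * float(np.exp(-((t - tn) ** 2) / tau2).sum())
        ros = max(0.0, ros + u_pos - u_neg)
        T = temp_fn(t) if temp_fn is not None else 37.0

        act = 1.0 / (1.0 + math.exp(-(ros - ROS_HALF) / ROS_SLOPE))
        if T > 37.0:
            act = min(1.0, act + (T - 37.0) / 4.0)

        if linear:
            v_rest = vm0 + alpha_vm * (gNa / gNam) - beta_vm * (gK / gKm)
        elif ghk:
            v_rest = (gNa * E_Na + gK * E_K + g_L * vm0) / (gNa + gK + g_L)
        else:
            v_rest = ep.hh_rest_potential(mem, gNa, gK)

        g_s = g_TRPV * act
        v_gate = (g_L * v_rest + g_s * E_Ca + K_IROS * ros) / (g_L + g_s)

        r_tot = ros + Ri

        if gated:
            dgNa = gain * kNa * r_tot / (1.0 + math.exp(-(v_gate - thNa) / eps)) * (gNam - gNa)
        else:
            sat = r_tot / (K_mm + r_tot) if r_tot > 0 else 0.0
            dgNa = gNam * (a_mm * (1.0 + sat) - b_mm * (gNa / gNam))
        dgCa = (
            gain * kCa_e * r_tot
            / (1.0 + math.exp(-(v_gate - thCl) / eps))
            / (1.0 + math.exp(-(thCh - v_gate) / eps))
            * (gCam - gCa)
        )
        dgK = gain * kK * r_tot / (1.0 + math.exp(-(thK - v_gate) / eps)) * (gKm - gK)

        if ros_first:
            gV_agg = gNa + gCa + gK
            dgV = 0.0
            dmRNA = kRNA * gV_agg - dRNA * mRNA
        else:
            gV_agg = gV
            dna = 0.0
            if has_pulses:
                dna = 1.0 if np.any(np.abs(t - tn) <= tau) else 0.0
            dmRNA = aDNA * dna - dRNA * mRNA
            dgV = kVm * (1.0 if literal13 else mRNA) * (gVm - gV)

        f = f_hi if v_rest > -30.0 else (f_mid if v_rest >= -50.0 else f_lo)
        dTF_dt = kTF * r_tot * f - dTF * TF
        dMut = kmut * mRNA

        I_Ca = max(0.0, g_TRPV * act * (E_Ca - v_rest))
        dCa = kCaF * I_Ca - gam * Ca

        thermal = 0.01 * max(0.0, T - 37.0)
        dRi_dt = kRi * gV_agg + kCaR * Ca - dRi * Ri + thermal - K_SCAV * u_neg * Ri

        p_act = 1.0 / (1.0 + math.exp(-(v_rest - vm_half) / vm_slope))
        dA = p_act * TF
        dB = Ri

        return (dgNa, dgCa, dgK, dgV, dTF_dt, dmRNA, dMut, dRi_dt, dCa, dA, dB)

    return rhs


def slow_rhs(t, y, preset, protocol, options, u=0.0):
    """Slow-system time derivative at (t, y); reference entry point."""
    return np.asarray(_make_rhs(preset, protocol, options, u)(t, y))


def integrate_segment(preset, protocol, options, y0, t0, t1, u=0.0, t_eval=None):
    rhs = _make_rhs(preset, protocol, options, u)
    sol = solve_ivp(
        rhs, (t0, t1), y0, method=options.method, rtol=options.rtol,
        atol=options.atol, max_step=options.max_step, t_eval=t_eval,
    )
    if not sol.success:
        raise SimulationError(
            f"integrator failed at t={sol.t[-1] if len(sol.t) else t0:.3f} h: "
            f"{sol.message}; last state {sol.y[:, -1] if sol.y.size else y0}"
        )
    return sol


def assemble_trajectory(preset, protocol, options, times, Y, extra_ros=None,
                        solver_meta=None) -> Trajectory:
    """Build the fixed-schema trajectory table from raw state samples."""
    exp_p, phe = preset.expression, preset.phenotype
    g_Na = np.clip(Y[I_GNA], 0.0, exp_p.g_Na_max)
    g_Ca = np.clip(Y[I_GCA], 0.0, exp_p.g_Ca_max)
    g_K = np.clip(Y[I_GK], 0.0, exp_p.g_K_max)
    vm = resting_vm(Y, preset, options)
    if np.any(vm < -100.0) or np.any(vm > 130.0):
        raise SimulationError("invariant breach: Vm outside [-100, +130] mV")
    ros_sig = ros_external(times, protocol)
    if extra_ros is not None:
        ros_sig = np.maximum(0.0, ros_sig + np.asarray(extra_ros))
    A, B = Y[I_A], Y[I_B]
    prolif = np.maximum(0.0, phe.alpha_P * A - phe.beta_P * B)
    frame = pd.DataFrame({
        "t_h": times,
        "Vm_mV": vm,
        "g_Na": g_Na,
        "g_K": g_K,
        "g_Ca": g_Ca,
        "G_Na_norm": g_Na / exp_p.g_Na_max,
        "G_K_norm": g_K / exp_p.g_K_max,
        "TF": np.maximum(Y[I_TF], 0.0),
        "mRNA": np.maximum(Y[I_MRNA], 0.0),
        "mutation": np.maximum(Y[I_MUT], 0.0),
        "ROS_ext": ros_sig,
        "ROS_int": np.maximum(Y[I_RI], 0.0),
        "Ca_int": np.maximum(Y[I_CA], 0.0),
        "proliferation": prolif,
        "phase": cycle_phases_over(times, vm, phe) if len(times) > 1 else [0],
    })
    meta = dict(solver_meta or {})
    meta.setdefault("method", options.method)
    meta.setdefault("rtol", options.rtol)
    meta.setdefault("atol", options.atol)
    return Trajectory(
        times=np.asarray(times, dtype=float), frame=frame,
        preset_name=preset.name, protocol=protocol, solver_meta=meta,
        growth_integral_A=np.asarray(A, dtype=float),
        growth_integral_B=np.asarray(B, dtype=float),
    )


def run_open_loop(preset: CellLinePreset, protocol: StressProtocol,
                  options: SolverOptions | None = None) -> Trajectory:
    """Integrate the coupled slow system under a stress protocol.

    Deterministic given (preset, protocol, options); output sampled on a
    fixed ``sample_dt`` grid.
    """
    options = options if options is not None else SolverOptions()
    n = int(round(protocol.duration / options.sample_dt))
    t_eval = np.linspace(0.0, protocol.duration, n + 1)
    y0 = initial_state_vector(preset, options)
    sol = integrate_segment(preset, protocol, options, y0, 0.0,
                            protocol.duration, t_eval=t_eval)
    return assemble_trajectory(preset, protocol, options, sol.t, sol.y)


def dose_response(preset: CellLinePreset, multipliers, duration: float = 48.0,
                  options: SolverOptions | None = None,
                  base_protocol: StressProtocol | None = None) -> pd.DataFrame:
    """Final Vm and proliferation for each dose multiplier (one open-loop
    run each, under the standard repeated-pulse programme)."""
    multipliers = list(multipliers)
    if any(m < 0 for m in multipliers):
        raise ValueError("multipliers must be >= 0")
    proto = base_protocol if base_protocol is not None else standard_protocol(duration=duration)
    rows = []
    for m in multipliers:
        traj = run_open_loop(preset, dose_scaled(proto, m), options)
        rows.append((m, traj.final_vm, traj.final_proliferation))
    return pd.DataFrame(rows, columns=["multiplier", "final_vm", "final_proliferation"])


# ---------------------------------------------------------------------------
# calibration

_CAL_SAMPLE_DT = 0.05
_GAIN_LO = 1e-3
_GAIN_HI = 1e9
_ALPHA_LO = 25.0
_ALPHA_HI = 150.0
_VM_TOL = 5e-4
_MAX_BISECT = 80


def _vm_metric(traj: Trajectory, metric: str) -> float:
    if metric == "endpoint":
        return traj.final_vm
    return plateau_vm(traj, window=4.0)


def _with_gain(preset, gain):
    return replace(preset, expression=replace(preset.expression, expression_gain=gain))


def _with_alpha(preset, alpha):
    return replace(preset, membrane=replace(preset.membrane, alpha_vm=alpha))


def _fit_gain(preset, protocol, options, target, metric, bracket=None):
    """Find the expression-gain multiplier whose run metric hits ``target``
    (geometric scan to the first crossing, then bisection)."""

    def f(gain):
        traj = run_open_loop(_with_gain(preset, gain), protocol, options)
        return _vm_metric(traj, metric)

    if bracket is None:
        lo = _GAIN_LO
        v_lo = f(lo)
        if v_lo > target + 1e-3:
            raise CalibrationError(
                f"stage 1: target Vm {target} below the zero-gain response {v_lo:.2f}"
            )
        hi = lo
        v_hi = v_lo
        while v_hi < target and hi < _GAIN_HI:
            hi *= 2.0
            v_hi = f(hi)
        if v_hi < target:
            raise CalibrationError(
                f"stage 1: target Vm {target} unreachable (max response {v_hi:.2f})"
            )
        lo = hi / 2.0 if hi > _GAIN_LO else lo
    else:
        lo, hi = bracket
        v_lo, v_hi = f(lo), f(hi)
        if not (v_lo <= target <= v_hi):
            return _fit_gain(preset, protocol, options, target, metric, bracket=None)

    g_mid, v_mid = hi, v_hi
    for _ in range(_MAX_BISECT):
        g_mid = math.sqrt(lo * hi)
        v_mid = f(g_mid)
        if abs(v_mid - target) < _VM_TOL:
            return g_mid, v_mid
        if v_mid < target:
            lo = g_mid
        else:
            hi = g_mid
    if abs(v_mid - target) > 1e-3:
        raise CalibrationError(
            f"stage 1: bisection residual {abs(v_mid - target):.2e} mV exceeds 1e-3"
        )
    return g_mid, v_mid


def calibrate_preset(preset: CellLinePreset, targets: dict | None = None,
                     options: SolverOptions | None = None) -> CellLinePreset:
    """Deterministic three-stage fit of a preset's free gains.

    Stage 1 bisects the expression-gain multiplier to match the
    baseline-dose membrane-potential target; stage 2 (when a high-dose
    plateau target is given) bisects ``alpha_vm`` on the 5x endpoint,
    re-running stage 1 at each iterate; stage 3 solves exactly (2x2
    linear, or 1 unknown when only a baseline value is given) for the
    growth gains using the linearity of the proliferation integral.
    Raises :class:`CalibrationError`, naming the stage, on infeasible
    targets.
    """
    targets = targets if targets is not None else default_calibration_targets(preset.name)
    options = options if options is not None else SolverOptions()
    cal_opts = replace(options, sample_dt=_CAL_SAMPLE_DT)
    proto1 = standard_protocol(1.0)
    proto5 = standard_protocol(5.0)
    metric = targets.get("vm_metric", "final_window_mean")
    vm_base = targets.get("vm_baseline")
    vm_plat = targets.get("vm_plateau")

    out = preset
    if vm_base is not None and vm_plat is None:
        gain, _ = _fit_gain(out, proto1, cal_opts, vm_base, metric)
        out = _with_gain(out, gain)
    elif vm_base is not None and vm_plat is not None:
        lo_a, hi_a = _ALPHA_LO, _ALPHA_HI
        if vm_plat > preset.vm_initial + hi_a:
            raise CalibrationError(
                f"stage 2: plateau target {vm_plat} above the map maximum "
                f"{preset.vm_initial + hi_a:.1f} mV"
            )

        gain_bracket = None

        def high_dose_endpoint(alpha):
            nonlocal gain_bracket
            cand = _with_alpha(out, alpha)
            gain, _ = _fit_gain(cand, proto1, cal_opts, vm_base, metric,
                                bracket=gain_bracket)
            gain_bracket = (gain / 4.0, gain * 4.0)
            cand = _with_gain(cand, gain)
            traj5 = run_open_loop(cand, proto5, cal_opts)
            return _vm_metric(traj5, metric), cand

        v_lo, _ = high_dose_endpoint(lo_a)
        v_hi, cand_hi = high_dose_endpoint(hi_a)
        if not (v_lo <= vm_plat <= v_hi):
            raise CalibrationError(
                f"stage 2: plateau target {vm_plat} outside reachable range "
                f"[{v_lo:.2f}, {v_hi:.2f}] mV"
            )
        cand_mid, v_mid = cand_hi, v_hi
        for _ in range(60):
            mid = 0.5 * (lo_a + hi_a)
            v_mid, cand_mid = high_dose_endpoint(mid)
            if abs(v_mid - vm_plat) < _VM_TOL:
                break
            if v_mid < vm_plat:
                lo_a = mid
            else:
                hi_a = mid
        if abs(v_mid - vm_plat) > 1e-3:
            raise CalibrationError(
                f"stage 2: residual {abs(v_mid - vm_plat):.2e} mV exceeds 1e-3"
            )
        out = cand_mid

    # stage 3: exact linear solve for the growth gains
    p_base = targets.get("prolif_baseline")
    p_high = targets.get("prolif_high")
    if p_base is not None:
        run1 = run_open_loop(out, proto1, cal_opts)
        A1, B1 = run1.growth_integral_A[-1], run1.growth_integral_B[-1]
        if p_high is not None:
            run5 = run_open_loop(out, proto5, cal_opts)
            A5, B5 = run5.growth_integral_A[-1], run5.growth_integral_B[-1]
            M = np.array([[A1, -B1], [A5, -B5]])
            if abs(np.linalg.det(M)) < 1e-30:
                raise CalibrationError("stage 3: singular growth-integral system")
            a_p, b_p = np.linalg.solve(M, np.array([p_base, p_high]))
        else:
            b_p = out.phenotype.beta_P
            if A1 <= 0:
                raise CalibrationError("stage 3: zero growth integral; cannot fit alpha_P")
            a_p = (p_base + b_p * B1) / A1
        out = replace(out, phenotype=replace(out.phenotype, alpha_P=float(a_p),
                                             beta_P=float(b_p)))
    return out
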