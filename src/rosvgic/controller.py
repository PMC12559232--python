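r"""ROS-actuated PID regulation of the resting membrane potential.

The controller measures the resting potential, forms the error
e(t) = V_target - Vm(t), and commands a redox drive

    u(t) = clamp(Kp e + Ki \int e dtau + Kd de/dt, u_min, u_max)   [uM]

at a fixed control interval.  Positive u adds exogenous ROS (pro-oxidant
arm); negative u is an antioxidant arm that both subtracts from the
extracellular signal and scavenges intracellular ROS.  Anti-windup is by
conditional integration: the integral is frozen while the command is
clamped.  The derivative acts on the error and is forced to zero on the
first step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["PIDParams", "PIDState", "pid_command", "run_closed_loop"]


@dataclass(frozen=True)
class PIDParams:
    """PID gains, setpoint and actuation limits.

    Gains are dimensionless multipliers mapping mV-scale error onto the
    uM-scale redox drive (Kp per mV, Ki per mV.h, Kd mV.h units).
    """

    Kp: float = 1.0
    Ki: float = 0.03
    Kd: float = 0.3
    v_target: float = -30.0
    u_min: float = -0.45
    u_max: float = 0.45
    control_dt: float = 0.02
    deriv_tau: float = 0.1

    def __post_init__(self):
        if self.control_dt <= 0:
            raise ValueError("control_dt must be > 0")
        if self.u_min >= self.u_max:
            raise ValueError("u_min must be < u_max")
        if self.deriv_tau < 0:
            raise ValueError("deriv_tau must be >= 0")


@dataclass
class PIDState:
    integral: float = 0.0
    prev_error: float | None = None
    deriv_filtered: float = 0.0


def pid_command(Vm, pid: PIDParams, state: PIDState, dt):
    """One discrete PID update; returns ``(u, new_state)``.

    The integral candidate is accepted only if the resulting command is
    inside the actuation bounds (conditional-integration anti-windup), and
    is additionally clamped so its contribution never exceeds the
    actuation span.  The derivative is first-order filtered (time constant
    ``deriv_tau``) to avoid chatter on the sampled measurement.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    e = pid.v_target - Vm
    raw_deriv = 0.0 if state.prev_error is None else (e - state.prev_error) / dt
    lam = dt / (dt + pid.deriv_tau) if pid.deriv_tau > 0 else 1.0
    deriv = state.deriv_filtered + lam * (raw_deriv - state.deriv_filtered)
    integral_trial = state.integral + e * dt
    if pid.Ki > 0:
        cap = max(abs(pid.u_min), abs(pid.u_max)) / pid.Ki
        integral_trial = min(max(integral_trial, -cap), cap)
    u_raw = pid.Kp * e + pid.Ki * integral_trial + pid.Kd * deriv
    if u_raw > pid.u_max:
        return pid.u_max, PIDState(state.integral, e, deriv)
    if u_raw < pid.u_min:
        return pid.u_min, PIDState(state.integral, e, deriv)
    return u_raw, PIDState(integral_trial, e, deriv)


def run_closed_loop(
    preset,
    pid: PIDParams | None = None,
    duration: float = 24.0,
    protocol=None,
    options=None,
    settle_fraction: float = 0.1,
    settle_tol: float = 0.5,
):
    """Closed-loop simulation of a cell-line plant under PID redox drive.

    The plant is the slow open-loop system; the command is held constant
    over each control interval.  Returns a :class:`~rosvgic.simulator.Trajectory`
    whose metadata records the convergence flag (steady-state error below
    ``settle_tol`` mV over the final ``settle_fraction`` of the horizon)
    and the actuation trace.  Non-convergence is flagged, never raised.
    """
    from . import simulator as sim
    from .stressors import StressProtocol, zero_stress_protocol

    pid = pid if pid is not None else preset.pid
    protocol = protocol if protocol is not None else zero_stress_protocol(duration)
    options = options if options is not None else sim.SolverOptions()

    n_seg = max(1, int(round(duration / pid.control_dt)))
    state = sim.initial_state_vector(preset, options)
    pstate = PIDState()
    times, rows, u_trace = [], [], []
    vm = sim.resting_vm(state, preset, options)
    t0 = 0.0
    for _ in range(n_seg):
        u, pstate = pid_command(vm, pid, pstate, pid.control_dt)
        seg = sim.integrate_segment(
            preset, protocol, options, state, t0, t0 + pid.control_dt, u=u
        )
        state = seg.y[:, -1]
        t0 += pid.control_dt
        vm = sim.resting_vm(state, preset, options)
        times.append(t0)
        rows.append(state.copy())
        u_trace.append(u)

    traj = sim.assemble_trajectory(
        preset, protocol, options, np.array(times), np.array(rows).T,
        extra_ros=np.array(u_trace),
    )
    tail = traj.frame["t_h"] >= (1.0 - settle_fraction) * duration
    err = np.abs(traj.frame.loc[tail, "Vm_mV"] - pid.v_target)
    traj.solver_meta["converged"] = bool(err.max() < settle_tol)
    traj.solver_meta["final_error_mV"] = float(err.iloc[-1])
    traj.solver_meta["u_trace"] = np.array(u_trace)
    traj.solver_meta["pid"] = {
        "Kp": pid.Kp, "Ki": pid.Ki, "Kd": pid.Kd, "v_target": pid.v_target,
    }
    return traj
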