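"""Membrane currents and membrane potential.

Three potential maps are provided:

* the full Hodgkin-Huxley membrane equation (ms timescale), used for
  excitability snapshots:
      C_m dV/dt = -I_Na - I_K - I_L + I_TRPV + I_ROS(t)
* the quasi-steady chord-conductance potential (conductance-weighted mean
  of reversal potentials);
* a linear expression-to-potential map used by the slow transformation
  loop:  Vm = -75 + alpha * G_Na - beta * G_K,  with G in [0, 1].

Sign convention: I_TRPV and I_ROS are inward-positive (they depolarize).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "MembraneParams",
    "MembraneState",
    "hh_gating_rates",
    "membrane_rhs",
    "integrate_hh",
    "hh_rest_potential",
    "quasi_steady_vm",
    "linear_vm",
    "trpv_current",
    "trpv_activation",
    "LINEAR_VM_INTERCEPT",
]

#: intercept of the linear expression-to-Vm map (mV)
LINEAR_VM_INTERCEPT = -75.0


@dataclass(frozen=True)
class MembraneParams:
    """Passive and maximal membrane properties (HH units: mV, ms, mS/cm2,
    uA/cm2, uF/cm2)."""

    C_m: float = 1.0
    g_L: float = 0.3
    E_L: float = -54.4
    E_Na: float = 60.0
    E_K: float = -90.0
    E_Ca: float = 120.0
    g_Na_max: float = 120.0
    g_K_max: float = 36.0
    g_TRPV: float = 2.0
    alpha_vm: float = 45.0
    beta_vm: float = 15.0

    def __post_init__(self):
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")
        for name in ("g_L", "g_Na_max", "g_K_max", "g_TRPV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.E_K < self.E_L < 0 < self.E_Na < self.E_Ca):
            raise ValueError("reversal potentials must satisfy E_K < E_L < 0 < E_Na < E_Ca")


@dataclass
class MembraneState:
    """Fast membrane state: potential plus HH gating variables."""

    Vm: float
    m: float
    h: float
    n: float

    def __post_init__(self):
        for g in (self.m, self.h, self.n):
            if not (0.0 <= g <= 1.0):
                raise ValueError("gating variables must lie in [0, 1]")


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        out = np.where(small, y * (1.0 + x / (2.0 * y)), x / -np.expm1(-x / y))
    return out


def hh_gating_rates(Vm):
    """Classical squid-axon gating rates (1/ms) at potential ``Vm`` (mV).

    Returns (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n); removable
    singularities (Vm = -40 for alpha_m, -55 for alpha_n) are evaluated by
    their limits.
    """
    Vm = np.asarray(Vm, dtype=float)
    if not np.all(np.isfinite(Vm)):
        raise ValueError("Vm must be finite")
    a_m = 0.1 * _vtrap(Vm + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(Vm + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(Vm + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(Vm + 35.0) / 10.0))
    a_n = 0.01 * _vtrap(Vm + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(Vm + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def membrane_rhs(state, params: MembraneParams, g_Na, g_K, I_TRPV=0.0, I_ROS=0.0):
    """Time derivative (per ms) of the fast membrane state.

    ``g_Na``/``g_K`` are the currently expressed maximal conductances; the
    instantaneous ionic conductances are g_Na*m^3*h and g_K*n^4.
    """
    Vm, m, h, n = state.Vm, state.m, state.h, state.n
    vals = (Vm, m, h, n, g_Na, g_K, I_TRPV, I_ROS)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("non-finite input to membrane_rhs")
    I_Na = g_Na * m**3 * h * (Vm - params.E_Na)
    I_K = g_K * n**4 * (Vm - params.E_K)
    I_L = params.g_L * (Vm - params.E_L)
    dVm = (-I_Na - I_K - I_L + I_TRPV + I_ROS) / params.C_m
    a_m, b_m, a_h, b_h, a_n, b_n = hh_gating_rates(Vm)
    return (
        dVm,
        a_m * (1.0 - m) - b_m * m,
        a_h * (1.0 - h) - b_h * h,
        a_n * (1.0 - n) - b_n * n,
    )


def integrate_hh(
    params: MembraneParams,
    g_Na,
    g_K,
    duration_ms=50.0,
    v0=-65.0,
    I_stim=None,
    rtol=1e-8,
    atol=1e-10,
    t_eval=None,
):
    """Integrate the HH membrane for an excitability snapshot.

    ``I_stim`` is an optional callable t(ms) -> inward-positive current
    (uA/cm2).  Gating variables start at their steady state for ``v0``.
    Returns ``(t, V, m, h, n)`` arrays.
    """
    a_m, b_m, a_h, b_h, a_n, b_n = hh_gating_rates(v0)
    y0 = [v0, a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)]

    def rhs(t, y):
        stim = I_stim(t) if I_stim is not None else 0.0
        st = MembraneState.__new__(MembraneState)
        st.Vm, st.m, st.h, st.n = y
        return membrane_rhs(st, params, g_Na, g_K, I_ROS=stim)

    sol = solve_ivp(
        rhs, (0.0, duration_ms), y0, method="LSODA", rtol=rtol, atol=atol,
        t_eval=t_eval, max_step=0.5,
    )
    if not sol.success:
        raise RuntimeError(f"HH integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1], sol.y[2], sol.y[3]


def hh_rest_potential(params: MembraneParams, g_Na, g_K, bracket=(-95.0, 50.0)):
    """Resting potential of the HH membrane with steady-state gating.

    Solves the current-balance equation with m, h, n at their
    voltage-dependent steady states (chord equation with HH gating).
    """

    def balance(V):
        a_m, b_m, a_h, b_h, a_n, b_n = hh_gating_rates(V)
        m = a_m / (a_m + b_m)
        h = a_h / (a_h + b_h)
        n = a_n / (a_n + b_n)
        return (
            -g_Na * m**3 * h * (V - params.E_Na)
            - g_K * n**4 * (V - params.E_K)
            - params.g_L * (V - params.E_L)
        )

    return brentq(balance, *bracket, xtol=1e-10)


def quasi_steady_vm(g_Na, g_K, g_L, E_Na, E_K, E_L):
    """Chord-conductance (quasi-steady) membrane potential (mV):
    the conductance-weighted mean of the reversal potentials."""
    total = g_Na + g_K + g_L
    if np.any(np.asarray(total) <= 0):
        raise ValueError("potential undefined: total conductance is zero")
    return (g_Na * E_Na + g_K * E_K + g_L * E_L) / total


def linear_vm(G_Na, G_K, alpha_vm, beta_vm):
    """Linear expression-to-potential map (mV) for normalized expression
    levels G_Na, G_K in [0, 1]:  -75 + alpha*G_Na - beta*G_K."""
    G_Na = np.asarray(G_Na, dtype=float)
    G_K = np.asarray(G_K, dtype=float)
    if np.any(G_Na < 0) or np.any(G_Na > 1) or np.any(G_K < 0) or np.any(G_K > 1):
        raise ValueError("normalized expression levels must lie in [0, 1]")
    out = LINEAR_VM_INTERCEPT + alpha_vm * G_Na - beta_vm * G_K
    return float(out) if out.ndim == 0 else out


def trpv_current(Vm, activation, g_TRPV, E_Ca):
    """Inward-positive TRPV calcium current (uA/cm2):
    g_TRPV * activation * (E_Ca - Vm)."""
    activation = np.asarray(activation, dtype=float)
    if np.any(activation < 0) or np.any(activation > 1):
        raise ValueError("activation must lie in [0, 1]")
    out = g_TRPV * activation * (E_Ca - np.asarray(Vm, dtype=float))
    return float(out) if out.ndim == 0 else out


def trpv_activation(ros_ext, T=37.0, ros_half=0.02, ros_slope=0.02 / 32.0):
    """TRPV open fraction in [0, 1].

    Sharp logistic in extracellular ROS (half-activation ``ros_half`` uM,
    default twice the standard baseline) plus a thermal arm
    max(0, (T - 37)/4); the sum is clipped to [0, 1] so either heat or
    oxidative stress alone can open the channel.
    """
    ros_ext = np.asarray(ros_ext, dtype=float)
    with np.errstate(over="ignore"):
        ros_arm = 1.0 / (1.0 + np.exp(-(ros_ext - ros_half) / ros_slope))
    thermal_arm = np.maximum(0.0, (np.asarray(T, dtype=float) - 37.0) / 4.0)
    out = np.clip(ros_arm + thermal_arm, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out
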