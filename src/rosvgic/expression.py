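"""Voltage- and ROS-gated ion-channel expression dynamics.

The conductance of each channel class grows toward its maximum at a
ROS-proportional rate whenever the membrane potential sits inside that
class's transcriptional window:

    dg_Na/dt = k_Na(ROS) * H(Vm + 30) * (g_Na,max - g_Na)
    dg_Ca/dt = k_Ca(ROS) * H(Vm + 50) * H(-30 - Vm) * (g_Ca,max - g_Ca)
    dg_K/dt  = k_K(ROS)  * H(-50 - Vm) * (g_K,max - g_K)

with k_x(ROS) = k_ROS_x * ROS (linear mass action).  As written these have
no decay term: expression is a ratchet.  Inside ODE right-hand sides the
Heaviside gates are smoothed by a logistic of width ``gate_smoothness_eps``
so the system stays Lipschitz; the algebraic channel-class selector uses
exact steps with the printed half-open tier boundaries.

An alternative reversible Michaelis-Menten form for the normalized sodium
expression level is also provided:

    dG_Na/dt = alpha_Na * (1 + ROS/(K + ROS)) - beta_Na * G_Na

as is the mRNA-driven aggregate VGIC accumulation used by the DNA-damage
scenario:

    dg_VGIC/dt = k_VGIC_mRNA * mRNA * (g_VGIC,max - g_VGIC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExpressionParams",
    "ExpressionState",
    "gate",
    "na_expression_rhs",
    "ca_expression_rhs",
    "k_expression_rhs",
    "mm_expression_rhs",
    "vgic_from_mrna_rhs",
    "select_channel_class",
]

#: unit conversion for literature per-second rate constants
PER_S_TO_PER_H = 3600.0


@dataclass(frozen=True)
class ExpressionParams:
    """Rate constants (per hour) and thresholds for channel expression.

    Literature values quoted per second (e.g. k_ROS_Na = 1e-4 /s per uM)
    are converted to per-hour at preset load time.
    """

    k_ROS_Na: float = 1e-4 * PER_S_TO_PER_H
    k_ROS_Ca: float = 1e-4 * PER_S_TO_PER_H
    k_ROS_K: float = 1e-4 * PER_S_TO_PER_H
    g_Na_max: float = 120.0
    g_K_max: float = 36.0
    g_Ca_max: float = 5.0
    theta_Na: float = -30.0
    theta_Ca_low: float = -50.0
    theta_Ca_high: float = -30.0
    theta_K: float = -50.0
    alpha_Na_mm: float = 0.05
    beta_Na_mm: float = 0.1
    K_mm: float = 0.05
    k_VGIC_mRNA: float = 0.05
    g_VGIC_max: float = 160.0
    gate_smoothness_eps: float = 1.0
    expression_gain: float = 1.0

    def __post_init__(self):
        for name in ("k_ROS_Na", "k_ROS_Ca", "k_ROS_K", "alpha_Na_mm",
                     "beta_Na_mm", "k_VGIC_mRNA", "expression_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.theta_Ca_low >= self.theta_Ca_high:
            raise ValueError("theta_Ca_low must be < theta_Ca_high")
        if self.gate_smoothness_eps <= 0:
            raise ValueError("gate_smoothness_eps must be > 0")


@dataclass
class ExpressionState:
    g_Na: float = 0.0
    g_K: float = 0.0
    g_Ca: float = 0.0
    G_Na_norm: float = 0.0
    G_K_norm: float = 0.0
    g_VGIC: float = 0.0


def gate(x, eps):
    """Heaviside gate H(x), optionally logistic-smoothed.

    ``eps > 0`` gives the logistic 1/(1 + exp(-x/eps)) for use inside ODE
    right-hand sides; ``eps == 0`` gives the exact step (x >= 0 -> 1) for
    algebraic classification.
    """
    x = np.asarray(x, dtype=float)
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if eps == 0:
        out = np.where(x >= 0.0, 1.0, 0.0)
    else:
        with np.errstate(over="ignore"):
            out = 1.0 / (1.0 + np.exp(-x / eps))
    return float(out) if out.ndim == 0 else out


def _check_bound(g, g_max, name):
    if g < 0 or g > g_max * (1 + 1e-9):
        raise ValueError(f"{name} outside [0, {name}_max]")


def na_expression_rhs(g_Na, ROS, Vm, p: ExpressionParams, eps=None):
    """d(g_Na)/dt: ROS-paced saturating growth, gated above -30 mV."""
    _check_bound(g_Na, p.g_Na_max, "g_Na")
    eps = p.gate_smoothness_eps if eps is None else eps
    k = p.expression_gain * p.k_ROS_Na * ROS
    return k * gate(Vm - p.theta_Na, eps) * (p.g_Na_max - g_Na)


def ca_expression_rhs(g_Ca, ROS, Vm, p: ExpressionParams, eps=None):
    """d(g_Ca)/dt: gated inside the window [-50, -30) mV."""
    _check_bound(g_Ca, p.g_Ca_max, "g_Ca")
    eps = p.gate_smoothness_eps if eps is None else eps
    k = p.expression_gain * p.k_ROS_Ca * ROS
    window = gate(Vm - p.theta_Ca_low, eps) * gate(p.theta_Ca_high - Vm, eps)
    if eps == 0:
        # exact mode: the window is half-open, [-50, -30)
        window = gate(Vm - p.theta_Ca_low, 0) * (1.0 - gate(Vm - p.theta_Ca_high, 0))
    return k * window * (p.g_Ca_max - g_Ca)


def k_expression_rhs(g_K, ROS, Vm, p: ExpressionParams, eps=None):
    """d(g_K)/dt: gated below -50 mV (hyperpolarized cells express K+)."""
    _check_bound(g_K, p.g_K_max, "g_K")
    eps = p.gate_smoothness_eps if eps is None else eps
    k = p.expression_gain * p.k_ROS_K * ROS
    if eps == 0:
        # exact mode: strictly below -50 (H(-50 - Vm) with H(0) = 1 would
        # include the boundary; the printed tier assigns -50 to the Ca tier)
        window = 1.0 if Vm < p.theta_K else 0.0
    else:
        window = gate(p.theta_K - Vm, eps)
    return k * window * (p.g_K_max - g_K)


def mm_expression_rhs(G_Na_norm, ROS, p: ExpressionParams):
    """Reversible Michaelis-Menten sodium expression (normalized units).

    Fixed point (alpha/beta) * (1 + ROS/(K + ROS)), globally attracting
    for constant ROS.
    """
    if G_Na_norm < 0:
        raise ValueError("G_Na_norm must be >= 0")
    sat = ROS / (p.K_mm + ROS) if ROS > 0 else 0.0
    return p.alpha_Na_mm * (1.0 + sat) - p.beta_Na_mm * G_Na_norm


def vgic_from_mrna_rhs(g_VGIC, mRNA, p: ExpressionParams, literal=False):
    """d(g_VGIC)/dt for the DNA-damage scenario.

    Default: effective rate k_VGIC_mRNA * mRNA (transcription-paced).
    ``literal=True`` restores the constant-rate form with no mRNA factor.
    """
    _check_bound(g_VGIC, p.g_VGIC_max, "g_VGIC")
    rate = p.k_VGIC_mRNA if literal else p.k_VGIC_mRNA * mRNA
    return rate * (p.g_VGIC_max - g_VGIC)


def select_channel_class(Vm, ros_level="moderate"):
    """Algebraic channel-class selector with exact tier boundaries.

    Vm < -50 -> 'K'; -50 <= Vm < -30 -> 'Ca_TRP'; Vm >= -30 -> 'Na'.
    ``ros_level`` ({'low','moderate','high'}) is carried for reporting but
    the tiers are set by the membrane potential.
    """
    if ros_level not in ("low", "moderate", "high"):
        raise ValueError("ros_level must be one of low/moderate/high")
    if Vm < -50.0:
        return "K"
    if Vm < -30.0:
        return "Ca_TRP"
    return "Na"
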