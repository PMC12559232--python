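"""Intracellular redox-transcription layer.

Linear first-order ODEs couple the oxidative input to transcription and
genomic instability:

* tissue/transcription factor with tiered voltage sensitivity,
      dTF/dt = k_TF * ROS * f(Vm) - d_TF * TF,
  where f is minimal below -50 mV, moderate in [-50, -30], rapid above;
* two mutually exclusive transcription scenarios:
  ros_first  — mRNA paced by total expressed conductance
      dmRNA/dt = k_RNA * (g_Na + g_Ca + g_K) - d_RNA * mRNA,
  dna_first  — mRNA paced by a DNA-damage signal
      dmRNA/dt = alpha_DNA * DNA_dam(t) - d_RNA * mRNA;
* mutation load as the running integral of transcription,
      dMut/dt = k_mut * mRNA  (non-decreasing);
* intracellular ROS fed back from channel activity and calcium,
      dROS_int/dt = k_ROS_int * g_VGIC + k_Ca_ROS * Ca_int - d_ROS_int * ROS_int;
* intracellular calcium with first-order clearance,
      dCa/dt = k_Ca_flux * I_Ca - gamma * Ca.

TF, mRNA and mutation load are in arbitrary units; rates are per hour
(literature per-second values converted at load time).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SignalingParams",
    "SignalingState",
    "f_vm",
    "tf_rhs",
    "mrna_rhs_scenario1",
    "mrna_rhs_scenario2",
    "mutation_rhs",
    "ros_int_rhs",
    "calcium_rhs",
]

PER_S_TO_PER_H = 3600.0


@dataclass(frozen=True)
class SignalingParams:
    """Rate constants of the signaling layer (per hour unless noted)."""

    k_TF: float = 5e-4 * PER_S_TO_PER_H      # TF production per uM ROS
    d_TF: float = 0.01 * PER_S_TO_PER_H
    f_minimal: float = 0.1
    f_moderate: float = 0.5
    f_rapid: float = 1.0
    k_RNA: float = 0.01 * PER_S_TO_PER_H     # mRNA per (mS/cm2)
    d_RNA: float = 0.01 * PER_S_TO_PER_H
    k_mut: float = 1e-6 * PER_S_TO_PER_H     # mutations per mRNA unit
    alpha_DNA: float = 0.01 * PER_S_TO_PER_H
    k_ROS_int: float = 1e-6 * PER_S_TO_PER_H  # uM per (mS/cm2)
    d_ROS_int: float = 0.01 * PER_S_TO_PER_H
    gamma_Ca: float = 0.01 * PER_S_TO_PER_H
    k_Ca_ROS: float = 1e-3 * PER_S_TO_PER_H
    k_Ca_flux: float = 1e-3                   # uM.cm2 per (uA.h)
    tier_low: float = -50.0
    tier_high: float = -30.0

    def __post_init__(self):
        for name in ("k_TF", "d_TF", "k_RNA", "d_RNA", "k_mut", "alpha_DNA",
                     "k_ROS_int", "d_ROS_int", "gamma_Ca", "k_Ca_ROS", "k_Ca_flux"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.f_minimal < self.f_moderate < self.f_rapid):
            raise ValueError("tier multipliers must satisfy minimal < moderate < rapid")


@dataclass
class SignalingState:
    TF: float = 0.0
    mRNA: float = 0.0
    mutation_load: float = 0.0
    ROS_int: float = 0.0
    Ca_int: float = 0.0
    DNA_dam: float = 0.0


def f_vm(Vm, p: SignalingParams):
    """Tiered voltage-sensitivity multiplier of TF production.

    Rapid above -30 mV, moderate on [-50, -30], minimal below -50 mV.
    """
    if Vm > p.tier_high:
        return p.f_rapid
    if Vm >= p.tier_low:
        return p.f_moderate
    return p.f_minimal


def tf_rhs(TF, ROS, Vm, p: SignalingParams):
    """d(TF)/dt: tier-gated ROS-driven production minus first-order decay."""
    return p.k_TF * ROS * f_vm(Vm, p) - p.d_TF * TF


def mrna_rhs_scenario1(mRNA, g_Na, g_Ca, g_K, p: SignalingParams):
    """d(mRNA)/dt paced by the total expressed conductance (ros_first)."""
    return p.k_RNA * (g_Na + g_Ca + g_K) - p.d_RNA * mRNA


def mrna_rhs_scenario2(mRNA, DNA_dam, p: SignalingParams):
    """d(mRNA)/dt paced by a time-dependent DNA-damage signal (dna_first)."""
    return p.alpha_DNA * DNA_dam - p.d_RNA * mRNA


def mutation_rhs(mRNA, p: SignalingParams):
    """d(mutation_load)/dt = k_mut * mRNA; never negative."""
    if mRNA < 0:
        raise ValueError("mRNA must be >= 0")
    return p.k_mut * mRNA


def ros_int_rhs(ROS_int, g_VGIC, Ca_int, p: SignalingParams, extra_source=0.0):
    """d(ROS_int)/dt: channel-activity and calcium sources minus clearance.

    ``extra_source`` (uM/h) carries the thermal drive or the controller's
    scavenging arm; with k_Ca_ROS = 0 and no extra source this is the
    two-term channel-feedback form exactly.
    """
    return (
        p.k_ROS_int * g_VGIC
        + p.k_Ca_ROS * Ca_int
        - p.d_ROS_int * ROS_int
        + extra_source
    )


def calcium_rhs(Ca_int, I_Ca_total, p: SignalingParams):
    """d(Ca_int)/dt: influx proportional to inward calcium current minus
    first-order clearance at rate gamma."""
    if Ca_int < 0 or I_Ca_total < 0:
        raise ValueError("Ca_int and I_Ca_total must be >= 0")
    return p.k_Ca_flux * I_Ca_total - p.gamma_Ca * Ca_int
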