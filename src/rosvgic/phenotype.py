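"""Proliferation dynamics and the membrane-potential-gated cell cycle.

The proliferation index accumulates as

    dProlif/dt = alpha_P * P(Vm) * TF(t) - beta_P * ROS_int,

with P a logistic voltage-activation curve (midpoint -30 mV).  Because the
index does not feed back into the dynamics, its final value is exactly
linear in (alpha_P, beta_P) for a fixed trajectory — the property the
calibration stage exploits.  The index is clipped at zero for reporting.

Cell-cycle progression is a four-phase state machine (G0/G1 -> S -> G2 ->
M) advancing on dwell-time completion; only the G1 -> S transition is
voltage-gated (requires Vm >= -30 mV), and hyperpolarization below -50 mV
resets the cell to quiescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "PhenotypeParams",
    "PhenotypeState",
    "CyclePhase",
    "p_of_vm",
    "proliferation_rhs",
    "cell_cycle_step",
    "cycle_phases_over",
]

PER_S_TO_PER_H = 3600.0


class CyclePhase(IntEnum):
    G0G1 = 0
    S = 1
    G2 = 2
    M = 3


_NEXT_PHASE = {
    CyclePhase.G0G1: CyclePhase.S,
    CyclePhase.S: CyclePhase.G2,
    CyclePhase.G2: CyclePhase.M,
    CyclePhase.M: CyclePhase.G0G1,
}


@dataclass(frozen=True)
class PhenotypeParams:
    """Growth gains (per hour) and cycle gating thresholds."""

    alpha_P: float = 1e-5 * PER_S_TO_PER_H
    beta_P: float = 5e-6 * PER_S_TO_PER_H
    vm_half: float = -30.0
    vm_slope: float = 5.0
    cycle_threshold: float = -30.0
    quiescence_threshold: float = -50.0
    phase_durations: dict = field(
        default_factory=lambda: {
            CyclePhase.G0G1: 10.0,
            CyclePhase.S: 8.0,
            CyclePhase.G2: 4.0,
            CyclePhase.M: 2.0,
        }
    )

    def __post_init__(self):
        if self.vm_slope <= 0:
            raise ValueError("vm_slope must be > 0")
        if any(d <= 0 for d in self.phase_durations.values()):
            raise ValueError("phase durations must be > 0")


@dataclass
class PhenotypeState:
    proliferation: float = 0.0
    phase: CyclePhase = CyclePhase.G0G1
    phase_dwell: float = 0.0


def p_of_vm(Vm, p: PhenotypeParams):
    """Logistic voltage activation of proliferative signaling, in (0, 1),
    strictly increasing in Vm with midpoint ``vm_half``."""
    x = (np.asarray(Vm, dtype=float) - p.vm_half) / p.vm_slope
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if out.ndim == 0 else out


def proliferation_rhs(prolif, Vm, TF, ROS_int, p: PhenotypeParams):
    """d(prolif)/dt = alpha_P * P(Vm) * TF - beta_P * ROS_int."""
    if TF < 0 or ROS_int < 0:
        raise ValueError("TF and ROS_int must be >= 0")
    return p.alpha_P * p_of_vm(Vm, p) * TF - p.beta_P * ROS_int


def cell_cycle_step(state: PhenotypeState, Vm, dt, p: PhenotypeParams) -> PhenotypeState:
    """Advance the cycle state machine by ``dt`` hours at potential ``Vm``.

    Hyperpolarization below the quiescence threshold forces (and holds)
    G0/G1 with the dwell clock reset.  From G0/G1, entry into S requires
    both dwell completion and Vm >= the activation threshold; the other
    transitions advance purely on dwell completion.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    phase, dwell = state.phase, state.phase_dwell + dt
    if Vm < p.quiescence_threshold:
        return PhenotypeState(state.proliferation, CyclePhase.G0G1, 0.0)
    if phase == CyclePhase.G0G1:
        if dwell >= p.phase_durations[phase] and Vm >= p.cycle_threshold:
            return PhenotypeState(state.proliferation, CyclePhase.S, 0.0)
        return PhenotypeState(state.proliferation, phase, dwell)
    if dwell >= p.phase_durations[phase]:
        return PhenotypeState(state.proliferation, _NEXT_PHASE[phase], 0.0)
    return PhenotypeState(state.proliferation, phase, dwell)


def cycle_phases_over(times, vms, p: PhenotypeParams) -> np.ndarray:
    """Run the cycle machine along a sampled Vm trace; returns the integer
    phase code at each sample (0=G0/G1, 1=S, 2=G2, 3=M)."""
    times = np.asarray(times, dtype=float)
    vms = np.asarray(vms, dtype=float)
    state = PhenotypeState()
    phases = np.empty(len(times), dtype=int)
    phases[0] = int(state.phase)
    for i in range(1, len(times)):
        state = cell_cycle_step(state, vms[i], times[i] - times[i - 1], p)
        phases[i] = int(state.phase)
    return phases
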