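"""Exogenous stress forcing: Gaussian ROS pulse trains and thermal drive.

The extracellular oxidative signal is a baseline concentration plus a train
of Gaussian pulses,

    ROS_ext(t) = ROS_baseline + d * sum_n  A * exp(-(t - t_n)^2 / (2 tau^2)),

where ``A`` is the pulse amplitude (uM), ``tau`` the pulse width (h) and
``d`` a dimensionless dose multiplier.  Mild hyperthermia enters as an
additional oxidative source proportional to the temperature excess above
normothermia (37 C).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "StressProtocol",
    "ros_external",
    "dose_scaled",
    "thermal_ros_drive",
    "standard_protocol",
    "zero_stress_protocol",
]

#: thermal ROS generation gain, uM per (h * degC above 37 C)
K_THERMAL = 0.01


@dataclass(frozen=True)
class StressProtocol:
    """A time-dependent extracellular stress programme.

    Parameters
    ----------
    ros_baseline : float
        Constant background ROS concentration (uM), >= 0.
    pulse_times : tuple of float
        Pulse centres t_n (h), all within [0, duration].
    pulse_amplitude : float
        Gaussian pulse amplitude (uM), >= 0.
    pulse_width_tau : float
        Gaussian width tau (h), > 0.
    dose_multiplier : float
        Dimensionless scaling of the pulse train (>= 0); the baseline is
        never scaled.
    duration : float
        Simulation horizon (h), > 0.
    temperature_trace : tuple of (time, temperature) pairs, optional
        Piecewise-constant temperature (degC) over time; ``None`` means
        normothermia (37 C) throughout.
    """

    ros_baseline: float = 0.01
    pulse_times: tuple = ()
    pulse_amplitude: float = 0.045
    pulse_width_tau: float = 0.25
    dose_multiplier: float = 1.0
    duration: float = 48.0
    temperature_trace: tuple | None = None

    def __post_init__(self):
        if self.ros_baseline < 0:
            raise ValueError("ros_baseline must be >= 0")
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be >= 0")
        if self.pulse_width_tau <= 0:
            raise ValueError("pulse_width_tau must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.dose_multiplier < 0:
            raise ValueError("dose_multiplier must be >= 0")
        object.__setattr__(self, "pulse_times", tuple(float(t) for t in self.pulse_times))
        for t in self.pulse_times:
            if not (0.0 <= t <= self.duration):
                raise ValueError(f"pulse time {t} outside [0, {self.duration}]")
        if self.temperature_trace is not None:
            object.__setattr__(
                self,
                "temperature_trace",
                tuple((float(a), float(b)) for a, b in self.temperature_trace),
            )

    def temperature(self, t):
        """Piecewise-constant temperature (degC) at time ``t`` (h)."""
        if self.temperature_trace is None:
            return 37.0 if np.isscalar(t) else np.full(np.shape(t), 37.0)
        times = np.array([p[0] for p in self.temperature_trace])
        temps = np.array([p[1] for p in self.temperature_trace])
        idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(temps) - 1)
        out = temps[idx]
        return float(out) if np.isscalar(t) else out


def ros_external(t, protocol: StressProtocol):
    """Extracellular ROS concentration (uM) at time ``t`` (h).

    Accepts a scalar or array ``t``; every element must lie inside the
    protocol horizon.  The returned signal is continuous, >= baseline, and
    its pulse part scales linearly with the dose multiplier.
    """
    t = np.asarray(t, dtype=float)
    slack = 1e-9 * max(1.0, protocol.duration)  # roundoff from accumulated steps
    if np.any(t < -slack) or np.any(t > protocol.duration + slack):
        raise ValueError("t outside the protocol horizon")
    out = np.full(t.shape, protocol.ros_baseline)
    if protocol.pulse_times and protocol.pulse_amplitude > 0:
        tau = protocol.pulse_width_tau
        tn = np.asarray(protocol.pulse_times)
        d2 = (t[..., None] - tn) ** 2
        out = out + protocol.dose_multiplier * protocol.pulse_amplitude * np.exp(
            -d2 / (2.0 * tau * tau)
        ).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def dose_scaled(protocol: StressProtocol, multiplier: float) -> StressProtocol:
    """Copy of ``protocol`` with the dose multiplier replaced."""
    if multiplier < 0:
        raise ValueError("dose multiplier must be >= 0")
    return replace(protocol, dose_multiplier=float(multiplier))


def thermal_ros_drive(T, k_thermal: float = K_THERMAL):
    """Thermal oxidative source term (uM/h) at temperature ``T`` (degC).

    Linear above normothermia, clamped to zero at or below 37 C:
    ``k_thermal * max(0, T - 37)``.
    """
    T = np.asarray(T, dtype=float)
    out = k_thermal * np.maximum(0.0, T - 37.0)
    return float(out) if out.ndim == 0 else out


def standard_protocol(
    dose_multiplier: float = 1.0,
    duration: float = 48.0,
    spacing: float = 2.0,
    amplitude: float = 0.045,
    baseline: float = 0.01,
    tau: float = 0.25,
) -> StressProtocol:
    """The standard repeated-pulse programme: evenly spaced Gaussian ROS
    pulses (default every 2 h over 48 h, i.e. 24 pulses)."""
    times = tuple(np.arange(spacing / 2.0, duration, spacing))
    return StressProtocol(
        ros_baseline=baseline,
        pulse_times=times,
        pulse_amplitude=amplitude,
        pulse_width_tau=tau,
        dose_multiplier=dose_multiplier,
        duration=duration,
    )


def zero_stress_protocol(duration: float = 48.0) -> StressProtocol:
    """A stress-free control programme (no baseline, no pulses)."""
    return StressProtocol(
        ros_baseline=0.0, pulse_times=(), pulse_amplitude=0.0, duration=duration
    )
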