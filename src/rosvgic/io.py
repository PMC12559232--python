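"""Configuration loading/validation and trajectory/dataset serialization.

Plain-text formats throughout: YAML configs, CSV trajectories and feature
tables, JSON metric reports.  Configuration parsing is strict — unknown
keys are rejected, and errors name the offending key.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .presets import PRESET_NAMES, get_preset
from .simulator import SolverOptions, TRAJECTORY_COLUMNS, Trajectory
from .stressors import StressProtocol, standard_protocol

__all__ = ["RunConfig", "load_config", "save_config", "write_trajectory",
           "read_trajectory", "config_hash"]

log = logging.getLogger("rosvgic")

_MODES = ("open_loop", "closed_loop", "dose_response", "dataset", "classify")

_PROTOCOL_KEYS = {
    "ros_baseline", "pulse_times", "pulse_amplitude", "pulse_width_tau",
    "dose_multiplier", "duration_h", "temperature",
}
_SOLVER_KEYS = {
    "method", "rtol", "atol", "sample_dt", "max_step", "vm_model",
    "expression_model", "scenario", "eq13_literal",
}
_EXPRESSION_KEYS = {"model", "eq13_literal", "gate_eps_mV"}
_TOP_KEYS = {"preset", "mode", "protocol", "solver", "expression", "seed",
             "out", "log_level"}


@dataclass(frozen=True)
class RunConfig:
    preset_name: str
    mode: str = "open_loop"
    protocol: StressProtocol = field(default_factory=standard_protocol)
    solver: SolverOptions = field(default_factory=SolverOptions)
    gate_eps_mV: float | None = None  # expression-gate smoothing override
    seed: int | None = None
    out: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        get_preset(self.preset_name)  # raises with the valid names listed
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.mode in ("dataset",) and self.seed is None:
            raise ValueError("seed is required for mode 'dataset'")


def _check_keys(block: dict, allowed: set, where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def _typed(block: dict, key: str, kind, where: str, default=None):
    if key not in block:
        return default
    val = block[key]
    if kind is float and isinstance(val, (int, float)) and not isinstance(val, bool):
        return float(val)
    if not isinstance(val, kind) or isinstance(val, bool) and kind is not bool:
        raise ValueError(f"{where}.{key}: expected {kind.__name__}, got {type(val).__name__}")
    return val


def _parse_protocol(block: dict) -> StressProtocol:
    _check_keys(block, _PROTOCOL_KEYS, "protocol")
    duration = _typed(block, "duration_h", float, "protocol", 48.0)
    if duration is not None and duration <= 0:
        raise ValueError("protocol.duration_h must be > 0")
    kwargs = dict(duration=duration)
    for src, dst in [("ros_baseline", "ros_baseline"),
                     ("pulse_amplitude", "pulse_amplitude"),
                     ("pulse_width_tau", "pulse_width_tau"),
                     ("dose_multiplier", "dose_multiplier")]:
        if src in block:
            kwargs[dst] = _typed(block, src, float, "protocol")
    if "pulse_times" in block:
        kwargs["pulse_times"] = tuple(float(t) for t in block["pulse_times"])
    else:
        kwargs["pulse_times"] = standard_protocol(duration=duration).pulse_times
    if "temperature" in block and block["temperature"] is not None:
        kwargs["temperature_trace"] = tuple(
            (float(a), float(b)) for a, b in block["temperature"]
        )
    return StressProtocol(**kwargs)


def _parse_solver(block: dict) -> SolverOptions:
    _check_keys(block, _SOLVER_KEYS, "solver")
    kwargs = {}
    for key in _SOLVER_KEYS:
        if key in block:
            kwargs[key] = block[key]
    return SolverOptions(**kwargs)


def _apply_expression_block(solver: SolverOptions, block: dict):
    """Fold the ``expression:`` block (model selection, smoothing) into
    the solver options; returns (solver, gate_eps_override)."""
    from dataclasses import replace as _replace

    _check_keys(block, _EXPRESSION_KEYS, "expression")
    if "model" in block:
        solver = _replace(solver, expression_model=block["model"])
    if "eq13_literal" in block:
        solver = _replace(solver, eq13_literal=bool(block["eq13_literal"]))
    eps = block.get("gate_eps_mV")
    if eps is not None and eps <= 0:
        raise ValueError("expression.gate_eps_mV must be > 0")
    return solver, eps


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (strict mode)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    if "preset" not in raw:
        raise ValueError(f"config requires 'preset' (one of {', '.join(PRESET_NAMES)})")
    solver = _parse_solver(raw.get("solver") or {})
    solver, gate_eps = _apply_expression_block(solver, raw.get("expression") or {})
    return RunConfig(
        preset_name=str(raw["preset"]),
        mode=raw.get("mode", "open_loop"),
        protocol=_parse_protocol(raw.get("protocol") or {}),
        solver=solver,
        gate_eps_mV=gate_eps,
        seed=raw.get("seed"),
        out=raw.get("out"),
        log_level=raw.get("log_level", "INFO"),
    )


def _config_dict(cfg: RunConfig) -> dict:
    proto = cfg.protocol
    return {
        "preset": cfg.preset_name,
        "mode": cfg.mode,
        "protocol": {
            "ros_baseline": proto.ros_baseline,
            "pulse_times": list(proto.pulse_times),
            "pulse_amplitude": proto.pulse_amplitude,
            "pulse_width_tau": proto.pulse_width_tau,
            "dose_multiplier": proto.dose_multiplier,
            "duration_h": proto.duration,
            "temperature": (
                [list(p) for p in proto.temperature_trace]
                if proto.temperature_trace is not None else None
            ),
        },
        "solver": asdict(cfg.solver),
        "expression": {"gate_eps_mV": cfg.gate_eps_mV},
        "seed": cfg.seed,
        "out": cfg.out,
        "log_level": cfg.log_level,
    }


def save_config(cfg: RunConfig, path):
    Path(path).write_text(yaml.safe_dump(_config_dict(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    canon = yaml.safe_dump(_config_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_trajectory(traj: Trajectory, path, config: RunConfig | None = None):
    """Write the fixed-schema trajectory CSV (9 significant digits) plus a
    YAML sidecar with the resolved configuration and package version."""
    from . import __version__

    path = Path(path)
    frame = traj.frame[TRAJECTORY_COLUMNS]
    frame.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "package_version": __version__,
        "preset": traj.preset_name,
        "solver_meta": {
            k: v for k, v in traj.solver_meta.items()
            if isinstance(v, (str, int, float, bool))
        },
    }
    if config is not None:
        meta["config"] = _config_dict(config)
        meta["config_hash"] = config_hash(config)
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    log.info("wrote trajectory %s (%d rows)", path, len(frame))


def read_trajectory(path) -> pd.DataFrame:
    """Read back a trajectory CSV, verifying the column schema."""
    frame = pd.read_csv(path)
    if list(frame.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(f"unexpected trajectory columns: {list(frame.columns)}")
    return frame
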