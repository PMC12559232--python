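"""Synthetic labeled trajectory datasets and the malignancy classifier.

Two trajectory populations are generated from the mechanistic simulator:

* ``malignant`` — the supra-threshold repeated-pulse programme (full
  amplitude, enough to open the TRPV/transcription gates) applied to
  transformation-prone presets (MDA-MB-231, HeLa, GBM);
* ``control`` — a sub-threshold programme (pulse amplitude scaled to a
  fifth, whose peaks stay at the TRPV half-activation point) applied to
  healthy presets (MCF10A, fibroblast).

Biological variability is modeled by multiplicative lognormal jitter
(coefficient of variation ``jitter_cv``) on the expression gain, the
pulse amplitude and the intracellular ROS clearance rate.  Labels are the
generating class, never a threshold on any stored feature.  Each
trajectory is summarised by an 8-feature vector and classified with a
random-forest benchmark under stratified k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .presets import get_preset
from .simulator import SolverOptions, Trajectory, SimulationError, run_open_loop
from .stressors import StressProtocol, standard_protocol

__all__ = [
    "DatasetSpec",
    "FEATURE_NAMES",
    "generate_dataset",
    "extract_features",
    "train_and_evaluate",
]

FEATURE_NAMES = [
    "final_vm",
    "vm_slope_late",
    "auc_gNa",
    "auc_ROS_int",
    "mutation_final",
    "proliferation_final",
    "tf_peak",
    "fraction_time_depolarized",
]

#: default class recipes: (protocol factory kwargs, preset names)
_MALIGNANT_PRESETS = ("MDA_MB_231", "HELA", "GBM")
_CONTROL_PRESETS = ("MCF10A", "FIBROBLAST")
#: control pulses are scaled so their peaks sit at the TRPV half-activation
_CONTROL_AMPLITUDE_FACTOR = 0.2


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one labeled synthetic dataset."""

    n_per_class: int = 250
    jitter_cv: float = 0.10
    seed: int = 42
    duration: float = 48.0
    sample_dt: float = 0.05

    def __post_init__(self):
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        if not (0.0 <= self.jitter_cv <= 0.5):
            raise ValueError("jitter_cv must lie in [0, 0.5]")


def _lognormal_factor(rng, cv):
    """Multiplicative jitter with unit median and coefficient of variation
    ``cv`` (sigma of the underlying normal = sqrt(ln(1 + cv^2)))."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(0.0, sigma)))


def _jittered_run(preset_name, amplitude_factor, rng, spec, options):
    preset = get_preset(preset_name)
    f_gain = _lognormal_factor(rng, spec.jitter_cv)
    f_amp = _lognormal_factor(rng, spec.jitter_cv)
    f_clear = _lognormal_factor(rng, spec.jitter_cv)
    preset = replace(
        preset,
        expression=replace(
            preset.expression,
            expression_gain=preset.expression.expression_gain * f_gain,
        ),
        signaling=replace(
            preset.signaling,
            d_ROS_int=preset.signaling.d_ROS_int * f_clear,
        ),
    )
    proto = standard_protocol(
        duration=spec.duration,
        amplitude=0.045 * amplitude_factor * f_amp,
    )
    return run_open_loop(preset, proto, options)


def extract_features(traj: Trajectory) -> np.ndarray:
    """Deterministic 8-feature summary of a trajectory.

    The late Vm slope is the least-squares slope over the final quarter
    of the samples; AUCs are trapezoidal integrals over time.
    """
    t = traj.frame["t_h"].to_numpy()
    if t[-1] - t[0] < 8.0:
        raise ValueError("trajectory must span at least 8 h")
    vm = traj.frame["Vm_mV"].to_numpy()
    n_late = max(2, len(t) // 4)
    tl, vl = t[-n_late:], vm[-n_late:]
    slope = float(np.polyfit(tl, vl, 1)[0]) if np.ptp(tl) > 0 else 0.0
    feats = np.array([
        vm[-1],
        slope,
        np.trapezoid(traj.frame["g_Na"].to_numpy(), t),
        np.trapezoid(traj.frame["ROS_int"].to_numpy(), t),
        traj.frame["mutation"].iloc[-1],
        traj.frame["proliferation"].iloc[-1],
        traj.frame["TF"].max(),
        np.mean(vm >= -30.0),
    ])
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite feature value")
    return feats


def generate_dataset(spec: DatasetSpec, options: SolverOptions | None = None) -> pd.DataFrame:
    """Generate the labeled feature table (one row per trajectory).

    Reproducible given ``spec.seed``; a failing simulation is skipped and
    recorded in ``frame.attrs['skipped']``, never relabeled.
    """
    options = options if options is not None else SolverOptions(sample_dt=spec.sample_dt)
    rng = np.random.default_rng(spec.seed)
    rows, labels, skipped = [], [], []
    recipes = [
        ("malignant", 1.0, _MALIGNANT_PRESETS),
        ("control", _CONTROL_AMPLITUDE_FACTOR, _CONTROL_PRESETS),
    ]
    for label, amp_factor, presets in recipes:
        for i in range(spec.n_per_class):
            name = presets[i % len(presets)]
            try:
                traj = _jittered_run(name, amp_factor, rng, spec, options)
                rows.append(extract_features(traj))
                labels.append(label)
            except (SimulationError, ValueError) as exc:  # skip, never relabel
                skipped.append((label, name, str(exc)))
    frame = pd.DataFrame(rows, columns=FEATURE_NAMES)
    frame["label"] = labels
    frame.attrs["skipped"] = skipped
    frame.attrs["spec"] = {
        "n_per_class": spec.n_per_class, "jitter_cv": spec.jitter_cv,
        "seed": spec.seed, "duration": spec.duration,
    }
    return frame


def train_and_evaluate(dataset: pd.DataFrame, folds: int = 5, seed: int = 7) -> dict:
    """Stratified k-fold cross-validation of the random-forest benchmark.

    Returns mean accuracy, per-fold accuracies and pooled confusion
    counts; deterministic given ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = dataset[FEATURE_NAMES].to_numpy()
    y = (dataset["label"] == "malignant").to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    confusion = np.zeros((2, 2), dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        clf = RandomForestClassifier(n_estimators=200, random_state=seed)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        for a, b in zip(y[test_idx], pred):
            confusion[a, b] += 1
    return {
        "mean_accuracy": float(np.mean(fold_acc)),
        "fold_accuracies": fold_acc,
        "confusion": confusion.tolist(),
        "n_samples": int(len(y)),
    }
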