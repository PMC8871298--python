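"""Synthetic breath-analyzer cohorts with controlled curve-shape structure.

The generator emulates the data model of the device: per measurement, a
room-air baseline phase and a breath phase per sensor, for a 26-sensor array
(8 GNP + 8 analogue MOX + 10 digital MOX), written in the same JSON dialect
the reader consumes.  Cohort sizes default to 54 cancer / 85 control
measurements, mirroring a realistic two-class clinical study.

Curves follow a rise–plateau–decay morphology (rapid rise after the breath
reaches the chamber, a plateau, slow recovery) around a unit ratio baseline;
no claim of fidelity to sensor physics is made.  Class signal is carried by
the prototype *shapes* on a configurable fraction of sensors.  Faulty
measurements (a missing sensor trace) and outliers (response deviation
amplified ×10) are injected at configurable rates, with ground truth
recorded for recovery tests.

``simulate_shape_only_cohort`` is the adversarial variant for the
shape-vs-summary experiment: the cancer prototype of a signal sensor is the
*time reversal* of the control prototype, built with identical flat unit
segments at both ends, so minimum, maximum, mean, trapezoidal AUC and
end-mean coincide exactly across classes while pointwise and warping
distances separate the shapes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .common_features import COMMON_FEATURES, extract_common
from .measurement_io import (
    BreathMeasurement,
    Cohort,
    RawSensorTrace,
    write_measurement,
)

DEFAULT_FAMILIES = (("GNP", 8), ("MOXA", 8), ("MOXD", 10))


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Units: series values are raw device signal units (the baseline level sets
    the scale; normalized curves live around 1.0); ``noise_sd`` and
    ``separation`` are in normalized-response units; rates are probabilities
    per measurement.
    """

    n_cancer: int = 54
    n_control: int = 85
    n_sensors: int = 26
    T: int = 120                       # breath-phase time points
    baseline_T: int = 40               # room-air phase time points
    n_prototypes: int = 2              # shape templates per class per sensor
    shape_signal: float = 0.5          # fraction of sensors with class-distinct shapes
    separation: float = 0.25           # amplitude gap between adjacent prototypes
    noise_sd: float = 0.05             # gaussian noise on the normalized curve
    baseline_level: float = 10.0       # raw-unit room-air level
    baseline_drift: float = 0.01       # fractional drift across the baseline phase
    outlier_rate: float = 0.02
    missing_sensor_rate: float = 12.0 / 139.0
    sampling_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shape_signal", "outlier_rate", "missing_sensor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cancer < 2 or self.n_control < 2:
            raise ValueError("need at least 2 measurements per class")
        if self.n_sensors < 1:
            raise ValueError("need at least 1 sensor")
        if self.T < 30:
            raise ValueError("T must be at least 30")
        if self.baseline_T < 10:
            raise ValueError("baseline_T must be at least 10")
        if self.n_prototypes < 1:
            raise ValueError("n_prototypes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimResult:
    cohort: Cohort
    truth: pd.DataFrame     # measurement_id, class, prototype_id, outlier, missing_sensor

    def write(self, out_dir: str | Path) -> dict:
        """Write device JSON files, sample sheet, ground truth and a manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for m in self.cohort.measurements:
            p = out_dir / f"{m.measurement_id}.json"
            write_measurement(m, p)
            paths.append(str(p))
        with open(out_dir / "sample_sheet.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["measurement_id", "label"])
            for m in self.cohort.measurements:
                writer.writerow([m.measurement_id, m.class_label])
        self.truth[["measurement_id", "class", "prototype_id"]].to_csv(
            out_dir / "ground_truth.csv", index=False
        )
        manifest = {"schema_version": self.cohort.schema_version, "files": paths}
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest


def sensor_ids(n_sensors: int = 26) -> list[str]:
    """Sensor identifiers, cycled through the 8/8/10 GNP/MOXA/MOXD layout."""
    ids: list[str] = []
    for family, count in DEFAULT_FAMILIES:
        for i in range(count):
            ids.append(f"{family}{i + 1:02d}")
    if n_sensors <= len(ids):
        return ids[:n_sensors]
    extra = [f"MOXD{i + 1:02d}" for i in range(10, 10 + n_sensors - len(ids))]
    return ids + extra


def _family_of(sensor_id: str) -> str:
    for family, _ in DEFAULT_FAMILIES:
        if sensor_id.startswith(family):
            return family
    return "MOXD"


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def response_prototype(
    T: int,
    amplitude: float,
    rise_start: int,
    rise_len: int,
    decay_start: int,
    decay_len: int,
) -> np.ndarray:
    """Rise–plateau–decay template around a unit baseline ratio."""
    t = np.arange(T, dtype=float)
    rise = _smoothstep((t - rise_start) / max(rise_len, 1))
    fall = 1.0 - _smoothstep((t - decay_start) / max(decay_len, 1))
    return 1.0 + amplitude * rise * fall


def _cohort_prototypes(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Per-sensor, per-class prototype curves.

    All 2·g prototypes of a signal sensor occupy interleaved amplitude slots
    separated by ``cfg.separation`` (controls on even slots, cancer on odd),
    so every pair of prototypes is pointwise separated on the plateau.
    Non-signal sensors share one prototype set across classes.
    """
    sids = sensor_ids(cfg.n_sensors)
    n_signal = int(round(cfg.shape_signal * cfg.n_sensors))
    signal_set = set(sids[:n_signal])
    prototypes: dict[str, dict[str, list[np.ndarray]]] = {}
    for sid in sids:
        base_amp = rng.uniform(0.3, 0.6)
        rise_start = int(rng.integers(8, 16))
        rise_len = int(rng.integers(6, 12))
        decay_start = int(cfg.T * rng.uniform(0.55, 0.7))
        decay_len = int(rng.integers(20, 40))
        per_class: dict[str, list[np.ndarray]] = {"control": [], "cancer": []}
        for j in range(cfg.n_prototypes):
            for ci, label in enumerate(("control", "cancer")):
                if sid in signal_set:
                    slot = 2 * j + ci
                    amp = base_amp + slot * cfg.separation
                    shift = 3 * ci          # cancer responds slightly later
                else:
                    amp = base_amp + j * cfg.separation
                    shift = 0
                per_class[label].append(
                    response_prototype(
                        cfg.T, amp, rise_start + shift, rise_len,
                        decay_start + shift, decay_len,
                    )
                )
        prototypes[sid] = per_class
    return prototypes


def _shape_only_prototypes(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Control prototype and its exact time reversal for the cancer class."""
    flat = 12
    min_decay = 6
    sids = sensor_ids(cfg.n_sensors)
    n_signal = int(round(cfg.shape_signal * cfg.n_sensors))
    signal_set = set(sids[:n_signal])
    prototypes: dict[str, dict[str, list[np.ndarray]]] = {}
    for sid in sids:
        amp = rng.uniform(0.4, 0.8)
        rise_len = int(rng.integers(6, 10))
        plateau_len = int(rng.integers(15, 25))
        decay_len = cfg.T - 2 * flat - rise_len - plateau_len
        if decay_len < min_decay:
            raise ValueError(
                f"cannot satisfy summary-match for requested T={cfg.T}"
            )
        t = np.arange(cfg.T, dtype=float)
        rise = _smoothstep((t - flat) / rise_len)
        fall = 1.0 - _smoothstep((t - (flat + rise_len + plateau_len)) / decay_len)
        control = 1.0 + amp * rise * fall
        control[:flat] = 1.0
        control[cfg.T - flat:] = 1.0
        cancer = control[::-1].copy() if sid in signal_set else control
        prototypes[sid] = {"control": [control], "cancer": [cancer]}
    return prototypes


def _emit_cohort(
    cfg: SimConfig,
    prototypes: dict[str, dict[str, list[np.ndarray]]],
    rng: np.random.Generator,
) -> SimResult:
    sids = sensor_ids(cfg.n_sensors)
    g = len(prototypes[sids[0]]["control"])
    labels = ["cancer"] * cfg.n_cancer + ["control"] * cfg.n_control
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    measurements = []
    truth_rows = []
    for i, label in enumerate(labels):
        mid = f"M{i + 1:03d}"
        proto_idx = int(rng.integers(g))
        is_outlier = bool(rng.random() < cfg.outlier_rate)
        missing = None
        if rng.random() < cfg.missing_sensor_rate:
            missing = sids[int(rng.integers(len(sids)))]
        sensors: dict[str, RawSensorTrace] = {}
        for sid in sids:
            if sid == missing:
                continue
            level = cfg.baseline_level * (1.0 + 0.1 * (sum(map(ord, sid)) % 7) / 7.0)
            drift = np.linspace(0.0, cfg.baseline_drift, cfg.baseline_T)
            baseline = level * (
                1.0 + drift + 0.1 * cfg.noise_sd * rng.standard_normal(cfg.baseline_T)
            )
            r = float(np.mean(baseline[-10:]))
            curve = prototypes[sid][label][proto_idx]
            normalized = curve + cfg.noise_sd * rng.standard_normal(cfg.T)
            if is_outlier:
                normalized = 1.0 + 10.0 * (normalized - 1.0)
            jitter = int(rng.integers(0, 5))
            if jitter:
                pre = 1.0 + cfg.noise_sd * rng.standard_normal(jitter)
                normalized = np.concatenate([pre, normalized])
            sensors[sid] = RawSensorTrace(
                sensor_id=sid,
                sensor_family=_family_of(sid),
                sampling_interval=cfg.sampling_interval,
                baseline_values=baseline,
                breath_values=r * normalized,
            )
        measurements.append(
            BreathMeasurement(
                measurement_id=mid,
                class_label=label,
                metadata={"seed": str(cfg.seed), "index": str(i)},
                sensors=sensors,
            )
        )
        truth_rows.append(
            {
                "measurement_id": mid,
                "class": label,
                "prototype_id": f"{label}_{proto_idx}",
                "outlier": is_outlier,
                "missing_sensor": missing or "",
            }
        )
    return SimResult(
        cohort=Cohort(measurements=measurements),
        truth=pd.DataFrame(truth_rows),
    )


def simulate_cohort(cfg: SimConfig | None = None) -> SimResult:
    """Generate a two-class cohort with class-distinct prototype shapes."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    prototypes = _cohort_prototypes(cfg, rng)
    return _emit_cohort(cfg, prototypes, rng)


def simulate_shape_only_cohort(cfg: SimConfig | None = None) -> SimResult:
    """Generate a cohort whose class signal is invisible to scalar summaries.

    Cancer prototypes are exact time reversals of control prototypes with
    matched flat ends, so per-sensor minimum / maximum / mean / AUC /
    end-mean distributions coincide across classes while the curve shapes
    differ.  The generator verifies the summary-match property on its own
    output and raises if it cannot be satisfied.
    """
    cfg = cfg or SimConfig()
    if cfg.T < 60:
        raise ValueError(f"cannot satisfy summary-match for requested T={cfg.T}")
    rng = np.random.default_rng(cfg.seed)
    prototypes = _shape_only_prototypes(cfg, rng)
    result = _emit_cohort(cfg, prototypes, rng)
    _assert_summary_match(cfg, prototypes)
    return result


def _assert_summary_match(cfg: SimConfig, prototypes: dict) -> None:
    """Noise-free prototypes must agree on every common feature across classes."""
    tol = max(cfg.noise_sd / 2.0, 1e-9)
    for sid, per_class in prototypes.items():
        for ctrl, canc in zip(per_class["control"], per_class["cancer"]):
            f_ctrl = extract_common(ctrl)
            f_canc = extract_common(canc)
            for name, a, b in zip(COMMON_FEATURES, f_ctrl, f_canc):
                if abs(a - b) > tol:
                    raise ValueError(
                        f"summary-match violated for sensor {sid!r} "
                        f"feature {name!r}: |{a} - {b}| > {tol}"
                    )
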