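"""Reading, writing and screening of breath-analyzer measurements.

A measurement is one subject's exhalation recorded by a multi-sensor array
(gold-nanoparticle chemiresistors plus analogue and digital metal-oxide
sensors).  Each sensor contributes two raw time series: a room-air *baseline*
phase recorded before the breath enters the chamber, and the *breath* phase
itself.  The device stores everything for one measurement in a single JSON
file; this module defines a versioned dialect of that file, validates it on
read, and assembles cohorts for the downstream pipeline.

The class label (``cancer`` / ``control``) may live in the file itself (the
synthetic generator writes it there) or be supplied separately through a
two-column sample sheet ``measurement_id,label``, since a real device file
would not know the histology.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

SCHEMA_VERSION = "1.0"
SENSOR_FAMILIES = ("GNP", "MOXA", "MOXD")
CLASS_LABELS = ("cancer", "control", "unknown")


class SchemaError(ValueError):
    """A device file or record violates the measurement schema."""


@dataclass
class RawSensorTrace:
    """Raw baseline and breath series of one sensor, in device signal units."""

    sensor_id: str
    sensor_family: str
    sampling_interval: float
    baseline_values: np.ndarray
    breath_values: np.ndarray

    def __post_init__(self) -> None:
        if self.sensor_family not in SENSOR_FAMILIES:
            raise SchemaError(
                f"sensor {self.sensor_id!r}: unknown family {self.sensor_family!r}"
            )
        if not self.sampling_interval > 0:
            raise SchemaError(
                f"sensor {self.sensor_id!r}: sampling_interval must be > 0"
            )
        self.baseline_values = _as_series(self.baseline_values, self.sensor_id, "baseline")
        self.breath_values = _as_series(self.breath_values, self.sensor_id, "breath")

    @property
    def is_valid(self) -> bool:
        return self.baseline_values.size > 0 and self.breath_values.size > 0


@dataclass
class BreathMeasurement:
    """One subject's metadata plus per-sensor baseline/breath traces."""

    measurement_id: str
    class_label: str
    metadata: dict[str, str] = field(default_factory=dict)
    sensors: dict[str, RawSensorTrace] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise SchemaError(
                f"measurement {self.measurement_id!r}: "
                f"unknown class label {self.class_label!r}"
            )
        for sensor_id, trace in self.sensors.items():
            if sensor_id != trace.sensor_id:
                raise SchemaError(
                    f"measurement {self.measurement_id!r}: sensors map key "
                    f"{sensor_id!r} does not match trace id {trace.sensor_id!r}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BreathMeasurement):
            return NotImplemented
        if (
            self.measurement_id != other.measurement_id
            or self.class_label != other.class_label
            or self.metadata != other.metadata
            or self.excluded != other.excluded
            or self.exclusion_reason != other.exclusion_reason
            or set(self.sensors) != set(other.sensors)
        ):
            return False
        for sid, trace in self.sensors.items():
            o = other.sensors[sid]
            if (
                trace.sensor_family != o.sensor_family
                or trace.sampling_interval != o.sampling_interval
                or not np.array_equal(trace.baseline_values, o.baseline_values)
                or not np.array_equal(trace.breath_values, o.breath_values)
            ):
                return False
        return True


@dataclass
class Cohort:
    """An ordered collection of measurements sharing one schema version."""

    measurements: list[BreathMeasurement]
    schema_version: str = SCHEMA_VERSION

    def kept(self) -> list[BreathMeasurement]:
        return [m for m in self.measurements if not m.excluded]

    def class_counts(self, kept_only: bool = True) -> dict[str, int]:
        counts: dict[str, int] = {}
        pool = self.kept() if kept_only else self.measurements
        for m in pool:
            counts[m.class_label] = counts.get(m.class_label, 0) + 1
        return counts

    def labels(self) -> dict[str, str]:
        return {m.measurement_id: m.class_label for m in self.kept()}


def _as_series(values: Sequence[float], sensor_id: str, phase: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise SchemaError(f"sensor {sensor_id!r}: {phase} series must be 1-D")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValueError(
            f"sensor {sensor_id!r}: non-finite {phase} value at index {int(bad[0])}"
        )
    return arr


def _require(obj: Mapping, key: str, context: str):
    if key not in obj:
        raise SchemaError(f"{context}: missing required key {key!r}")
    return obj[key]


def _numeric_list(values, context: str) -> list[float]:
    if not isinstance(values, list):
        raise SchemaError(f"{context}: expected a list of numbers")
    out = []
    for i, v in enumerate(values):
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise ValueError(f"{context}: non-numeric entry at index {i}")
        if not math.isfinite(v):
            raise ValueError(f"{context}: non-finite entry at index {i}")
        out.append(float(v))
    return out


def measurement_from_dict(doc: Mapping, source: str = "<memory>") -> BreathMeasurement:
    """Validate a parsed device-dialect document into a typed record."""
    version = _require(doc, "schema_version", source)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"{source}: unsupported schema_version {version!r}")
    mid = _require(doc, "measurement_id", source)
    label = doc.get("label", "unknown")
    metadata = doc.get("metadata", {})
    if not isinstance(metadata, Mapping):
        raise SchemaError(f"{source}: metadata must be a mapping")
    sensors_doc = _require(doc, "sensors", source)
    if not isinstance(sensors_doc, list):
        raise SchemaError(f"{source}: sensors must be a list")
    sensors: dict[str, RawSensorTrace] = {}
    for entry in sensors_doc:
        sid = _require(entry, "sensor_id", source)
        ctx = f"{source}: sensor {sid!r}"
        if sid in sensors:
            raise SchemaError(f"{ctx}: duplicate sensor_id")
        trace = RawSensorTrace(
            sensor_id=sid,
            sensor_family=_require(entry, "family", ctx),
            sampling_interval=float(_require(entry, "sampling_interval_s", ctx)),
            baseline_values=np.array(
                _numeric_list(_require(entry, "baseline", ctx), f"{ctx} baseline")
            ),
            breath_values=np.array(
                _numeric_list(_require(entry, "breath", ctx), f"{ctx} breath")
            ),
        )
        sensors[sid] = trace
    return BreathMeasurement(
        measurement_id=str(mid),
        class_label=str(label),
        metadata={str(k): str(v) for k, v in metadata.items()},
        sensors=sensors,
        excluded=bool(doc.get("excluded", False)),
        exclusion_reason=doc.get("exclusion_reason"),
    )


def measurement_to_dict(m: BreathMeasurement) -> dict:
    if not m.sensors:
        raise SchemaError(
            f"measurement {m.measurement_id!r}: refusing to write empty sensors map"
        )
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "measurement_id": m.measurement_id,
        "label": m.class_label,
        "metadata": dict(m.metadata),
        "sensors": [
            {
                "sensor_id": t.sensor_id,
                "family": t.sensor_family,
                "sampling_interval_s": t.sampling_interval,
                "baseline": t.baseline_values.tolist(),
                "breath": t.breath_values.tolist(),
            }
            for t in m.sensors.values()
        ],
    }
    if m.excluded:
        doc["excluded"] = True
        doc["exclusion_reason"] = m.exclusion_reason
    return doc


def read_measurement(path: str | Path) -> BreathMeasurement:
    """Read and validate one device-dialect JSON file.

    Unparseable or schema-violating files raise; they are never silently
    skipped.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return measurement_from_dict(doc, source=str(path))


def write_measurement(m: BreathMeasurement, path: str | Path) -> None:
    """Write a measurement as device-dialect JSON.

    Floats are serialized via ``repr`` (the ``json`` default), which
    round-trips IEEE doubles bit-exactly, so ``read(write(m)) == m``.
    """
    doc = measurement_to_dict(m)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=1)


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read a ``measurement_id,label`` CSV mapping ids to class labels."""
    labels: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["measurement_id", "label"]:
            raise SchemaError(f"{path}: expected header 'measurement_id,label'")
        for row in reader:
            if not row:
                continue
            labels[row[0]] = row[1]
    return labels


def load_cohort(
    paths: Iterable[str | Path],
    sample_sheet: str | Path | None = None,
) -> Cohort:
    """Assemble a cohort from device files, optionally relabelling from a sheet."""
    sheet = read_sample_sheet(sample_sheet) if sample_sheet is not None else None
    measurements = []
    for p in paths:
        m = read_measurement(p)
        if sheet is not None:
            if m.measurement_id not in sheet:
                raise SchemaError(
                    f"sample sheet has no label for {m.measurement_id!r}"
                )
            m = replace(m, class_label=sheet[m.measurement_id])
        measurements.append(m)
    ids = [m.measurement_id for m in measurements]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate measurement_id in cohort")
    return Cohort(measurements=measurements)


def screen_cohort(cohort: Cohort, required_sensors: Iterable[str]) -> Cohort:
    """Exclude measurements that lack (or have empty traces for) a required sensor.

    Measurements recorded with technical faults — a sensor never reported, or
    reported an empty series — cannot enter shape analysis; they are marked
    ``excluded`` with reason ``missing_sensor:<id>`` but stay listed in the
    returned cohort.  Screening is idempotent and label-blind.
    """
    required = sorted(set(required_sensors))
    if not required:
        raise ValueError("required_sensors must be non-empty")
    screened = []
    n_excluded = 0
    for m in cohort.measurements:
        reason = m.exclusion_reason
        excluded = m.excluded
        if not excluded:
            for sid in required:
                trace = m.sensors.get(sid)
                if trace is None or not trace.is_valid:
                    excluded = True
                    reason = f"missing_sensor:{sid}"
                    break
        if excluded:
            n_excluded += 1
        screened.append(replace(m, excluded=excluded, exclusion_reason=reason))
    kept = len(screened) - n_excluded
    if kept == 0:
        raise ValueError("empty cohort after screening")
    return Cohort(measurements=screened, schema_version=cohort.schema_version)
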