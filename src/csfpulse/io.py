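"""File formats: delimited waveform tables, NIfTI velocity series with JSON
sidecars, pipeline configuration and JSON reports."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .image import VelocityImageSeries
from .waveform import FlowWaveform

__all__ = [
    "PipelineConfig",
    "write_waveform",
    "read_waveform",
    "write_series",
    "read_series",
    "write_report",
]

_WAVEFORM_COLUMNS = "time_ms\tflow_ml_s"


@dataclass
class PipelineConfig:
    """End-to-end analysis settings (defaults mirror the study's printed
    processing parameters)."""

    nominal_cycle_ms: float = 1000.0
    resample_dt_ms: float = 10.0
    tf_order: int = 5
    venc_cm_s: dict = field(
        default_factory=lambda: {"arterial": 100.0, "spinal": 12.0, "aqueduct": 15.0}
    )
    component_counts: dict = field(
        default_factory=lambda: {"arterial": 10, "spinal": 7, "aqueduct": 5}
    )
    noise_limit_hz: dict = field(default_factory=lambda: {"spinal": 7.0, "aqueduct": 5.0})
    bode_df_hz: float = 0.05
    stroke_volume_threshold_ul: float = 42.0
    average_flow_threshold_ml_min: float = 18.0
    n_subjects: int = 11
    seed: int = 0

    def __post_init__(self):
        if self.resample_dt_ms <= 0 or (self.nominal_cycle_ms % self.resample_dt_ms):
            raise ValueError("resample interval must divide the nominal cycle")
        if self.tf_order < 1:
            raise ValueError("transfer-function order must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_waveform(w: FlowWaveform, path):
    """Waveform as a delimited text table with a metadata header."""
    sys_end = "None" if w.systole_end_ms is None else f"{float(w.systole_end_ms):.17g}"
    lines = [
        f"# compartment: {w.compartment}",
        f"# heart_period_ms: {float(w.heart_period_ms):.17g}",
        f"# systole_end_ms: {sys_end}",
        f"# amplitude_mode: {w.amplitude_mode}",
        f"# time_normalized: {w.time_normalized}",
        f"# cranial_positive: {w.cranial_positive}",
        _WAVEFORM_COLUMNS,
    ]
    lines += [f"{t:.17g}\t{v:.17g}" for t, v in zip(w.times_ms, w.flow)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_waveform(path) -> FlowWaveform:
    """Read a waveform table written by :func:`write_waveform` (lossless
    round trip)."""
    meta: dict = {}
    times, flows = [], []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            if line != _WAVEFORM_COLUMNS:
                raise ValueError(
                    f"missing or malformed units header: expected {_WAVEFORM_COLUMNS!r}"
                )
            header_seen = True
            continue
        t, v = line.split("\t")
        times.append(float(t))
        flows.append(float(v))
    if not header_seen:
        raise ValueError(f"missing or malformed units header: expected {_WAVEFORM_COLUMNS!r}")
    if "heart_period_ms" not in meta:
        raise ValueError("missing heart_period_ms header")
    times = np.array(times)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("time column must be strictly increasing")
    sys_end = meta.get("systole_end_ms", "None")
    return FlowWaveform(
        times_ms=times,
        flow=np.array(flows),
        heart_period_ms=float(meta["heart_period_ms"]),
        systole_end_ms=None if sys_end == "None" else float(sys_end),
        compartment=meta.get("compartment", ""),
        cranial_positive=meta.get("cranial_positive", "True") == "True",
        amplitude_mode=meta.get("amplitude_mode", "none"),
        time_normalized=meta.get("time_normalized", "False") == "True",
    )


def write_series(series: VelocityImageSeries, base_path):
    """Velocity series as phase/magnitude NIfTI stacks (frames along the
    third axis) plus a JSON sidecar with the acquisition metadata."""
    base = Path(base_path)
    affine = np.diag([series.pixel_mm[0], series.pixel_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.moveaxis(series.phase, 0, -1), affine),
             str(base) + "_phase.nii")
    nib.save(nib.Nifti1Image(np.moveaxis(series.magnitude, 0, -1), affine),
             str(base) + "_mag.nii")
    sidecar = {
        "venc_cm_s": series.venc_cm_s,
        "pixel_mm": list(series.pixel_mm),
        "frame_times_ms": [float(t) for t in series.frame_times_ms],
        "compartment": series.compartment,
        "wrapped": series.wrapped,
        "heart_period_ms": series.meta.get("heart_period_ms"),
    }
    Path(str(base) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_series(base_path) -> VelocityImageSeries:
    base = Path(base_path)
    sidecar = json.loads(Path(str(base) + ".json").read_text())
    for key in ("venc_cm_s", "pixel_mm", "frame_times_ms"):
        if sidecar.get(key) is None:
            raise ValueError(f"sidecar missing required field {key!r}")
    phase = np.moveaxis(
        np.asarray(nib.load(str(base) + "_phase.nii").dataobj, dtype=float), -1, 0
    )
    mag = np.moveaxis(
        np.asarray(nib.load(str(base) + "_mag.nii").dataobj, dtype=float), -1, 0
    )
    if phase.shape[0] != len(sidecar["frame_times_ms"]):
        raise ValueError("sidecar/stack frame-count mismatch")
    meta = {}
    if sidecar.get("heart_period_ms") is not None:
        meta["heart_period_ms"] = sidecar["heart_period_ms"]
    return VelocityImageSeries(
        phase=phase,
        magnitude=mag,
        venc_cm_s=float(sidecar["venc_cm_s"]),
        pixel_mm=tuple(sidecar["pixel_mm"]),
        frame_times_ms=np.array(sidecar["frame_times_ms"]),
        compartment=sidecar.get("compartment", ""),
        wrapped=bool(sidecar.get("wrapped", True)),
        meta=meta,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path):
    Path(path).write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))
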