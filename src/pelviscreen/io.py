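"""Reading and writing the tool's plain-text formats.

Formats (all delimited text / YAML / JSON):

* trace CSV — header ``t,ax,ay,az``; time in seconds, accelerations in g
  (a unit scale factor converts raw sensor units on ingest);
* session YAML — ``patient_id``, optional ``covariates``, and an ordered
  ``captures`` list of ``{position, trace, reference_tilt_deg}`` entries
  with trace paths relative to the YAML file;
* paired-measures CSV — ``patient_id,position,device_delta_deg,
  reference_delta_deg``;
* reports — JSON plus a human-readable text rendering; angles are
  serialized with three decimal places.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imu_core import DEFAULT_SAMPLE_RATE_HZ, AccelTrace
from .screening import PositionCapture, ScreeningReport, SessionRecord
from .validation_stats import PairedMeasures

__all__ = [
    "read_trace",
    "write_trace",
    "load_session",
    "write_session",
    "read_paired_measures",
    "write_paired_measures",
    "screening_report_dict",
    "screening_report_text",
]

TRACE_COLUMNS = ("t", "ax", "ay", "az")


def read_trace(path, unit_scale_to_g: float = 1.0,
               sample_rate_hz: float | None = None) -> AccelTrace:
    """Read a capture from a trace CSV.

    ``unit_scale_to_g`` multiplies the acceleration channels (e.g. to
    convert raw mV output to g).  If ``sample_rate_hz`` is omitted it is
    inferred from the median timestamp spacing (falling back to the 200 Hz
    default for single-sample files).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parse error types
        raise ValueError(f"could not parse trace file {path}: {exc}") from exc
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"trace file {path} is missing columns {sorted(missing)}; "
            f"expected header {','.join(TRACE_COLUMNS)}"
        )
    for col in TRACE_COLUMNS:
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 one-based
            raise ValueError(f"non-numeric or non-finite value in {path}, column {col!r}, line {line}")
    t = df["t"].to_numpy(float)
    if sample_rate_hz is None:
        dt = np.median(np.diff(t)) if t.size > 1 else None
        sample_rate_hz = 1.0 / dt if dt and dt > 0 else DEFAULT_SAMPLE_RATE_HZ
    return AccelTrace(
        t=t,
        a_x=df["ax"].to_numpy(float) * unit_scale_to_g,
        a_y=df["ay"].to_numpy(float) * unit_scale_to_g,
        a_z=df["az"].to_numpy(float) * unit_scale_to_g,
        sample_rate_hz=sample_rate_hz,
    )


def write_trace(trace: AccelTrace, path) -> None:
    df = pd.DataFrame({"t": trace.t, "ax": trace.a_x, "ay": trace.a_y, "az": trace.a_z})
    df.to_csv(path, index=False, float_format="%.6f")


def load_session(path, unit_scale_to_g: float = 1.0) -> SessionRecord:
    """Load a session YAML and all the trace files it references."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "captures" not in data:
        raise ValueError(f"session file {path} must define 'patient_id' and 'captures'")
    captures = []
    for entry in data["captures"]:
        trace = read_trace(path.parent / entry["trace"], unit_scale_to_g)
        captures.append(
            PositionCapture(
                position=entry["position"],
                trace=trace,
                reference_tilt_deg=entry.get("reference_tilt_deg"),
            )
        )
    return SessionRecord(
        patient_id=str(data.get("patient_id", path.stem)),
        captures=tuple(captures),
        covariates=data.get("covariates") or {},
    )


def write_session(session: SessionRecord, out_dir) -> Path:
    """Write a session as session.yaml plus one trace CSV per capture.

    Returns the path of the session YAML.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, cap in enumerate(session.captures):
        fname = f"capture_{i:02d}_{cap.position.value}.csv"
        write_trace(cap.trace, out_dir / fname)
        entry = {"position": cap.position.value, "trace": fname}
        if cap.reference_tilt_deg is not None:
            entry["reference_tilt_deg"] = round(float(cap.reference_tilt_deg), 3)
        entries.append(entry)
    doc = {
        "patient_id": session.patient_id,
        "covariates": dict(session.covariates),
        "captures": entries,
    }
    out = out_dir / "session.yaml"
    out.write_text(yaml.safe_dump(doc, sort_keys=False))
    return out


def read_paired_measures(path) -> PairedMeasures:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"could not parse paired-measures file {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"paired-measures file {path} contains no rows")
    return PairedMeasures.from_frame(df)


def write_paired_measures(pairs: PairedMeasures, path) -> None:
    pairs.to_frame().to_csv(path, index=False, float_format="%.3f")


def _round_angles(obj):
    if isinstance(obj, float):
        return round(obj, 3)
    if isinstance(obj, dict):
        return {k: _round_angles(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_angles(v) for v in obj]
    return obj


def screening_report_dict(report: ScreeningReport, run_config: dict | None = None) -> dict:
    """JSON-ready rendering of a screening report, with window diagnostics."""
    doc = {
        "patient_id": report.patient_id,
        "high_mobility": report.high_mobility,
        "threshold_deg": report.threshold_deg,
        "fs_only": report.fs_only,
        "positions": [
            {
                "position": r.position.value,
                "delta_pitch_deg": r.delta_pitch_deg,
                "high_mobility": r.high_mobility,
                "baseline_pitch_deg": r.baseline_pitch_deg,
                "functional_pitch_deg": r.functional_pitch_deg,
                "baseline_window": {
                    "start_s": r.baseline_estimate.window_start_s,
                    "end_s": r.baseline_estimate.window_end_s,
                    "sd_deg": r.baseline_estimate.window_sd_deg,
                },
                "functional_window": {
                    "start_s": r.functional_estimate.window_start_s,
                    "end_s": r.functional_estimate.window_end_s,
                    "sd_deg": r.functional_estimate.window_sd_deg,
                },
            }
            for r in report.results
        ],
    }
    if run_config is not None:
        doc["config"] = run_config
    return _round_angles(doc)


def screening_report_text(report: ScreeningReport) -> str:
    lines = [
        f"Screening report — patient {report.patient_id}",
        f"Threshold: |Δ pitch| ≥ {report.threshold_deg:g}°"
        + (" (flexed-seated only)" if report.fs_only else ""),
        "",
    ]
    for r in report.results:
        flag = "HIGH" if r.high_mobility else "low"
        lines.append(
            f"  {r.position.value:<14} Δ = {r.delta_pitch_deg:+7.3f}°  "
            f"(standing {r.baseline_pitch_deg:+.3f}° → {r.functional_pitch_deg:+.3f}°)  [{flag}]"
        )
    verdict = "HIGH pelvic mobility — refer for detailed planning" \
        if report.high_mobility else "low pelvic mobility"
    lines += ["", f"Overall: {verdict}"]
    return "\n".join(lines) + "\n"


def write_json(doc: dict, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
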