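"""Reading and writing recording bundles and result files.

A recording bundle is a directory containing ``manifest.json`` (neuron id,
baseline temperature, latencies, trace file names) plus one CSV per stimulus
with header ``time_s,temp_C``.  Results are JSON throughout; temperatures in
deg C, times in s, depths in both mm and um.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classical import Recording
from .thermal import StimulusTrace

MANIFEST = "manifest.json"


class RecordingLoadError(ValueError):
    """A structured load failure naming the offending stimulus or field."""


def write_recording(recording: Recording, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    trace_files = []
    for i, trace in enumerate(recording.traces):
        name = f"stimulus_{i:02d}.csv"
        pd.DataFrame({"time_s": trace.times, "temp_C": trace.temperatures}) \
            .to_csv(d / name, index=False)
        trace_files.append(name)
    manifest = {
        "neuron_id": recording.neuron_id,
        "T0_C": recording.T0,
        "latencies_s": [float(x) for x in recording.latencies],
        "trace_files": trace_files,
    }
    (d / MANIFEST).write_text(json.dumps(manifest, indent=2))
    return d


def read_recording(directory) -> Recording:
    d = Path(directory)
    manifest_path = d / MANIFEST
    if not manifest_path.exists():
        raise RecordingLoadError(f"no {MANIFEST} in {d}")
    manifest = json.loads(manifest_path.read_text())
    for key in ("T0_C", "latencies_s", "trace_files"):
        if key not in manifest:
            raise RecordingLoadError(f"manifest missing field {key!r}")
    latencies = np.asarray(manifest["latencies_s"], dtype=float)
    files = manifest["trace_files"]
    if len(files) != len(latencies):
        raise RecordingLoadError("manifest: one latency per trace file required")
    traces = []
    for i, name in enumerate(files):
        path = d / name
        if not path.exists():
            raise RecordingLoadError(f"stimulus {i}: trace file {name} missing")
        df = pd.read_csv(path)
        if not {"time_s", "temp_C"} <= set(df.columns):
            raise RecordingLoadError(
                f"stimulus {i}: trace file {name} must have columns time_s,temp_C")
        try:
            traces.append(StimulusTrace(times=df["time_s"].to_numpy(),
                                        temperatures=df["temp_C"].to_numpy()))
        except ValueError as exc:
            raise RecordingLoadError(f"stimulus {i}: {exc}") from exc
    try:
        return Recording(traces=tuple(traces), latencies=latencies,
                         T0=float(manifest["T0_C"]),
                         neuron_id=str(manifest.get("neuron_id", "unknown")))
    except ValueError as exc:
        raise RecordingLoadError(str(exc)) from exc


def write_json(payload: dict, path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return str(obj)

    p.write_text(json.dumps(payload, indent=2, default=default))
    return p
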