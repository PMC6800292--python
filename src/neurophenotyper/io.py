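"""File formats: multi-page TIFF scenes with JSON sidecars, raw MEA traces
as binary float with a JSON header, spike-time and ROI-trace CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synth.calcium_gen import CalciumTraceSet
from .synth.electro import MEARecording
from .synth.scenes import ImageScene


# ---------------------------------------------------------------------------
# scenes


def write_scene(scene: ImageScene, path: str | Path, ground_truth_json: str | None = None):
    """One TIFF page per channel plus a JSON sidecar with the channel map."""
    path = Path(path)
    names = list(scene.channels)
    stack = np.stack([scene.channels[n] for n in names])
    tifffile.imwrite(path, stack.astype(np.float32))
    meta = {"channels": names, "pixel_size_um": scene.pixel_size_um}
    path.with_suffix(".json").write_text(json.dumps(meta))
    if ground_truth_json is not None:
        path.with_name(path.stem + "_truth.json").write_text(ground_truth_json)


def read_scene(path: str | Path) -> ImageScene:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    channels = {n: stack[i] for i, n in enumerate(meta["channels"])}
    return ImageScene(channels=channels, pixel_size_um=float(meta["pixel_size_um"]))


# ---------------------------------------------------------------------------
# MEA


def write_mea(recording: MEARecording, path: str | Path):
    """Raw float32 binary (electrodes x samples) with a JSON header."""
    path = Path(path)
    recording.voltage.astype(np.float32).tofile(path)
    header = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "electrode_ids": recording.electrode_ids,
        "well_map": recording.well_map,
        "n_electrodes": recording.n_electrodes,
        "n_samples": recording.voltage.shape[1],
        "dtype": "float32",
    }
    path.with_suffix(".json").write_text(json.dumps(header))


def read_mea(path: str | Path) -> MEARecording:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    voltage = np.fromfile(path, dtype=np.float32).reshape(
        header["n_electrodes"], header["n_samples"]
    )
    return MEARecording(
        voltage=voltage,
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        electrode_ids=list(header["electrode_ids"]),
        well_map=dict(header["well_map"]),
    )


def write_spike_times(spikes, path: str | Path):
    """Tidy CSV (time_s, electrode) usable to bypass raw detection."""
    rows = [
        {"time_s": t, "electrode": tr.electrode_id}
        for tr in spikes.trains
        for t in tr.times_s
    ]
    pd.DataFrame(rows, columns=["time_s", "electrode"]).to_csv(path, index=False)


def read_spike_times(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        e: np.sort(sub["time_s"].to_numpy(dtype=float))
        for e, sub in df.groupby("electrode")
    }


# ---------------------------------------------------------------------------
# calcium


def write_calcium_traces(traces: CalciumTraceSet, path: str | Path):
    """CSV with a frame column and one column per ROI; interval in a sidecar."""
    path = Path(path)
    df = pd.DataFrame(traces.raw, columns=traces.roi_ids)
    df.insert(0, "frame", np.arange(traces.n_frames))
    df.to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps({"frame_interval_s": traces.frame_interval_s})
    )


def read_calcium_traces(path: str | Path, frame_interval_s: float | None = None) -> CalciumTraceSet:
    path = Path(path)
    df = pd.read_csv(path)
    if frame_interval_s is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            frame_interval_s = json.loads(sidecar.read_text())["frame_interval_s"]
        else:
            raise ValueError("frame_interval_s not given and no sidecar found")
    rois = [c for c in df.columns if c != "frame"]
    return CalciumTraceSet(
        raw=df[rois].to_numpy(dtype=float),
        frame_interval_s=float(frame_interval_s),
        roi_ids=rois,
    )
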