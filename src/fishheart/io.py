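"""File IO for pipeline inputs and outputs.

Videos travel as one multi-page TIFF per plane plus a JSON sidecar carrying
pixel/time calibration (and, for synthetic data, the ground truth); traces
and tables are CSV with a single header line; results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .doppler import DopplerWaveform
from .myofibril import ForceTrace, ProtocolMarks
from .video import BiplaneVideo

__all__ = [
    "save_video",
    "load_video",
    "save_trace",
    "load_trace",
    "save_waveform",
    "load_waveform",
    "write_json",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2))


def save_video(video: BiplaneVideo, outdir: str | Path, truth: dict | None = None) -> dict:
    """Write the two plane stacks as TIFF plus a JSON sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long_path = outdir / "plane_long.tif"
    short_path = outdir / "plane_short.tif"
    meta_path = outdir / "meta.json"
    tifffile.imwrite(long_path, video.plane_long)
    tifffile.imwrite(short_path, video.plane_short)
    meta = {"pixel_size": video.pixel_size, "frame_rate": video.frame_rate}
    if truth is not None:
        meta["ground_truth"] = {k: v for k, v in truth.items() if k != "protocol"}
    write_json(meta, meta_path)
    return {"long": str(long_path), "short": str(short_path), "meta": str(meta_path)}


def load_video(long_tiff: str | Path, short_tiff: str | Path, meta_json: str | Path) -> BiplaneVideo:
    meta = json.loads(Path(meta_json).read_text())
    return BiplaneVideo(
        plane_long=tifffile.imread(long_tiff),
        plane_short=tifffile.imread(short_tiff),
        pixel_size=float(meta["pixel_size"]),
        frame_rate=float(meta["frame_rate"]),
    )


def save_trace(trace: ForceTrace, csv_path: str | Path, meta_path: str | Path) -> None:
    pd.DataFrame({"time": trace.time, "force": trace.force}).to_csv(csv_path, index=False)
    write_json(
        {
            "marks": {
                "activation": trace.marks.activation,
                "release": trace.marks.release,
                "restretch": trace.marks.restretch,
                "relaxation": trace.marks.relaxation,
            },
            "csa": trace.csa,
            "sarcomere_length": trace.sarcomere_length,
            "temperature": trace.temperature,
        },
        meta_path,
    )


def load_trace(csv_path: str | Path, meta_path: str | Path) -> ForceTrace:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(meta_path).read_text())
    m = meta["marks"]
    return ForceTrace(
        time=df["time"].to_numpy(),
        force=df["force"].to_numpy(),
        marks=ProtocolMarks(m["activation"], m["release"], m["restretch"], m["relaxation"]),
        csa=meta.get("csa"),
        sarcomere_length=meta.get("sarcomere_length", 2.3),
        temperature=meta.get("temperature", 10.0),
    )


def save_waveform(
    waveform: DopplerWaveform, csv_path: str | Path, events_path: str | Path | None = None
) -> None:
    pd.DataFrame({"time": waveform.time, "velocity": waveform.velocity}).to_csv(
        csv_path, index=False
    )
    if events_path is not None and waveform.events is not None:
        waveform.events.to_csv(events_path, index=False)


def load_waveform(csv_path: str | Path, events_path: str | Path | None = None) -> DopplerWaveform:
    df = pd.read_csv(csv_path)
    events = pd.read_csv(events_path) if events_path is not None else None
    return DopplerWaveform(
        time=df["time"].to_numpy(), velocity=df["velocity"].to_numpy(), events=events
    )
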