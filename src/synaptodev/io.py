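"""File I/O for the formats the pipeline exchanges.

Movies and multi-channel images travel as TIFF (via ``tifffile``), line ROIs
as JSON ``{"points": [[x, y], ...], "width_px": n}``, traces and tables as
headered CSV, and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calcium import LineROI
from .epsc import EPSCTrace
from .synthetic import GroundTruth

__all__ = [
    "save_movie",
    "load_movie",
    "save_channels",
    "load_channels",
    "save_roi",
    "load_roi",
    "save_trace",
    "load_trace",
    "save_truth",
]


def save_movie(path, movie: np.ndarray) -> None:
    """Write a (frames, H, W) stack as a multi-page float32 TIFF."""
    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.float32))


def load_movie(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr[None, ...] if arr.ndim == 2 else arr


def save_channels(path, channels: dict) -> None:
    """Write channels as one TIFF page each, channel names in a sidecar JSON."""
    names = sorted(channels)
    stack = np.stack([np.asarray(channels[n], dtype=np.float32) for n in names])
    tifffile.imwrite(str(path), stack)
    Path(str(path) + ".channels.json").write_text(json.dumps({"channels": names}))


def load_channels(path) -> dict:
    stack = tifffile.imread(str(path))
    names = json.loads(Path(str(path) + ".channels.json").read_text())["channels"]
    return {n: stack[i] for i, n in enumerate(names)}


def save_roi(path, roi: LineROI) -> None:
    Path(path).write_text(json.dumps({"points": roi.points, "width_px": roi.width_px}))


def load_roi(path) -> LineROI:
    d = json.loads(Path(path).read_text())
    return LineROI(points=[tuple(p) for p in d["points"]], width_px=int(d["width_px"]))


def save_trace(path, trace: EPSCTrace) -> None:
    pd.DataFrame({"time_ms": trace.time, "current_pA": trace.current}).to_csv(path, index=False)


def load_trace(path, stim_onset: float) -> EPSCTrace:
    df = pd.read_csv(path)
    return EPSCTrace(df["time_ms"].to_numpy(), df["current_pA"].to_numpy(), stim_onset)


def save_truth(path, truth: GroundTruth) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))
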