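"""File formats: multi-frame TIFF stacks with JSON metadata sidecars,
mask PNGs, trace CSVs, and feature-table CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .fluorsim import FrameStack
from .imaging import KineticTrace
from .phenoml import FeatureTable

__all__ = [
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_trace",
    "read_trace",
    "write_feature_table",
    "read_feature_table",
]


def write_stack(stack: FrameStack, path, dtype=np.uint16) -> None:
    """Write a frame stack as a multi-frame TIFF plus a ``.json`` sidecar
    holding times, light states, and metadata."""
    path = Path(path)
    frames = np.clip(np.round(stack.frames), 0, np.iinfo(dtype).max).astype(dtype)
    tifffile.imwrite(path, frames)
    sidecar = {
        "times_s": [float(t) for t in stack.times_s],
        "light_state": [str(s) for s in stack.light_state],
        "meta": _jsonable(stack.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_stack(path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FrameStack(
        frames=frames,
        times_s=np.asarray(sidecar["times_s"], dtype=float),
        light_state=np.asarray(sidecar["light_state"]),
        meta=sidecar.get("meta", {}),
    )


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def write_trace(trace: KineticTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times_s,
            "mean": trace.mean_counts,
            "sd": trace.sd_counts,
            "n": trace.n_pixels,
            "light_state": trace.light_state,
        }
    ).to_csv(path, index=False)


def read_trace(path) -> KineticTrace:
    df = pd.read_csv(path)
    return KineticTrace(
        times_s=df["time_s"].to_numpy(float),
        mean_counts=df["mean"].to_numpy(float),
        sd_counts=df["sd"].to_numpy(float),
        n_pixels=int(df["n"].iloc[0]),
        light_state=df["light_state"].to_numpy(str),
    )


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.features.copy()
    df["label"] = table.labels
    df.to_csv(path, index_label="sample_id")


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, index_col="sample_id")
    labels = df.pop("label")
    return FeatureTable(features=df, labels=labels)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
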