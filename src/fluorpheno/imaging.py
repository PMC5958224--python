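"""Background segmentation, ROI handling and kinetic-trace extraction.

Preprocessing turns a raw frame stack into a canopy ROI (one mask per pot)
and a mean kinetic trace; projected leaf area is the ROI pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .fluorsim import FrameStack
from .protocol import ProtocolDefinition

__all__ = [
    "SegmentationConfig",
    "KineticTrace",
    "segment_plant",
    "reference_frame",
    "extract_trace",
    "projected_leaf_area",
]


@dataclass
class SegmentationConfig:
    method: str = "otsu"            # or "fixed_threshold"
    threshold: float = 50.0         # used in fixed mode only
    min_object_px: int = 50
    reference: str = "Fm"           # which image to threshold: Fm or IrF

    def __post_init__(self):
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")
        if self.method == "fixed_threshold" and self.threshold <= 0:
            raise ValueError("fixed threshold must be > 0")
        if self.method not in ("otsu", "fixed_threshold"):
            raise ValueError(f"unknown segmentation method {self.method!r}")


@dataclass
class KineticTrace:
    """Canopy-mean fluorescence trace: one entry per frame."""

    times_s: np.ndarray
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    n_pixels: int
    light_state: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times_s)


def segment_plant(reference_image: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Threshold a reference image into a boolean plant mask.

    Otsu by default (parameter-free, deterministic); connected components
    smaller than ``min_object_px`` are dropped. Raises ``ValueError`` when
    nothing survives ("no plant detected").
    """
    cfg = cfg or SegmentationConfig()
    img = np.asarray(reference_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("reference image must be 2-D")
    if cfg.method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("no plant detected: reference image is constant")
        thr = threshold_otsu(img)
    else:
        thr = cfg.threshold
    mask = img > thr
    try:
        mask = remove_small_objects(mask, max_size=cfg.min_object_px - 1)
    except TypeError:  # scikit-image < 0.26 keyword
        mask = remove_small_objects(mask, min_size=cfg.min_object_px)
    if not mask.any():
        raise ValueError("no plant detected")
    return mask


def reference_frame(stack: FrameStack, p: ProtocolDefinition, which: str = "Fm") -> np.ndarray:
    """Pick the segmentation reference frame from a stack: the brightest
    frame inside the Fm flash window (highest plant/background contrast)."""
    if which != "Fm":
        raise ValueError("only the Fm reference is defined for kinetic stacks")
    ev = p.fm_flash
    in_win = (stack.times_s >= ev.time_s) & (stack.times_s < ev.end_s)
    if not in_win.any():
        raise ValueError("stack has no frames in the Fm flash window")
    sub = stack.frames[in_win]
    return sub[np.argmax(sub.mean(axis=(1, 2)))]


def extract_trace(stack: FrameStack, mask: np.ndarray) -> KineticTrace:
    """Per-frame mean and SD over the mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.frames.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match frames {stack.frames.shape[1:]}"
        )
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    vals = stack.frames[:, mask]
    return KineticTrace(
        times_s=stack.times_s.copy(),
        mean_counts=vals.mean(axis=1),
        sd_counts=vals.std(axis=1),
        n_pixels=n,
        light_state=stack.light_state.copy(),
        meta=dict(stack.meta),
    )


def projected_leaf_area(mask: np.ndarray, px_scale: float | None = None) -> dict:
    """Projected leaf area from the ROI pixel count.

    ``px_scale`` is mm^2 per pixel; when given, the area is also reported
    in mm^2.
    """
    mask = np.asarray(mask, dtype=bool)
    out = {"pixels": int(mask.sum())}
    if px_scale is not None:
        out["mm2"] = out["pixels"] * float(px_scale)
    return out
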