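"""Radiologist-facing QC renders: colored organ overlays on windowed CT slices.

Each slice is windowed with the standard CT display transform (default
abdominal window, center 40 / width 400 HU), organ masks are alpha-blended
on top (liver red, spleen blue by default), and the result is exported as a
DICOM Secondary Capture series in the same study, so the render appears next
to the source images in a PACS viewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dicom_io import SeriesStack, write_secondary_capture

__all__ = ["OverlayStyle", "window_slice", "blend_overlay", "render_qc_series"]

#: Organ painting precedence where masks overlap: later entries are painted
#: first, so earlier organs win.
ORGAN_ORDER = ("liver", "spleen", "visceral_fat", "subcutaneous_fat")

DEFAULT_PALETTE = {
    "liver": (255, 0, 0),
    "spleen": (0, 0, 255),
    "visceral_fat": (255, 255, 0),
    "subcutaneous_fat": (0, 255, 0),
}


@dataclass(frozen=True)
class OverlayStyle:
    palette: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    alpha: float = 0.4
    window_center: float = 40.0  # HU
    window_width: float = 400.0  # HU

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.window_width <= 0:
            raise ValueError("window width must be positive")


def window_slice(plane: np.ndarray, center: float, width: float) -> np.ndarray:
    """Linear map of [center - width/2, center + width/2] onto [0, 255], clipped."""
    if width <= 0:
        raise ValueError("window width must be positive")
    lo = center - width / 2.0
    scaled = (np.asarray(plane, dtype=np.float64) - lo) / width * 255.0
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def blend_overlay(
    gray: np.ndarray,
    masks: Mapping[str, np.ndarray],
    style: OverlayStyle,
) -> np.ndarray:
    """Alpha-blend organ masks onto an 8-bit grayscale plane.

    Out-of-mask pixels are the grayscale replicated across RGB; in-mask
    pixels are ``(1 - alpha) * gray + alpha * color`` per channel, rounded.
    Overlaps resolve by :data:`ORGAN_ORDER` precedence (liver wins).
    """
    gray = np.asarray(gray)
    out = np.repeat(gray[:, :, None], 3, axis=2).astype(np.float64)
    known = [o for o in ORGAN_ORDER if o in masks]
    extras = [o for o in masks if o not in ORGAN_ORDER]
    # paint lowest-precedence first so higher-precedence organs overwrite
    for organ in list(reversed(extras)) + list(reversed(known)):
        mask = np.asarray(masks[organ], dtype=bool)
        if mask.shape != gray.shape:
            raise ValueError(f"mask shape mismatch for {organ}")
        color = np.asarray(style.palette[organ], dtype=np.float64)
        blended = (1.0 - style.alpha) * gray[mask, None] + style.alpha * color
        out[mask] = blended
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_qc_series(
    stack: SeriesStack,
    masks: Mapping[str, np.ndarray],
    style: OverlayStyle,
    out_dir: str | Path,
    *,
    series_description: str = "AI QC: liver/spleen segmentation overlay",
) -> list[Path]:
    """Render one overlay SC instance per source slice and write the series."""
    for organ, mask in masks.items():
        if np.asarray(mask).shape != stack.voxels.shape:
            raise ValueError(f"mask {organ!r} is not aligned to the stack")
    planes = []
    for i in range(stack.n_slices):
        gray = window_slice(stack.voxels[i], style.window_center, style.window_width)
        slice_masks = {o: np.asarray(m)[i] for o, m in masks.items()}
        planes.append(blend_overlay(gray, slice_masks, style))
    return write_secondary_capture(
        stack,
        planes,
        stack.meta,
        out_dir,
        series_description=series_description,
    )
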