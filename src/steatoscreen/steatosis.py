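"""Hepatic steatosis screening on a non-contrast CT series stack.

The analysis stage obtains liver and spleen masks (from a pluggable
segmenter), computes the mean attenuation of each organ in Hounsfield units,
the spleen-hepatic attenuation difference

    SHAD = mean(spleen HU) - mean(liver HU),

the hepatic volume, and the radiologic determinant for moderate-to-severe
steatosis:

    steatosis present  <=>  liver mean < 40 HU  or  SHAD > 10 HU

(strict inequalities; the equivalent report form "liver - spleen < -10 HU"
is the same predicate with the sign flipped).  Fatty infiltration lowers
hepatic attenuation, so a liver that is dark in absolute terms or clearly
darker than the spleen flags positive.

Segmentation is a plug-in contract (SeriesStack -> (liver_mask, spleen_mask));
the production deep-learning model sits behind that seam and is not part of
this package.  The bundled fallback is a classical threshold +
connected-component labeller that is valid on phantom-grade data only and is
documented as NOT clinically usable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from scipy import ndimage

from .dicom_io import SeriesStack

__all__ = [
    "SteatosisConfig",
    "SteatosisResult",
    "SegmentationError",
    "fallback_segment",
    "masks_on_disk_segmenter",
    "mean_attenuation",
    "organ_volume",
    "compute_shad",
    "classify_steatosis",
    "analyze_stack",
    "analyze_masks",
]


class SegmentationError(RuntimeError):
    """The segmenter could not produce liver and spleen masks."""


class SegmentationPlugin(Protocol):
    def __call__(self, stack: SeriesStack) -> tuple[np.ndarray, np.ndarray]: ...


@dataclass(frozen=True)
class SteatosisConfig:
    liver_hu_threshold: float = 40.0  # HU, liver mean below this flags
    shad_threshold: float = 10.0  # HU, SHAD above this flags
    hu_rounding: int = 0  # decimals for report rendering

    def __post_init__(self) -> None:
        if not (np.isfinite(self.liver_hu_threshold) and np.isfinite(self.shad_threshold)):
            raise ValueError("thresholds must be finite")


@dataclass(frozen=True)
class SteatosisResult:
    """Full-precision organ statistics for one study (rounding happens at
    report rendering, never here)."""

    liver_mean_hu: float
    spleen_mean_hu: float
    shad: float
    liver_volume_ml: float
    steatosis_present: bool
    voxel_counts: dict[str, int]

    @property
    def liver_minus_spleen_hu(self) -> float:
        return -self.shad


# --- fallback segmentation ------------------------------------------------

SOFT_TISSUE_WINDOW = (-20.0, 200.0)  # HU


def fallback_segment(
    stack: SeriesStack,
    *,
    window: tuple[float, float] = SOFT_TISSUE_WINDOW,
    min_volume_ml: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Phantom-grade liver/spleen segmentation; NOT clinically valid.

    Thresholds the volume to a soft-tissue HU window, labels 3-D connected
    components, discards components smaller than ``min_volume_ml``, and
    applies a size heuristic: the largest component is called liver, the
    largest remaining one spleen.  On anatomy where the spleen outgrows the
    liver the labels follow the size rule and are wrong — the plug-in seam
    exists precisely so a real model can replace this.
    """
    lo, hi = window
    tissue = (stack.voxels >= lo) & (stack.voxels <= hi)
    labels, n = ndimage.label(tissue)
    if n < 2:
        raise SegmentationError(
            f"expected >= 2 soft-tissue components, found {n}"
        )
    counts = np.bincount(labels.ravel())[1:]  # skip background label 0
    min_voxels = min_volume_ml * 1000.0 / stack.voxel_volume_mm3
    qualifying = [(int(c), i + 1) for i, c in enumerate(counts) if c >= min_voxels]
    if len(qualifying) < 2:
        raise SegmentationError(
            f"only {len(qualifying)} components above {min_volume_ml} mL"
        )
    qualifying.sort(reverse=True)
    liver_label = qualifying[0][1]
    spleen_label = qualifying[1][1]
    return labels == liver_label, labels == spleen_label


def masks_on_disk_segmenter(mask_path) -> SegmentationPlugin:
    """Segmenter that loads externally supplied co-registered label volumes.

    ``mask_path`` is an ``.npz`` with boolean ``liver_mask`` / ``spleen_mask``
    arrays aligned to the series stack (the format the phantom generator's
    truth files use).
    """

    def _segment(stack: SeriesStack) -> tuple[np.ndarray, np.ndarray]:
        with np.load(mask_path) as data:
            liver = data["liver_mask"].astype(bool)
            spleen = data["spleen_mask"].astype(bool)
        if liver.shape != stack.voxels.shape or spleen.shape != stack.voxels.shape:
            raise SegmentationError("mask shape does not match series stack")
        return liver, spleen

    return _segment


def _check_masks(stack: SeriesStack, liver: np.ndarray, spleen: np.ndarray) -> None:
    if liver.shape != stack.voxels.shape or spleen.shape != stack.voxels.shape:
        raise SegmentationError("mask shape does not match series stack")
    if np.any(liver & spleen):
        raise SegmentationError("liver and spleen masks overlap")


# --- statistics -----------------------------------------------------------


def mean_attenuation(stack: SeriesStack, mask: np.ndarray) -> float:
    """Unweighted arithmetic mean HU over in-mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.voxels.shape:
        raise ValueError("mask shape does not match stack")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(stack.voxels[mask].mean())


def organ_volume(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Mask volume in mL: voxel count x voxel volume (mm^3) / 1000."""
    if min(spacing) <= 0:
        raise ValueError("spacing must be positive")
    return int(np.asarray(mask, dtype=bool).sum()) * float(np.prod(spacing)) / 1000.0


def compute_shad(liver_mean: float, spleen_mean: float) -> float:
    """Spleen-hepatic attenuation difference: spleen mean minus liver mean."""
    return spleen_mean - liver_mean


def classify_steatosis(
    liver_mean: float, shad: float, config: SteatosisConfig = SteatosisConfig()
) -> bool:
    """Moderate-to-severe steatosis determinant (strict inequalities)."""
    if not (np.isfinite(liver_mean) and np.isfinite(shad)):
        raise ValueError("inputs must be finite")
    return liver_mean < config.liver_hu_threshold or shad > config.shad_threshold


def analyze_stack(
    stack: SeriesStack,
    segmenter: SegmentationPlugin = fallback_segment,
    config: SteatosisConfig = SteatosisConfig(),
) -> SteatosisResult:
    """Run the full analysis stage on one routed series stack."""
    liver_mask, spleen_mask = segmenter(stack)
    return analyze_masks(stack, liver_mask, spleen_mask, config)


def analyze_masks(
    stack: SeriesStack,
    liver_mask: np.ndarray,
    spleen_mask: np.ndarray,
    config: SteatosisConfig = SteatosisConfig(),
) -> SteatosisResult:
    """Compute the steatosis statistics from already-obtained organ masks."""
    _check_masks(stack, liver_mask, spleen_mask)
    liver_mean = mean_attenuation(stack, liver_mask)
    spleen_mean = mean_attenuation(stack, spleen_mask)
    shad = compute_shad(liver_mean, spleen_mean)
    return SteatosisResult(
        liver_mean_hu=liver_mean,
        spleen_mean_hu=spleen_mean,
        shad=shad,
        liver_volume_ml=organ_volume(liver_mask, stack.spacing),
        steatosis_present=classify_steatosis(liver_mean, shad, config),
        voxel_counts={
            "liver": int(liver_mask.sum()),
            "spleen": int(spleen_mask.sum()),
        },
    )
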