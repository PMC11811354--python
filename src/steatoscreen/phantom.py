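"""Synthetic abdominal-CT phantom studies with known ground truth.

Each phantom is a small 3-D HU volume containing an ellipsoidal "liver" and
"spleen" embedded in an elliptical body outline, written as a
standards-compliant single-frame CT DICOM study.  Organ attenuations, noise,
geometry (slice thickness schedule, orientation), the procedure code and the
contrast-agent tag are all configurable, so every routing outcome and every
analysis quantity can be exercised with exact ground truth and no data
download.

Composition of a slice, outside-in: air (-1000 HU) beyond the body ellipse, a
subcutaneous fat ring (``fat_hu``), a visceral-fat-like interior
(``background_hu``), and the two organ ellipsoids drawn at their configured
mean HU plus Gaussian noise.  The interior is deliberately fat-like (below
the soft-tissue window) so that the liver and spleen are the only soft-tissue
connected components — the property the classical fallback segmenter relies
on.  HU values are quantized to integers before writing (stored as unsigned
with slope 1 / intercept -1024), which makes fixtures bit-stable across
platforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dicom_io import new_uid, write_ct_instance

__all__ = [
    "Ellipsoid",
    "PhantomConfig",
    "PhantomTruth",
    "SCENARIOS",
    "generate_volume",
    "generate_phantom",
    "make_scenario",
]

AIR_HU = -1000.0
HU_MIN, HU_MAX = -1024, 3071  # 12-bit CT range

AXIAL = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)
CORONAL = (1.0, 0.0, 0.0, 0.0, 0.0, -1.0)

CPT_ABDOMEN_PELVIS_NC = "74176"
CPT_CHEST_NC = "71250"


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel units: center and semi-axes (z, y, x)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        cz, cy, cx = self.center
        az, ay, ax = self.semi_axes
        return (
            ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        ) <= 1.0


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic phantom.

    Defaults model a uniform-thickness axial non-contrast abdominal CT with
    mildly steatotic liver attenuation; per-organ HU and the noise level are
    the knobs the analysis-stage tests turn.
    """

    grid: tuple[int, int, int] = (10, 64, 64)  # (n_slices, rows, cols)
    spacing: tuple[float, float, float] = (3.0, 5.0, 5.0)  # mm (slice, row, col)
    liver_mean_hu: float = 30.0
    spleen_mean_hu: float = 49.0
    background_hu: float = -75.0  # visceral-fat-like interior
    fat_hu: float = -100.0  # subcutaneous fat ring
    noise_sd: float = 0.0
    liver_ellipsoid: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((4.5, 32.0, 22.0), (4.0, 17.0, 13.0))
    )
    spleen_ellipsoid: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((4.5, 30.0, 50.0), (3.0, 9.0, 8.0))
    )
    body_semi_axes: tuple[float, float] = (28.0, 30.0)  # (rows, cols)
    fat_ring_fraction: float = 0.88  # inner ellipse scale; ring lies outside it
    procedure_code: str | None = CPT_ABDOMEN_PELVIS_NC
    contrast_agent: str | None = None
    slice_thickness_schedule: list[float] | None = None  # default: uniform 3 mm
    orientation: tuple[float, ...] = AXIAL
    seed: int = 0

    def thicknesses(self) -> list[float]:
        if self.slice_thickness_schedule is not None:
            sched = list(self.slice_thickness_schedule)
            if len(sched) != self.grid[0]:
                raise ValueError("slice_thickness_schedule length != n_slices")
            return sched
        return [self.spacing[0]] * self.grid[0]

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        liver = self.liver_ellipsoid.mask(self.grid)
        spleen = self.spleen_ellipsoid.mask(self.grid)
        if np.any(liver & spleen):
            raise ValueError("liver and spleen ellipsoids overlap")
        for name, e in (("liver", self.liver_ellipsoid), ("spleen", self.spleen_ellipsoid)):
            lo = np.asarray(e.center) - np.asarray(e.semi_axes)
            hi = np.asarray(e.center) + np.asarray(e.semi_axes)
            if np.any(lo < 0) or np.any(hi > np.asarray(self.grid)):
                raise ValueError(f"{name} ellipsoid extends outside the grid")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    liver_mask: np.ndarray
    spleen_mask: np.ndarray
    liver_volume_ml: float
    spleen_volume_ml: float
    true_means: dict[str, float]
    study_uid: str = ""
    series_uid: str = ""


def _body_masks(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """(body, inner) 2-D ellipse masks; the fat ring is body & ~inner."""
    _, rows, cols = config.grid
    yy, xx = np.ogrid[:rows, :cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ay, ax = config.body_semi_axes
    body = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    f = config.fat_ring_fraction
    inner = ((yy - cy) / (ay * f)) ** 2 + ((xx - cx) / (ax * f)) ** 2 <= 1.0
    return body, inner


def generate_volume(config: PhantomConfig) -> tuple[np.ndarray, PhantomTruth]:
    """Build the integer-quantized HU volume and its ground truth in memory.

    Deterministic given ``config.seed``.  Noise is drawn per voxel and the
    result rounded to integer HU, so a zero-noise phantom contains the
    configured organ means exactly.
    """
    config.validate()
    n_slices, rows, cols = config.grid
    body2d, inner2d = _body_masks(config)

    vol = np.full(config.grid, AIR_HU, dtype=np.float64)
    vol[:, body2d & ~inner2d] = config.fat_hu
    vol[:, inner2d] = config.background_hu

    liver = config.liver_ellipsoid.mask(config.grid)
    spleen = config.spleen_ellipsoid.mask(config.grid)
    vol[liver] = config.liver_mean_hu
    vol[spleen] = config.spleen_mean_hu

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        body3d = np.broadcast_to(body2d, config.grid)
        noise = rng.normal(0.0, config.noise_sd, size=config.grid)
        vol = np.where(body3d, vol + noise, vol)

    vol = np.clip(np.rint(vol), HU_MIN, HU_MAX)

    voxel_ml = float(np.prod(config.spacing)) / 1000.0
    truth = PhantomTruth(
        liver_mask=liver,
        spleen_mask=spleen,
        liver_volume_ml=int(liver.sum()) * voxel_ml,
        spleen_volume_ml=int(spleen.sum()) * voxel_ml,
        true_means={"liver": config.liver_mean_hu, "spleen": config.spleen_mean_hu},
    )
    return vol, truth


def generate_phantom(
    config: PhantomConfig,
    out_dir: str | Path,
    *,
    write_truth: bool = True,
) -> tuple[Path, PhantomTruth]:
    """Write a phantom study as DICOM slices under ``out_dir/<study_uid>/``.

    Returns the study directory and the ground truth.  UIDs are deterministic
    in the seed, so the same config writes byte-identical pixel data (and the
    same file names) every time.  Truth masks go next to the study as a
    compressed array file plus a JSON manifest.
    """
    vol, truth = generate_volume(config)
    out_dir = Path(out_dir)

    study_uid = new_uid(["study", config.seed, config.procedure_code or ""])
    series_uid = new_uid(["series", config.seed, "primary"])
    truth.study_uid = study_uid
    truth.series_uid = series_uid
    study_dir = out_dir / study_uid
    study_dir.mkdir(parents=True, exist_ok=True)

    stored = (vol + 1024.0).astype(np.uint16)
    thicknesses = config.thicknesses()
    orientation = np.asarray(config.orientation, dtype=float)
    normal = np.cross(orientation[:3], orientation[3:])
    for i in range(config.grid[0]):
        sop_uid = new_uid(["sop", config.seed, i])
        position = normal * (i * config.spacing[0])
        write_ct_instance(
            study_dir / f"{sop_uid}.dcm",
            study_uid=study_uid,
            series_uid=series_uid,
            sop_uid=sop_uid,
            instance_number=i + 1,
            stored_plane=stored[i],
            image_position=position,
            image_orientation=orientation,
            pixel_spacing=config.spacing[1:],
            slice_thickness=thicknesses[i],
            procedure_code=config.procedure_code,
            contrast_agent=config.contrast_agent,
            series_description="synthetic abdominal phantom",
        )

    if write_truth:
        truth_dir = out_dir / f"{study_uid}.truth"
        truth_dir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            truth_dir / "masks.npz",
            liver_mask=truth.liver_mask,
            spleen_mask=truth.spleen_mask,
        )
        manifest = {
            "study_uid": study_uid,
            "series_uid": series_uid,
            "liver_volume_ml": truth.liver_volume_ml,
            "spleen_volume_ml": truth.spleen_volume_ml,
            "true_means": truth.true_means,
            "config": _config_to_json(config),
        }
        (truth_dir / "truth.json").write_text(json.dumps(manifest, indent=2))

    return study_dir, truth


def _config_to_json(config: PhantomConfig) -> dict:
    d = dataclasses.asdict(config)
    d["liver_ellipsoid"] = dataclasses.asdict(config.liver_ellipsoid)
    d["spleen_ellipsoid"] = dataclasses.asdict(config.spleen_ellipsoid)
    return d


#: Scenario ids exercising each routing outcome.
SCENARIOS = (
    "steatotic",
    "normal",
    "nonuniform_thickness",
    "contrast_tagged",
    "wrong_cpt",
    "nonaxial",
)


def make_scenario(name: str, *, seed: int = 0, noise_sd: float = 0.0) -> PhantomConfig:
    """Return a config that triggers exactly the named routing outcome.

    ``steatotic`` and ``normal`` are fully eligible studies that differ only
    in liver attenuation (steatosis present vs. absent); the remaining four
    each violate exactly one eligibility rule.
    """
    base = PhantomConfig(seed=seed, noise_sd=noise_sd)
    if name == "steatotic":
        return base  # liver 30 / spleen 49, CPT 74176, no contrast
    if name == "normal":
        return dataclasses.replace(base, liver_mean_hu=55.0, spleen_mean_hu=50.0)
    if name == "nonuniform_thickness":
        sched = [3.0] * base.grid[0]
        sched[-1] = 5.0
        return dataclasses.replace(base, slice_thickness_schedule=sched)
    if name == "contrast_tagged":
        return dataclasses.replace(base, contrast_agent="IOHEXOL")
    if name == "wrong_cpt":
        return dataclasses.replace(base, procedure_code=CPT_CHEST_NC)
    if name == "nonaxial":
        return dataclasses.replace(base, orientation=CORONAL)
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
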