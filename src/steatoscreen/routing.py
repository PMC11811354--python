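"""Eligibility routing: which studies run the steatosis algorithm, on which series.

The gate mirrors a production orchestrator's checks for a non-contrast
abdominal CT screening application:

1. the study's procedure (CPT) code marks it as a non-contrast abdominal
   exam (codes compared after stripping thousands separators, so "74,176"
   and "74176" are the same code);
2. no instance carries a contrast-agent tag;
3. the series is axial within tolerance, has a uniform slice-thickness tag,
   and that thickness lies inside the configured range.

Among series passing all checks, the one with the largest slice thickness is
selected (fewest slices, least compute); ties break by lowest instance
number then lexicographic series UID.  The decision is a pure function of
its inputs and records machine-readable reasons for every rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dicom_io import InstanceMeta, SeriesStack

__all__ = [
    "RoutingConfig",
    "RoutingDecision",
    "RejectionReason",
    "study_eligible",
    "verify_non_contrast",
    "series_technical_check",
    "select_series",
]


class RejectionReason:
    WRONG_CPT = "WRONG_CPT"
    CONTRAST_PRESENT = "CONTRAST_PRESENT"
    NO_AXIAL_SERIES = "NO_AXIAL_SERIES"
    THICKNESS_OUT_OF_RANGE = "THICKNESS_OUT_OF_RANGE"
    NONUNIFORM_THICKNESS = "NONUNIFORM_THICKNESS"
    NO_SERIES = "NO_SERIES"


@dataclass(frozen=True)
class RoutingConfig:
    eligible_cpt_codes: frozenset[str] = frozenset({"74176", "74150"})
    min_thickness: float = 1.0  # mm, inclusive
    max_thickness: float = 5.0  # mm, inclusive
    require_uniform_thickness: bool = True
    require_axial: bool = True
    axial_tolerance: float = 0.01  # |normal_z| >= 1 - tolerance

    def __post_init__(self) -> None:
        if not self.min_thickness < self.max_thickness:
            raise ValueError("min_thickness must be < max_thickness")
        if not 0.0 < self.axial_tolerance < 0.5:
            raise ValueError("axial_tolerance must lie in (0, 0.5)")


@dataclass(frozen=True)
class RoutingDecision:
    """Verdict for one study.  eligible <=> a series was selected <=> no reasons."""

    study_uid: str
    eligible: bool
    selected_series_uid: str | None
    reasons: tuple[str, ...] = ()
    #: per-series rejection detail, kept for the funnel even when the study
    #: is eligible via another series (the invariant constrains `reasons` only)
    series_reasons: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self) -> None:
        ok = self.eligible == (self.selected_series_uid is not None) == (
            len(self.reasons) == 0
        )
        if not ok:
            raise ValueError("inconsistent RoutingDecision")


def normalize_cpt(code: str) -> str:
    """Strip thousands separators and whitespace: '74,176' -> '74176'."""
    return code.replace(",", "").replace(" ", "")


def study_eligible(
    study_meta: InstanceMeta, config: RoutingConfig
) -> tuple[bool, str | None]:
    """CPT-code gate.  Absent or unlisted codes fail with WRONG_CPT."""
    code = study_meta.procedure_code
    if code is None:
        return False, RejectionReason.WRONG_CPT
    normalized = {normalize_cpt(c) for c in config.eligible_cpt_codes}
    if normalize_cpt(code) in normalized:
        return True, None
    return False, RejectionReason.WRONG_CPT


def verify_non_contrast(stack: SeriesStack) -> bool:
    """Pass iff the contrast-agent tag is absent/empty on every instance."""
    return all(m.contrast_agent in (None, "") for m in stack.meta)


def series_technical_check(
    stack: SeriesStack, config: RoutingConfig
) -> tuple[bool, list[str]]:
    """Axiality, thickness uniformity and thickness range, in that order."""
    reasons: list[str] = []
    if config.require_axial:
        nz = abs(float(stack.normal[2]))
        if nz < 1.0 - config.axial_tolerance:
            reasons.append(RejectionReason.NO_AXIAL_SERIES)
    thicknesses = stack.slice_thickness_set
    if config.require_uniform_thickness and len(thicknesses) != 1:
        reasons.append(RejectionReason.NONUNIFORM_THICKNESS)
    elif len(thicknesses) >= 1:
        t = max(thicknesses)
        if not config.min_thickness <= t <= config.max_thickness:
            reasons.append(RejectionReason.THICKNESS_OUT_OF_RANGE)
    return (len(reasons) == 0), reasons


def select_series(
    candidates: Sequence[SeriesStack], config: RoutingConfig
) -> RoutingDecision:
    """Route one study given all its assembled series.

    Series-level checks (contrast tag, axiality, thickness) run on each
    candidate; the CPT gate uses the metadata of the first instance seen.
    Rejection reasons from every failing series are aggregated in order,
    de-duplicated.
    """
    if len(candidates) == 0:
        return RoutingDecision("", False, None, (RejectionReason.NO_SERIES,))

    study_uids = {s.study_uid for s in candidates}
    if len(study_uids) != 1:
        raise ValueError(f"candidates span multiple studies: {sorted(study_uids)}")
    study_uid = candidates[0].study_uid

    reasons: list[str] = []

    ok_cpt, cpt_reason = study_eligible(candidates[0].meta[0], config)
    if not ok_cpt:
        reasons.append(cpt_reason)

    passing: list[SeriesStack] = []
    per_series: list[tuple[str, tuple[str, ...]]] = []
    for stack in sorted(candidates, key=lambda s: s.series_uid):
        series_reasons: list[str] = []
        if not verify_non_contrast(stack):
            series_reasons.append(RejectionReason.CONTRAST_PRESENT)
        ok_tech, tech_reasons = series_technical_check(stack, config)
        series_reasons.extend(tech_reasons)
        if series_reasons:
            reasons.extend(series_reasons)
            per_series.append((stack.series_uid, tuple(series_reasons)))
        elif ok_cpt:
            passing.append(stack)

    if not ok_cpt or not passing:
        deduped = tuple(dict.fromkeys(reasons)) or (RejectionReason.NO_SERIES,)
        return RoutingDecision(study_uid, False, None, deduped, tuple(per_series))

    # Thickest passing series wins (fewest slices -> least compute); ties by
    # lowest instance number, then lexicographic series UID.
    def key(stack: SeriesStack):
        thickness = max(stack.slice_thickness_set)
        first_instance = min(m.instance_number for m in stack.meta)
        return (-thickness, first_instance, stack.series_uid)

    winner = min(passing, key=key)
    return RoutingDecision(study_uid, True, winner.series_uid, (), tuple(per_series))
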