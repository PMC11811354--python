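"""Common-data-element packaging, report-template filling, and DICOM-SR export.

Measurements leave the analysis stage as registry-coded common data elements
(CDEs) so the reporting engine can populate the radiologist's template
automatically:

=============  =============================  ==========
code           meaning                        units
=============  =============================  ==========
RDE1194        liver mean attenuation         HU
RDE1207        spleen mean attenuation        HU
RDE1193        liver minus spleen mean        HU
LIVF1          hepatic steatosis flag         (present/absent)
LOCAL-LIVVOL   hepatic volume (local code)    mL
=============  =============================  ==========

RDE codes are RadElement registry identifiers; LOCAL- codes are local
extensions for values without a printed registry code.

Rounding policy: HU values are rounded to integers (half away from zero) for
display, and the printed liver-minus-spleen difference is recomputed from the
*rounded* liver and spleen values so the report is arithmetically
self-consistent; unrounded values are retained in the database record.

The structured report is a plain measurement-report SR built on pydicom: a
root CONTAINER, one NUM content item per numeric CDE (value + UCUM units) and
one CODE item for the flag, referencing the source study and sharing its
study UID.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ComprehensiveSRStorage, ExplicitVRLittleEndian

from .dicom_io import InstanceMeta, new_uid
from .steatosis import SteatosisResult

__all__ = [
    "CDE",
    "CDESet",
    "DEFAULT_TEMPLATE",
    "ReportError",
    "round_half_away",
    "build_cde_set",
    "render_report",
    "build_sr",
    "read_sr",
]

LIVER_MEAN_CODE = "RDE1194"
SPLEEN_MEAN_CODE = "RDE1207"
LIVER_MINUS_SPLEEN_CODE = "RDE1193"
STEATOSIS_FLAG_CODE = "LIVF1"
LIVER_VOLUME_CODE = "LOCAL-LIVVOL"

HU_UNITS = "HU"
ML_UNITS = "mL"


class ReportError(ValueError):
    """Template rendering or CDE packaging failed."""


@dataclass(frozen=True)
class CDE:
    code: str
    meaning: str
    value: float | bool
    units: str = ""

    def __post_init__(self) -> None:
        if not self.code:
            raise ReportError("CDE code must be nonempty")
        if isinstance(self.value, (int, float)) and not isinstance(self.value, bool):
            if not math.isfinite(self.value):
                raise ReportError(f"non-finite value for {self.code}")
            if not self.units:
                raise ReportError(f"numeric CDE {self.code} must carry units")


class CDESet(dict):
    """Mapping code -> CDE for one study."""

    def add(self, cde: CDE) -> None:
        self[cde.code] = cde

    def value(self, code: str):
        return self[code].value


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def build_cde_set(result: SteatosisResult, rounding: int = 0) -> CDESet:
    """Package a steatosis result as display-ready CDEs.

    The liver-minus-spleen element is the difference of the *rounded* liver
    and spleen values, keeping the printed arithmetic exact.
    """
    for name, v in (
        ("liver mean", result.liver_mean_hu),
        ("spleen mean", result.spleen_mean_hu),
        ("liver volume", result.liver_volume_ml),
    ):
        if not math.isfinite(v):
            raise ReportError(f"non-finite {name}")
    liver = round_half_away(result.liver_mean_hu, rounding)
    spleen = round_half_away(result.spleen_mean_hu, rounding)
    cdes = CDESet()
    cdes.add(CDE(LIVER_MEAN_CODE, "Liver mean attenuation", liver, HU_UNITS))
    cdes.add(CDE(SPLEEN_MEAN_CODE, "Spleen mean attenuation", spleen, HU_UNITS))
    cdes.add(
        CDE(
            LIVER_MINUS_SPLEEN_CODE,
            "Liver minus spleen mean attenuation",
            liver - spleen,
            HU_UNITS,
        )
    )
    cdes.add(CDE(STEATOSIS_FLAG_CODE, "Hepatic steatosis", result.steatosis_present))
    cdes.add(
        CDE(
            LIVER_VOLUME_CODE,
            "Hepatic volume",
            round_half_away(result.liver_volume_ml, rounding),
            ML_UNITS,
        )
    )
    return cdes


#: Report-template section with bracket placeholders resolved from a CDESet.
DEFAULT_TEMPLATE = """\
ATTENUATION MEASUREMENTS:
Liver ([RDE1194] HU) - Spleen ([RDE1207] HU) = [RDE1193] HU
Hepatic steatosis: [yes/no]
Threshold: liver < 40 HU or Liver-Spleen < -10 HU
(Hamer O, et al. RadioGraphics 2006)
"""

FLAG_PLACEHOLDER = "[yes/no]"


def _format_number(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def render_report(template: str, cdes: CDESet) -> str:
    """Fill a bracket-placeholder template; byte-deterministic.

    Numeric placeholders look like ``[RDE1194]`` (or ``[LOCAL-...]``); the
    steatosis flag placeholder is ``[yes/no]`` and renders as
    ``present``/``absent``.  Unresolvable placeholders raise
    :class:`ReportError` naming every missing code.
    """
    text = template
    if FLAG_PLACEHOLDER in text:
        if STEATOSIS_FLAG_CODE not in cdes:
            raise ReportError(f"missing codes: {STEATOSIS_FLAG_CODE}")
        flag = "present" if cdes.value(STEATOSIS_FLAG_CODE) else "absent"
        text = text.replace(FLAG_PLACEHOLDER, flag)
    for code, cde in cdes.items():
        placeholder = f"[{code}]"
        if placeholder in text:
            value = cde.value
            rendered = (
                ("present" if value else "absent")
                if isinstance(value, bool)
                else _format_number(value)
            )
            text = text.replace(placeholder, rendered)
    missing = sorted(set(re.findall(r"\[(RDE\d+|LOCAL-[A-Z0-9]+|LIVF\d+)\]", text)))
    if missing:
        raise ReportError(f"missing codes: {', '.join(missing)}")
    return text


# --- DICOM-SR -------------------------------------------------------------

_CODING_SCHEME = "RADELEMENT"  # registry codes; LOCAL- codes use 99LOCAL
_UCUM = {"HU": "[hnsf'U]", "mL": "mL"}


def _code_item(value: str, meaning: str, scheme: str | None = None) -> Dataset:
    item = Dataset()
    item.CodeValue = value
    item.CodingSchemeDesignator = scheme or (
        "99LOCAL" if value.startswith("LOCAL-") or value.startswith("LIVF") else _CODING_SCHEME
    )
    item.CodeMeaning = meaning
    return item


def build_sr(
    cdes: CDESet,
    study_refs: list[InstanceMeta],
    out_path: str | Path,
) -> Path:
    """Write a measurement-report DICOM-SR for one study.

    One NUM item per numeric CDE (value plus UCUM-coded units), one CODE
    item for each flag CDE; the SR shares the source study UID and lists the
    referenced source instances as evidence.
    """
    if not cdes:
        raise ReportError("empty CDESet")
    if not study_refs:
        raise ReportError("study_refs must not be empty")
    out_path = Path(out_path)
    study_uid = study_refs[0].study_uid
    sop_uid = new_uid()

    ds = Dataset()
    ds.SOPClassUID = ComprehensiveSRStorage
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = new_uid()
    ds.Modality = "SR"
    ds.SeriesDescription = "AI hepatic steatosis measurements"
    ds.InstanceNumber = 1
    ds.ValueType = "CONTAINER"
    ds.ContinuityOfContent = "SEPARATE"
    ds.ConceptNameCodeSequence = [_code_item("126000", "Imaging Measurement Report", "DCM")]
    ds.CompletionFlag = "COMPLETE"
    ds.VerificationFlag = "UNVERIFIED"

    content = []
    for code, cde in sorted(cdes.items()):
        if isinstance(cde.value, bool):
            item = Dataset()
            item.RelationshipType = "CONTAINS"
            item.ValueType = "CODE"
            item.ConceptNameCodeSequence = [_code_item(code, cde.meaning)]
            item.ConceptCodeSequence = [
                _code_item(
                    "present" if cde.value else "absent",
                    "present" if cde.value else "absent",
                    "99LOCAL",
                )
            ]
            content.append(item)
        else:
            item = Dataset()
            item.RelationshipType = "CONTAINS"
            item.ValueType = "NUM"
            item.ConceptNameCodeSequence = [_code_item(code, cde.meaning)]
            mv = Dataset()
            mv.NumericValue = f"{float(cde.value):.8g}"  # DS VR: <= 16 bytes
            mv.MeasurementUnitsCodeSequence = [
                _code_item(_UCUM.get(cde.units, cde.units), cde.units, "UCUM")
            ]
            item.MeasuredValueSequence = [mv]
            content.append(item)
    ds.ContentSequence = content

    # evidence: which source instances the measurements came from
    ref_sops = []
    for m in study_refs:
        r = Dataset()
        r.ReferencedSOPClassUID = "1.2.840.10008.5.1.4.1.1.2"  # CT Image Storage
        r.ReferencedSOPInstanceUID = m.sop_uid
        ref_sops.append(r)
    series_item = Dataset()
    series_item.SeriesInstanceUID = study_refs[0].series_uid
    series_item.ReferencedSOPSequence = ref_sops
    study_item = Dataset()
    study_item.StudyInstanceUID = study_uid
    study_item.ReferencedSeriesSequence = [series_item]
    ds.CurrentRequestedProcedureEvidenceSequence = [study_item]

    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = ComprehensiveSRStorage
    fm.MediaStorageSOPInstanceUID = sop_uid
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = fm
    out_path.parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(out_path, enforce_file_format=True)
    return out_path


def read_sr(path: str | Path) -> CDESet:
    """Re-extract the CDESet from an SR written by :func:`build_sr`."""
    import pydicom

    ds = pydicom.dcmread(path)
    cdes = CDESet()
    inverse_ucum = {v: k for k, v in _UCUM.items()}
    for item in ds.ContentSequence:
        name = item.ConceptNameCodeSequence[0]
        code = str(name.CodeValue)
        meaning = str(name.CodeMeaning)
        if item.ValueType == "NUM":
            mv = item.MeasuredValueSequence[0]
            units_code = str(mv.MeasurementUnitsCodeSequence[0].CodeValue)
            cdes.add(
                CDE(
                    code,
                    meaning,
                    float(mv.NumericValue),
                    inverse_ucum.get(units_code, units_code),
                )
            )
        elif item.ValueType == "CODE":
            flag = str(item.ConceptCodeSequence[0].CodeValue) == "present"
            cdes.add(CDE(code, meaning, flag))
    return cdes
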