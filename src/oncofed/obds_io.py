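"""Reading, writing, validating and decomposing oBDS-style XML exports.

The oncological basic dataset (oBDS) is the standardized dataset German
hospitals use to report cancer cases to the state cancer registries.  Tumor
documentation systems export *collections* of reports as XML; downstream
stages of this pipeline operate on decomposed *single reports*.  This module
implements a minimal XML dialect carrying exactly the data elements the
analysis consumes — patient identifier, administrative gender, ICD-10
diagnosis code, diagnosis date — plus the schema version used for the
pipeline's version gate.

Dialect::

    <oBDSCollection obds_version="2.2.2" site_id="site1">
      <Report id="R000001">
        <PatientID>P000001</PatientID>
        <Gender>W</Gender>
        <QuasiIdentifier>QI-site1-000001</QuasiIdentifier>  <!-- optional -->
        <Diagnosis icd10="C50.1" icd10_version="10-GM-2022" date="2022-03-01"/>
      </Report>
      ...
    </oBDSCollection>

A single report uses root ``<oBDSReport obds_version=".." site_id=".."
id="..">`` with identical children.  Reports that violate an invariant are
rejected individually (with a machine-readable code) rather than failing the
whole file; the full oBDS schema (therapy, TNM, histology) is out of scope.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass
from pathlib import Path

from lxml import etree

log = logging.getLogger(__name__)

#: Administrative gender codes used by oBDS: male, female, diverse, unknown.
GENDER_CODES: tuple[str, ...] = ("M", "W", "D", "U")

ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$")

#: Schema versions the pipeline accepts by default.
DEFAULT_SUPPORTED_VERSIONS = frozenset({"2.2.2"})

COLLECTION_ROOT = "oBDSCollection"
SINGLE_REPORT_ROOT = "oBDSReport"


class OBDSError(ValueError):
    """Base class for oBDS I/O errors."""


class OBDSParseError(OBDSError):
    """Malformed XML; the message names the offending line when known."""


class OBDSDialectError(OBDSError):
    """Well-formed XML that is not in the expected oBDS dialect."""


@dataclass(frozen=True)
class OBDSReport:
    """One cancer-case report.

    One report corresponds to one cancer case; multiple reports may share a
    ``patient_id`` but are counted as distinct cases throughout the pipeline.
    """

    report_id: str
    site_id: str
    patient_id: str
    gender: str
    icd10_code: str
    icd10_version: str
    diagnosis_date: dt.date
    obds_version: str
    quasi_identifier: str | None = None

    def invariant_errors(self, reference_date: dt.date | None = None) -> list[tuple[str, str]]:
        """Return ``(code, message)`` pairs for every violated invariant."""
        errors: list[tuple[str, str]] = []
        if not self.report_id:
            errors.append(("EMPTY_REPORT_ID", "report_id must be nonempty"))
        if not self.patient_id:
            errors.append(("EMPTY_PATIENT_ID", "patient_id must be nonempty"))
        if self.gender not in GENDER_CODES:
            errors.append(
                ("INVALID_GENDER", f"gender {self.gender!r} not in {set(GENDER_CODES)}")
            )
        if not ICD10_PATTERN.match(self.icd10_code):
            errors.append(("INVALID_ICD10", f"icd10_code {self.icd10_code!r} malformed"))
        if reference_date is not None and self.diagnosis_date > reference_date:
            errors.append(
                (
                    "FUTURE_DATE",
                    f"diagnosis_date {self.diagnosis_date} after reference {reference_date}",
                )
            )
        return errors

    @property
    def diagnosis_year(self) -> int:
        return self.diagnosis_date.year


@dataclass(frozen=True)
class OBDSCollection:
    """A site's export: an ordered list of reports sharing version and site."""

    obds_version: str
    site_id: str
    reports: tuple[OBDSReport, ...]

    def __post_init__(self) -> None:
        for r in self.reports:
            if r.obds_version != self.obds_version or r.site_id != self.site_id:
                raise OBDSError(
                    f"report {r.report_id!r} does not share the collection's "
                    f"obds_version/site_id"
                )


@dataclass(frozen=True)
class RejectedReport:
    report_id: str
    code: str
    message: str
    source: dict[str, str] | None = None  # raw field strings, for quarantine


@dataclass(frozen=True)
class ParseResult:
    collection: OBDSCollection
    rejections: tuple[RejectedReport, ...]


@dataclass(frozen=True)
class SupportedVersions:
    versions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.versions:
            raise ValueError("SupportedVersions must be nonempty")

    @classmethod
    def default(cls) -> "SupportedVersions":
        return cls(DEFAULT_SUPPORTED_VERSIONS)


@dataclass(frozen=True)
class VersionCheck:
    ok: bool
    version: str
    supported: frozenset[str]

    @property
    def message(self) -> str:
        if self.ok:
            return f"obds_version {self.version} is supported"
        return (
            f"unsupported obds_version {self.version!r}; "
            f"supported: {sorted(self.supported)}"
        )


# ---------------------------------------------------------------------------
# parsing


def _text(el: etree._Element, tag: str) -> str | None:
    child = el.find(tag)
    if child is None or child.text is None:
        return None
    return child.text.strip()


def _report_fields(el: etree._Element) -> dict[str, str]:
    diag = el.find("Diagnosis")
    return {
        "report_id": el.get("id", ""),
        "patient_id": _text(el, "PatientID") or "",
        "gender": _text(el, "Gender") or "",
        "quasi_identifier": _text(el, "QuasiIdentifier") or "",
        "icd10": (diag.get("icd10", "") if diag is not None else ""),
        "icd10_version": (diag.get("icd10_version", "") if diag is not None else ""),
        "date": (diag.get("date", "") if diag is not None else ""),
    }


def _build_report(
    fields: dict[str, str],
    obds_version: str,
    site_id: str,
    reference_date: dt.date | None,
) -> OBDSReport | RejectedReport:
    try:
        date = dt.date.fromisoformat(fields["date"])
    except ValueError:
        return RejectedReport(
            fields["report_id"],
            "INVALID_DATE",
            f"diagnosis date {fields['date']!r} is not an ISO 8601 calendar date",
            source=fields,
        )
    report = OBDSReport(
        report_id=fields["report_id"],
        site_id=site_id,
        patient_id=fields["patient_id"],
        gender=fields["gender"],
        icd10_code=fields["icd10"],
        icd10_version=fields["icd10_version"],
        diagnosis_date=date,
        obds_version=obds_version,
        quasi_identifier=fields["quasi_identifier"] or None,
    )
    errors = report.invariant_errors(reference_date)
    if errors:
        code, message = errors[0]
        return RejectedReport(report.report_id, code, message, source=fields)
    return report


def _parse_root(xml_document: str | bytes) -> etree._Element:
    data = xml_document.encode("utf-8") if isinstance(xml_document, str) else xml_document
    try:
        return etree.fromstring(data)
    except etree.XMLSyntaxError as exc:  # message includes "line N"
        raise OBDSParseError(f"malformed XML: {exc}") from exc


def parse_collection(
    xml_document: str | bytes, reference_date: dt.date | None = None
) -> ParseResult:
    """Parse a collection export.

    Reports violating an invariant are rejected individually and recorded;
    valid reports are retained in document order.  Duplicate report ids keep
    the first occurrence and reject the rest.
    """
    root = _parse_root(xml_document)
    if root.tag != COLLECTION_ROOT:
        raise OBDSDialectError(
            f"expected root <{COLLECTION_ROOT}>, found <{root.tag}>"
        )
    obds_version = root.get("obds_version")
    site_id = root.get("site_id")
    if not obds_version or not site_id:
        raise OBDSDialectError("root must carry obds_version and site_id attributes")

    reports: list[OBDSReport] = []
    rejections: list[RejectedReport] = []
    seen: set[str] = set()
    for el in root.iterfind("Report"):
        result = _build_report(_report_fields(el), obds_version, site_id, reference_date)
        if isinstance(result, RejectedReport):
            rejections.append(result)
            continue
        if result.report_id in seen:
            rejections.append(
                RejectedReport(
                    result.report_id,
                    "DUPLICATE_REPORT_ID",
                    f"report_id {result.report_id!r} already seen in this collection",
                )
            )
            continue
        seen.add(result.report_id)
        reports.append(result)
    return ParseResult(
        OBDSCollection(obds_version, site_id, tuple(reports)), tuple(rejections)
    )


def parse_single_report(
    xml_document: str | bytes, reference_date: dt.date | None = None
) -> OBDSReport:
    """Parse a decomposed single-report document; invariant failures raise."""
    root = _parse_root(xml_document)
    if root.tag != SINGLE_REPORT_ROOT:
        raise OBDSDialectError(f"expected root <{SINGLE_REPORT_ROOT}>, found <{root.tag}>")
    obds_version = root.get("obds_version")
    site_id = root.get("site_id")
    if not obds_version or not site_id:
        raise OBDSDialectError("root must carry obds_version and site_id attributes")
    fields = _report_fields(root)
    fields["report_id"] = root.get("id", "")
    result = _build_report(fields, obds_version, site_id, reference_date)
    if isinstance(result, RejectedReport):
        raise OBDSError(f"{result.code}: {result.message}")
    return result


def read_collection(path: str | Path, reference_date: dt.date | None = None) -> ParseResult:
    return parse_collection(Path(path).read_bytes(), reference_date)


# ---------------------------------------------------------------------------
# version gate


def check_version(
    collection: OBDSCollection, supported: SupportedVersions | None = None
) -> VersionCheck:
    supported = supported or SupportedVersions.default()
    return VersionCheck(
        ok=collection.obds_version in supported.versions,
        version=collection.obds_version,
        supported=supported.versions,
    )


# ---------------------------------------------------------------------------
# decomposition


def decompose_collection(collection: OBDSCollection) -> list[OBDSReport]:
    """Split a collection into single reports, preserving order.

    Each report already carries the collection's ``obds_version`` and
    ``site_id`` (enforced by the collection invariant).
    """
    if not collection.reports:
        log.warning("decompose: collection for site %s is empty", collection.site_id)
    return list(collection.reports)


# ---------------------------------------------------------------------------
# writing


def _report_element(tag: str, report: OBDSReport) -> etree._Element:
    el = etree.Element(tag, id=report.report_id)
    etree.SubElement(el, "PatientID").text = report.patient_id
    etree.SubElement(el, "Gender").text = report.gender
    if report.quasi_identifier is not None:
        etree.SubElement(el, "QuasiIdentifier").text = report.quasi_identifier
    etree.SubElement(
        el,
        "Diagnosis",
        icd10=report.icd10_code,
        icd10_version=report.icd10_version,
        date=report.diagnosis_date.isoformat(),
    )
    return el


def collection_to_xml(collection: OBDSCollection) -> bytes:
    root = etree.Element(
        COLLECTION_ROOT,
        obds_version=collection.obds_version,
        site_id=collection.site_id,
    )
    for report in collection.reports:
        root.append(_report_element("Report", report))
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def single_report_to_xml(report: OBDSReport) -> bytes:
    el = _report_element(SINGLE_REPORT_ROOT, report)
    el.set("obds_version", report.obds_version)
    el.set("site_id", report.site_id)
    return etree.tostring(el, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def write_collection(collection: OBDSCollection, path: str | Path) -> Path:
    path = Path(path)
    path.write_bytes(collection_to_xml(collection))
    return path


def write_single_report(report: OBDSReport, folder: str | Path) -> Path:
    """Write one decomposed report as ``<site_id>_<report_id>.xml``."""
    folder = Path(folder)
    path = folder / f"{report.site_id}_{report.report_id}.xml"
    path.write_bytes(single_report_to_xml(report))
    return path


def list_import_folder(folder: str | Path) -> list[Path]:
    """Folder-import contract: non-recursive ``*.xml``, lexicographic order."""
    return sorted(Path(folder).glob("*.xml"), key=lambda p: p.name)
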