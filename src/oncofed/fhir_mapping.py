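"""Mapping single oBDS reports to FHIR-style Patient/Condition bundles.

Only the slice of the oncology FHIR model that the downstream analysis
consumes is implemented: one Patient (identifier, administrative gender) and
one Condition (ICD-10-GM coding, onset date) per cancer-case report, grouped
in a reference-closed bundle.  Bundles travel between stages as NDJSON —
one FHIR-JSON object per line — which replaces a message broker with a
folder contract at identical message granularity.  Resource ids are stable
functions of (site_id, report_id) so re-processing is idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

log = logging.getLogger(__name__)

#: oBDS administrative gender -> FHIR administrative gender
GENDER_MAP = {"M": "male", "W": "female", "D": "other", "U": "unknown"}

DEFAULT_ICD10_SYSTEM = "http://fhir.de/CodeSystem/bfarm/icd-10-gm"
PATIENT_ID_SYSTEM = "https://oncofed.local/sid/patient-id"
SITE_TAG_SYSTEM = "https://oncofed.local/sid/site"
REPORT_TAG_SYSTEM = "https://oncofed.local/sid/report"
DEIDENT_TAG_SYSTEM = "https://oncofed.local/sid/deidentified"
QUASI_IDENTIFIER_URL = "https://oncofed.local/fhir/StructureDefinition/quasi-identifier"


class MappingError(ValueError):
    """A report field could not be mapped to its FHIR representation."""


def stable_id(prefix: str, site_id: str, report_id: str) -> str:
    digest = hashlib.sha256(f"{site_id}|{report_id}".encode()).hexdigest()[:16]
    return f"{prefix}-{digest}"


@dataclass(frozen=True)
class PatientResource:
    id: str
    identifier_system: str
    identifier_value: str
    gender: str
    quasi_identifier: str | None = None
    resource_type: str = "Patient"


@dataclass(frozen=True)
class ConditionResource:
    id: str
    subject_reference: str
    code: str
    code_system: str
    code_version: str
    onset_date: str  # ISO calendar date
    resource_type: str = "Condition"


@dataclass(frozen=True)
class ResourceBundle:
    bundle_id: str
    site_id: str
    report_id: str
    patient: PatientResource
    condition: ConditionResource
    deidentified: bool = False

    def __post_init__(self) -> None:
        if self.condition.subject_reference != f"Patient/{self.patient.id}":
            raise MappingError(
                f"bundle {self.bundle_id}: subject reference "
                f"{self.condition.subject_reference!r} does not resolve to the "
                f"bundled patient"
            )
        if not self.report_id:
            raise MappingError("bundle provenance (report_id) must be nonempty")


def map_report(report, code_system: str = DEFAULT_ICD10_SYSTEM) -> ResourceBundle:
    """Map one validated single report to a Patient+Condition bundle.

    Gender follows the fixed table M->male, W->female, D->other, U->unknown;
    the diagnosis code, catalog version and date are copied verbatim.
    """
    if report.gender not in GENDER_MAP:
        raise MappingError(f"unmapped gender code {report.gender!r}")
    if report.diagnosis_date is None:
        raise MappingError("missing diagnosis date")
    patient_id = stable_id("pat", report.site_id, report.report_id)
    patient = PatientResource(
        id=patient_id,
        identifier_system=PATIENT_ID_SYSTEM,
        identifier_value=report.patient_id,
        gender=GENDER_MAP[report.gender],
        quasi_identifier=report.quasi_identifier,
    )
    condition = ConditionResource(
        id=stable_id("con", report.site_id, report.report_id),
        subject_reference=f"Patient/{patient_id}",
        code=report.icd10_code,
        code_system=code_system,
        code_version=report.icd10_version,
        onset_date=report.diagnosis_date.isoformat(),
    )
    return ResourceBundle(
        bundle_id=stable_id("bnd", report.site_id, report.report_id),
        site_id=report.site_id,
        report_id=report.report_id,
        patient=patient,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# FHIR-JSON serialization


def _patient_json(p: PatientResource) -> dict:
    obj: dict = {
        "resourceType": "Patient",
        "id": p.id,
        "identifier": [{"system": p.identifier_system, "value": p.identifier_value}],
        "gender": p.gender,
    }
    if p.quasi_identifier is not None:
        obj["extension"] = [
            {"url": QUASI_IDENTIFIER_URL, "valueString": p.quasi_identifier}
        ]
    return obj


def _condition_json(c: ConditionResource) -> dict:
    return {
        "resourceType": "Condition",
        "id": c.id,
        "subject": {"reference": c.subject_reference},
        "code": {
            "coding": [
                {"system": c.code_system, "version": c.code_version, "code": c.code}
            ]
        },
        "onsetDateTime": c.onset_date,
    }


def bundle_to_json(bundle: ResourceBundle) -> dict:
    return {
        "resourceType": "Bundle",
        "id": bundle.bundle_id,
        "type": "collection",
        "meta": {
            "tag": [
                {"system": SITE_TAG_SYSTEM, "code": bundle.site_id},
                {"system": REPORT_TAG_SYSTEM, "code": bundle.report_id},
                {
                    "system": DEIDENT_TAG_SYSTEM,
                    "code": "true" if bundle.deidentified else "false",
                },
            ]
        },
        "entry": [
            {"resource": _patient_json(bundle.patient)},
            {"resource": _condition_json(bundle.condition)},
        ],
    }


def bundle_from_json(obj: dict) -> ResourceBundle:
    if obj.get("resourceType") != "Bundle":
        raise MappingError(f"not a Bundle: resourceType={obj.get('resourceType')!r}")
    tags = {t["system"]: t["code"] for t in obj.get("meta", {}).get("tag", [])}
    resources = {e["resource"]["resourceType"]: e["resource"] for e in obj["entry"]}
    pat, con = resources["Patient"], resources["Condition"]
    quasi = None
    for ext in pat.get("extension", []):
        if ext.get("url") == QUASI_IDENTIFIER_URL:
            quasi = ext.get("valueString")
    patient = PatientResource(
        id=pat["id"],
        identifier_system=pat["identifier"][0]["system"],
        identifier_value=pat["identifier"][0]["value"],
        gender=pat["gender"],
        quasi_identifier=quasi,
    )
    coding = con["code"]["coding"][0]
    condition = ConditionResource(
        id=con["id"],
        subject_reference=con["subject"]["reference"],
        code=coding["code"],
        code_system=coding["system"],
        code_version=coding.get("version", ""),
        onset_date=con["onsetDateTime"],
    )
    return ResourceBundle(
        bundle_id=obj["id"],
        site_id=tags.get(SITE_TAG_SYSTEM, ""),
        report_id=tags.get(REPORT_TAG_SYSTEM, ""),
        patient=patient,
        condition=condition,
        deidentified=tags.get(DEIDENT_TAG_SYSTEM) == "true",
    )


def write_bundles(bundles: Sequence[ResourceBundle], path: str | Path) -> Path:
    """Write bundles as NDJSON (one FHIR-JSON object per line, sorted keys)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for bundle in bundles:
            fh.write(json.dumps(bundle_to_json(bundle), sort_keys=True))
            fh.write("\n")
    return path


@dataclass(frozen=True)
class LineRejection:
    path: str
    line_number: int
    message: str


def read_bundles(path: str | Path) -> tuple[list[ResourceBundle], list[LineRejection]]:
    """Read an NDJSON bundle file; malformed lines are recorded, not fatal."""
    path = Path(path)
    bundles: list[ResourceBundle] = []
    rejections: list[LineRejection] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                bundles.append(bundle_from_json(json.loads(line)))
            except (json.JSONDecodeError, KeyError, IndexError, MappingError) as exc:
                rejections.append(LineRejection(str(path), lineno, str(exc)))
    if rejections:
        log.warning("read_bundles: %d malformed line(s) in %s", len(rejections), path)
    return bundles, rejections


def read_bundle_folder(
    folder: str | Path,
) -> tuple[list[ResourceBundle], list[LineRejection]]:
    bundles: list[ResourceBundle] = []
    rejections: list[LineRejection] = []
    for path in sorted(Path(folder).glob("*.ndjson")):
        b, r = read_bundles(path)
        bundles.extend(b)
        rejections.extend(r)
    return bundles, rejections
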