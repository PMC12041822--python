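"""Flattening deidentified bundles to per-site case tables.

This is the analysis boundary of the pipeline: nested FHIR-style bundles are
projected onto flat rows (one per cancer case) with the ICD-10 code grouped
into a clinically meaningful *entity group* and the diagnosis date
generalized to a year.  The resulting CSV is what a site would upload to its
local analysis server; nothing finer-grained ever leaves this stage.
"""

from __future__ import annotations

import csv
import hashlib
import importlib.resources
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .fhir_mapping import ResourceBundle
from .obds_io import ICD10_PATTERN

log = logging.getLogger(__name__)

CASE_TABLE_HEADER = (
    "pseudonym",
    "gender",
    "icd10_code",
    "diagnosis_year",
    "entity_group",
    "site_id",
)

_RANGE_RE = re.compile(r"^([A-Z])([0-9]{2})-([A-Z])([0-9]{2})$")
_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")


class EntityMapError(ValueError):
    """Malformed entity-group map configuration."""


class PrivacyError(RuntimeError):
    """An identified bundle reached a stage that requires deidentified input."""


class CaseTableFormatError(ValueError):
    """CSV does not match the case-table dialect."""


def _spec_matches(spec: str, code: str) -> bool:
    category = code[:3]
    m = _RANGE_RE.match(spec)
    if m:
        lo_letter, lo_num, hi_letter, hi_num = m.groups()
        return lo_letter == category[0] == hi_letter and lo_num <= category[1:] <= hi_num
    if _CATEGORY_RE.match(spec):
        # bare category: subcodes inherit the category's group
        return category == spec
    if "." in spec:
        return code == spec or code.startswith(spec)
    raise EntityMapError(f"malformed ICD-10 spec {spec!r}")


def _validate_spec(spec: str) -> None:
    if not (_RANGE_RE.match(spec) or _CATEGORY_RE.match(spec) or ICD10_PATTERN.match(spec)):
        raise EntityMapError(f"malformed ICD-10 spec {spec!r}")


def _expand_spec(spec: str) -> list[str]:
    m = _RANGE_RE.match(spec)
    if m:
        letter, lo, hi = m.group(1), int(m.group(2)), int(m.group(4))
        return [f"{letter}{n:02d}" for n in range(lo, hi + 1)]
    return [spec]


@dataclass(frozen=True)
class EntityGroupMap:
    """Ordered first-match-wins mapping from ICD-10 codes to entity groups.

    Specs are either full codes ("D09.0"), three-character categories
    ("C50", matching all subcodes) or category ranges ("C18-C21").
    """

    groups: tuple[tuple[str, tuple[str, ...]], ...]
    fallback_label: str = "other"

    def __post_init__(self) -> None:
        seen = set()
        for label, specs in self.groups:
            if label in seen:
                raise EntityMapError(f"duplicate group label {label!r}")
            seen.add(label)
            for spec in specs:
                _validate_spec(spec)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.groups)

    def assign(self, icd10_code: str) -> str:
        """Group label for a code; unmatched codes get the fallback label."""
        if not ICD10_PATTERN.match(icd10_code):
            raise ValueError(f"malformed ICD-10 code {icd10_code!r}")
        for label, specs in self.groups:
            for spec in specs:
                if _spec_matches(spec, icd10_code):
                    return label
        return self.fallback_label

    def sample_codes(self, label: str) -> list[str]:
        """Concrete codes representing a group (ranges expanded), for generators."""
        for group_label, specs in self.groups:
            if group_label == label:
                return [c for spec in specs for c in _expand_spec(spec)]
        raise KeyError(f"unknown entity group {label!r}")

    def config_hash(self) -> str:
        payload = repr((self.groups, self.fallback_label)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, source: str | Path) -> "EntityGroupMap":
        data = yaml.safe_load(Path(source).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "EntityGroupMap":
        try:
            groups = tuple(
                (g["label"], tuple(str(s) for s in g["icd10"])) for g in data["groups"]
            )
        except (KeyError, TypeError) as exc:
            raise EntityMapError(f"malformed entity map: {exc}") from exc
        return cls(groups=groups, fallback_label=str(data.get("fallback", "other")))

    @classmethod
    def default(cls) -> "EntityGroupMap":
        text = (
            importlib.resources.files("oncofed.data")
            .joinpath("entity_groups_default.yaml")
            .read_text()
        )
        return cls.from_dict(yaml.safe_load(text))


def assign_entity_group(icd10_code: str, entity_map: EntityGroupMap) -> str:
    return entity_map.assign(icd10_code)


@dataclass(frozen=True)
class CaseRow:
    pseudonym: str
    gender: str
    icd10_code: str
    diagnosis_year: int
    entity_group: str
    site_id: str

    def __post_init__(self) -> None:
        if not 1900 <= self.diagnosis_year <= 2100:
            raise ValueError(f"implausible diagnosis_year {self.diagnosis_year}")


@dataclass(frozen=True)
class CaseTable:
    rows: tuple[CaseRow, ...]
    site_id: str
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.site_id != self.site_id:
                raise ValueError(
                    f"row site_id {row.site_id!r} differs from table {self.site_id!r}"
                )


def flatten(
    bundles: Sequence[ResourceBundle],
    entity_map: EntityGroupMap,
    year_filter: Iterable[int],
) -> CaseTable:
    """One row per deidentified bundle whose diagnosis year passes the filter.

    Raises :class:`PrivacyError` if any bundle has not been deidentified —
    identified data must never reach the analysis boundary.
    """
    years = set(year_filter)
    site_ids = {b.site_id for b in bundles}
    if len(site_ids) > 1:
        raise ValueError(f"flatten expects a single site, got {sorted(site_ids)}")
    site_id = site_ids.pop() if site_ids else ""
    rows: list[CaseRow] = []
    filtered = 0
    for bundle in bundles:
        if not bundle.deidentified:
            raise PrivacyError(
                f"bundle {bundle.bundle_id} reached flatten without deidentification"
            )
        year = int(bundle.condition.onset_date[:4])
        if year not in years:
            filtered += 1
            continue
        rows.append(
            CaseRow(
                pseudonym=bundle.patient.identifier_value,
                gender=bundle.patient.gender,
                icd10_code=bundle.condition.code,
                diagnosis_year=year,
                entity_group=entity_map.assign(bundle.condition.code),
                site_id=bundle.site_id,
            )
        )
    if filtered:
        log.info("flatten: %d bundle(s) outside year filter %s", filtered, sorted(years))
    provenance = {
        "year_filtered": filtered,
        "bundles_in": len(bundles),
        "entity_map_hash": entity_map.config_hash(),
    }
    return CaseTable(rows=tuple(rows), site_id=site_id, provenance=provenance)


def fallback_share(table: CaseTable, entity_map: EntityGroupMap) -> float:
    """Fraction of rows in the fallback group (visibility of 'other' inflation)."""
    if not table.rows:
        return 0.0
    n = sum(1 for r in table.rows if r.entity_group == entity_map.fallback_label)
    return n / len(table.rows)


def case_table_to_csv(table: CaseTable) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(CASE_TABLE_HEADER)
    for row in table.rows:
        writer.writerow(
            [
                row.pseudonym,
                row.gender,
                row.icd10_code,
                row.diagnosis_year,
                row.entity_group,
                row.site_id,
            ]
        )
    return buf.getvalue()


def write_case_table(table: CaseTable, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(case_table_to_csv(table), encoding="utf-8", newline="")
    return path


def read_case_table(path: str | Path) -> CaseTable:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = tuple(next(reader))
        except StopIteration:
            raise CaseTableFormatError("empty file; expected a header row")
        if header != CASE_TABLE_HEADER:
            raise CaseTableFormatError(
                f"header mismatch: {header!r} != {CASE_TABLE_HEADER!r}"
            )
        rows = tuple(
            CaseRow(r[0], r[1], r[2], int(r[3]), r[4], r[5]) for r in reader if r
        )
    site_id = rows[0].site_id if rows else ""
    return CaseTable(rows=rows, site_id=site_id)
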