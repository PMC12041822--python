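import datetime as dt
import string

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from oncofed.deidentify import HashingPseudonymProvider
from oncofed.obds_io import OBDSCollection, OBDSReport
from oncofed.tabular import CaseRow, CaseTable, EntityGroupMap

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def entity_map() -> EntityGroupMap:
    return EntityGroupMap.default()


@pytest.fixture()
def provider() -> HashingPseudonymProvider:
    return HashingPseudonymProvider("test-secret", domains=("patient", "other"))


# ---------------------------------------------------------------------------
# hypothesis strategies for the oBDS domain


_token = st.text(alphabet=string.ascii_letters + string.digits + "-_", min_size=1, max_size=10)
_gender = st.sampled_from("MWDU")
_icd10 = st.from_regex(r"[A-Z][0-9]{2}(\.[0-9]{1,2})?", fullmatch=True)
_date = st.dates(min_value=dt.date(2000, 1, 1), max_value=dt.date(2025, 12, 31))


@st.composite
def obds_reports(draw, site_id=None, obds_version="2.2.2", report_id=None):
    return OBDSReport(
        report_id=report_id if report_id is not None else draw(_token),
        site_id=site_id if site_id is not None else draw(_token),
        patient_id=draw(_token),
        gender=draw(_gender),
        icd10_code=draw(_icd10),
        icd10_version="10-GM-2022",
        diagnosis_date=draw(_date),
        obds_version=obds_version,
        quasi_identifier=draw(st.none() | _token),
    )


@st.composite
def obds_collections(draw, max_reports=8):
    site_id = draw(_token)
    report_ids = draw(
        st.lists(_token, max_size=max_reports, unique=True)
    )
    reports = tuple(
        draw(obds_reports(site_id=site_id, report_id=rid)) for rid in report_ids
    )
    return OBDSCollection("2.2.2", site_id, reports)


# ---------------------------------------------------------------------------
# seeded random builders (for bulk robustness/oracle checks)

GENDERS_FHIR = ("male", "female", "other", "unknown")


def make_random_collection(rng: np.random.Generator, site_id: str, n: int) -> OBDSCollection:
    letters = "CD"
    reports = []
    for i in range(n):
        code = f"{letters[rng.integers(2)]}{rng.integers(100):02d}"
        if rng.random() < 0.5:
            code += f".{rng.integers(10)}"
        reports.append(
            OBDSReport(
                report_id=f"R{i:04d}",
                site_id=site_id,
                patient_id=f"P{i:04d}",
                gender="MWDU"[rng.integers(4)],
                icd10_code=code,
                icd10_version="10-GM-2022",
                diagnosis_date=dt.date(2022, 1, 1) + dt.timedelta(days=int(rng.integers(365))),
                obds_version="2.2.2",
                quasi_identifier=f"QI-{site_id}-{i:04d}" if rng.random() < 0.5 else None,
            )
        )
    return OBDSCollection("2.2.2", site_id, tuple(reports))


def make_random_table(
    rng: np.random.Generator,
    site_id: str,
    n: int,
    entities=("breast", "prostate", "melanoma", "lung", "other"),
) -> CaseTable:
    rows = tuple(
        CaseRow(
            pseudonym=f"tok{site_id}{i:05d}",
            gender=GENDERS_FHIR[rng.integers(len(GENDERS_FHIR))],
            icd10_code="C50",
            diagnosis_year=2022,
            entity_group=entities[rng.integers(len(entities))],
            site_id=site_id,
        )
        for i in range(n)
    )
    return CaseTable(rows=rows, site_id=site_id)
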