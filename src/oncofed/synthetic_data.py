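"""Synthetic per-site oBDS exports with controlled count structure.

Every downstream stage of the pipeline is exercised on synthetic data only:
a :class:`SiteProfile` fixes the entity-group × gender cell counts of one
site's annual export, either *exactly* (the generated collection reproduces
the cells bit-exactly once flattened and grouped) or *multinomially* (cells
are weights for a seeded multinomial draw of a given total, emulating
sampling variability between documentation years).

Report internals are deterministic given the seed: ICD-10 codes are drawn
uniformly from the codes configured for the cell's entity group (optionally
with a random subcode digit), diagnosis dates are uniform over the profile
year, patient identifiers are zero-padded per-site counters, and every
report carries a synthetic quasi-identifier so the deidentification rules
have something to strip.

The packaged ``paper_federation.yaml`` profile encodes a 6-site federation
whose combined entity and gender totals equal the published figures this
package's worked example reproduces (17,885 cases overall; site 5 with
2045 cases of which 500 melanoma).
"""

from __future__ import annotations

import datetime as dt
import importlib.resources
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .obds_io import OBDSCollection, OBDSReport, write_collection
from .tabular import EntityGroupMap

log = logging.getLogger(__name__)

DEFAULT_OBDS_VERSION = "2.2.2"


class ProfileError(ValueError):
    """Invalid generator profile configuration."""


@dataclass(frozen=True)
class SiteProfile:
    """Count structure of one site's export for one diagnosis year."""

    site_id: str
    year: int
    cell_counts: tuple[tuple[tuple[str, str], int], ...]  # ((entity, gender), n)
    mode: str = "exact"  # or "multinomial"
    total: int | None = None  # multinomial only
    seed: int = 0
    obds_version: str = DEFAULT_OBDS_VERSION

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "multinomial"):
            raise ProfileError(f"unknown mode {self.mode!r}")
        counts = dict(self.cell_counts)
        if any(v < 0 for v in counts.values()):
            raise ProfileError("cell counts must be nonnegative")
        if self.mode == "exact" and sum(counts.values()) < 1:
            raise ProfileError("exact mode requires at least one case")
        if self.mode == "multinomial":
            if self.total is None or self.total < 1:
                raise ProfileError("multinomial mode requires a positive total")
            if sum(counts.values()) <= 0:
                raise ProfileError("multinomial weights must sum to a positive value")

    @property
    def cells(self) -> dict[tuple[str, str], int]:
        return dict(self.cell_counts)


@dataclass(frozen=True)
class FederationProfile:
    name: str
    sites: tuple[SiteProfile, ...]
    entity_map_ref: str = "builtin"

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ProfileError(f"duplicate site_ids in federation: {ids}")

    def site(self, site_id: str) -> SiteProfile:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)


# ---------------------------------------------------------------------------
# profile I/O


def _profile_from_dict(data: Mapping) -> SiteProfile:
    cells = []
    for entity, genders in data["cells"].items():
        for gender, count in genders.items():
            cells.append(((str(entity), str(gender)), int(count)))
    return SiteProfile(
        site_id=str(data["site_id"]),
        year=int(data["year"]),
        cell_counts=tuple(sorted(cells)),
        mode=data.get("mode", "exact"),
        total=data.get("total"),
        seed=int(data.get("seed", 0)),
        obds_version=str(data.get("obds_version", DEFAULT_OBDS_VERSION)),
    )


def federation_from_dict(data: Mapping) -> FederationProfile:
    return FederationProfile(
        name=str(data.get("name", "federation")),
        sites=tuple(_profile_from_dict(s) for s in data["sites"]),
        entity_map_ref=str(data.get("entity_map", "builtin")),
    )


def load_federation_profile(path: str | Path) -> FederationProfile:
    return federation_from_dict(yaml.safe_load(Path(path).read_text()))


def paper_federation() -> FederationProfile:
    """The packaged 6-site worked-example federation (exact mode)."""
    text = (
        importlib.resources.files("oncofed.data")
        .joinpath("paper_federation.yaml")
        .read_text()
    )
    return federation_from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# generation


def _draw_code(rng: np.random.Generator, codes: list[str]) -> str:
    code = codes[int(rng.integers(len(codes)))]
    # half the time add a subcode digit so category matching is exercised
    if "." not in code and rng.random() < 0.5:
        code = f"{code}.{int(rng.integers(10))}"
    return code


def _cell_sizes(profile: SiteProfile, rng: np.random.Generator) -> list[tuple[tuple[str, str], int]]:
    cells = sorted(profile.cells.items())
    if profile.mode == "exact":
        return cells
    weights = np.array([c for _, c in cells], dtype=float)
    draws = rng.multinomial(profile.total, weights / weights.sum())
    return [(key, int(n)) for (key, _), n in zip(cells, draws)]


def generate_site(
    profile: SiteProfile,
    entity_map: EntityGroupMap,
    seed: int | None = None,
) -> OBDSCollection:
    """Generate one site's collection; identical profile+seed give identical output."""
    unknown = [e for (e, _), _ in profile.cell_counts if e not in entity_map.labels]
    if unknown:
        raise ProfileError(f"unknown entity group(s) in profile: {sorted(set(unknown))}")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    year_start = dt.date(profile.year, 1, 1)
    days = (dt.date(profile.year + 1, 1, 1) - year_start).days
    reports: list[OBDSReport] = []
    counter = 0
    for (entity, gender), n in _cell_sizes(profile, rng):
        codes = entity_map.sample_codes(entity)
        for _ in range(n):
            counter += 1
            reports.append(
                OBDSReport(
                    report_id=f"R{counter:06d}",
                    site_id=profile.site_id,
                    patient_id=f"P{counter:06d}",
                    gender=gender,
                    icd10_code=_draw_code(rng, codes),
                    icd10_version=f"10-GM-{profile.year}",
                    diagnosis_date=year_start + dt.timedelta(days=int(rng.integers(days))),
                    obds_version=profile.obds_version,
                    quasi_identifier=f"QI-{profile.site_id}-{counter:06d}",
                )
            )
    return OBDSCollection(profile.obds_version, profile.site_id, tuple(reports))


def generate_federation(
    federation: FederationProfile,
    entity_map: EntityGroupMap,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, OBDSCollection]:
    """Generate every site; optionally write one XML file per site.

    A global ``seed`` derives per-site seeds (seed*97 + index) so a single
    integer reproduces the whole federation; without it each profile's own
    seed is used.
    """
    if not federation.sites:
        log.warning("generate_federation: empty federation %r", federation.name)
        return {}
    collections: dict[str, OBDSCollection] = {}
    for index, profile in enumerate(federation.sites):
        site_seed = None if seed is None else (seed * 97 + index) % (2**31 - 1)
        try:
            collections[profile.site_id] = generate_site(profile, entity_map, site_seed)
        except ProfileError as exc:
            raise ProfileError(f"site {profile.site_id}: {exc}") from exc
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for site_id, collection in collections.items():
            write_collection(collection, out_dir / f"{site_id}.xml")
    return collections


# ---------------------------------------------------------------------------
# gold-standard helpers


def collection_entity_counts(
    collection: OBDSCollection, entity_map: EntityGroupMap
) -> dict[str, int]:
    return dict(
        sorted(Counter(entity_map.assign(r.icd10_code) for r in collection.reports).items())
    )


def federation_entity_counts(
    collections: Iterable[OBDSCollection], entity_map: EntityGroupMap
) -> dict[str, int]:
    total: Counter = Counter()
    for collection in collections:
        total.update(collection_entity_counts(collection, entity_map))
    return dict(sorted(total.items()))


def perturb_gold(
    collection: OBDSCollection,
    add_late: int,
    seed: int,
    entity_map: EntityGroupMap,
) -> tuple[OBDSCollection, dict[str, int]]:
    """Return the unmodified collection plus a perturbed gold-standard table.

    Emulates retrospective documentation: ``add_late`` extra cases (random
    entities, seeded) exist in the tumor documentation system but were
    absent from the export, so every entity's gold count is >= the pipeline
    count and the totals differ by exactly ``add_late``.
    """
    if add_late < 0:
        raise ValueError("add_late must be >= 0")
    gold = Counter(collection_entity_counts(collection, entity_map))
    rng = np.random.default_rng(seed)
    labels = entity_map.labels
    for _ in range(add_late):
        gold[labels[int(rng.integers(len(labels)))]] += 1
    return collection, dict(sorted(gold.items()))
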