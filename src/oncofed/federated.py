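"""Disclosure-controlled per-site aggregation and central combination.

This module stands in for a DataSHIELD/OPAL deployment at desk scale: each
site computes an exact entity-group × gender cross-tabulation of its case
table, suppresses any cell or marginal whose count is positive but below a
minimum cell size, and exports *only* that aggregate.  A central step sums
the site aggregates into the federation-wide result used to answer

* Q1 — the distribution of tumor entities (per site and combined), and
* Q2 — the distribution of administrative gender within each entity,
  under two estimators: pooled (combined cell over combined reported cells)
  and mean-of-sites (unweighted mean of site-level shares).

Raw rows never leave :func:`aggregate_site`; everything downstream sees
counts only.  True zeros are reported as zero by default (absence of a
combination discloses nothing beyond absence); strict mode treats a
missing cell at any site as non-combinable.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .tabular import CaseTable


class _Suppressed:
    """Singleton marker for a disclosure-suppressed count."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "SUPPRESSED"


SUPPRESSED = _Suppressed()
SUPPRESSION_MARKER = "SUPPRESSED"

Cell = int  # unsuppressed counts
CellValue = "int | _Suppressed"


class DisclosureError(RuntimeError):
    """A serialized aggregate would disclose a below-threshold count."""


@dataclass(frozen=True)
class DisclosurePolicy:
    """Small-cell suppression policy.

    min_cell is the smallest publishable positive count (default 5, a common
    registry small-cell rule).  strict_zeros=True additionally refuses to
    combine a cell that any site did not report at all.
    """

    min_cell: int = 5
    strict_zeros: bool = False

    def __post_init__(self) -> None:
        if self.min_cell < 1:
            raise ValueError("min_cell must be >= 1")

    def screen(self, count: int):
        return SUPPRESSED if 0 < count < self.min_cell else count


@dataclass
class SiteAggregate:
    """Disclosure-filtered local cross-tabulation; the only exported object.

    ``cells`` holds only observed (entity, gender) combinations; absent keys
    are true zeros.  ``total_cases`` is the pre-suppression row count —
    totals are never reduced by suppression.
    """

    site_id: str
    total_cases: int
    cells: dict[tuple[str, str], "int | _Suppressed"]
    entity_marginals: dict[str, "int | _Suppressed"]
    gender_marginals: dict[str, "int | _Suppressed"]


def aggregate_site(table: CaseTable, policy: DisclosurePolicy) -> SiteAggregate:
    """Exact cross-tabulation of one site's case table, then suppression."""
    site_ids = {row.site_id for row in table.rows}
    if len(site_ids) > 1:
        raise ValueError(f"mixed site_ids in one table: {sorted(site_ids)}")
    counts = Counter((row.entity_group, row.gender) for row in table.rows)
    entity = Counter(row.entity_group for row in table.rows)
    gender = Counter(row.gender for row in table.rows)
    return SiteAggregate(
        site_id=table.site_id,
        total_cases=len(table.rows),
        cells={k: policy.screen(v) for k, v in sorted(counts.items())},
        entity_marginals={k: policy.screen(v) for k, v in sorted(entity.items())},
        gender_marginals={k: policy.screen(v) for k, v in sorted(gender.items())},
    )


@dataclass
class FederatedResult:
    """Central combination of site aggregates."""

    per_site: list[SiteAggregate]
    combined_cells: dict[tuple[str, str], "int | _Suppressed"]
    combined_entity_marginals: dict[str, "int | _Suppressed"]
    combined_gender_marginals: dict[str, "int | _Suppressed"]
    combined_total: int
    policy: DisclosurePolicy = field(default_factory=DisclosurePolicy)

    def site(self, site_id: str) -> SiteAggregate:
        for agg in self.per_site:
            if agg.site_id == site_id:
                return agg
        raise KeyError(f"no such site {site_id!r}")


def _combine_maps(
    maps: Sequence[Mapping], policy: DisclosurePolicy
) -> dict:
    """Sum per-site count maps; any suppressed contribution poisons the sum."""
    keys = sorted({k for m in maps for k in m})
    out: dict = {}
    for key in keys:
        total = 0
        poisoned = False
        for m in maps:
            value = m.get(key, 0)
            if value is SUPPRESSED:
                poisoned = True
                break
            if value == 0 and key not in m and policy.strict_zeros:
                poisoned = True
                break
            total += value
        out[key] = SUPPRESSED if poisoned else total
    return out


def combine(
    aggregates: Sequence[SiteAggregate], policy: DisclosurePolicy
) -> FederatedResult:
    """Combine site aggregates; order of sites does not affect the result."""
    if not aggregates:
        raise ValueError("combine requires at least one site aggregate")
    site_ids = [a.site_id for a in aggregates]
    if len(set(site_ids)) != len(site_ids):
        raise ValueError(f"duplicate site_ids: {site_ids}")
    return FederatedResult(
        per_site=list(aggregates),
        combined_cells=_combine_maps([a.cells for a in aggregates], policy),
        combined_entity_marginals=_combine_maps(
            [a.entity_marginals for a in aggregates], policy
        ),
        combined_gender_marginals=_combine_maps(
            [a.gender_marginals for a in aggregates], policy
        ),
        combined_total=sum(a.total_cases for a in aggregates),
        policy=policy,
    )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ndigits decimals (reporting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _scope_marginals(result: FederatedResult, scope: str):
    if scope == "combined":
        return result.combined_entity_marginals, result.combined_total
    agg = result.site(scope)
    return agg.entity_marginals, agg.total_cases


def entity_shares(result: FederatedResult, scope: str = "combined") -> list[tuple[str, float]]:
    """Q1: relative entity frequencies (percent, one decimal), largest first.

    Suppressed marginals are omitted; because the scope total is never
    reduced, the reported shares sum to at most 100% and the gap is the
    suppressed/fallback share.
    """
    marginals, total = _scope_marginals(result, scope)
    shares = [
        (entity, round_half_up(100.0 * count / total))
        for entity, count in marginals.items()
        if count is not SUPPRESSED and total > 0
    ]
    return sorted(shares, key=lambda item: (-item[1], item[0]))


def suppressed_entities(result: FederatedResult, scope: str = "combined") -> list[str]:
    marginals, _ = _scope_marginals(result, scope)
    return sorted(e for e, v in marginals.items() if v is SUPPRESSED)


def gender_shares(
    result: FederatedResult, estimator: str = "mean_of_sites"
) -> dict[str, dict[str, float]]:
    """Q2: gender distribution within each entity (percent, one decimal).

    pooled
        combined cell count over the sum of reported combined cells of the
        entity, so reported genders sum to 100%.
    mean_of_sites
        unweighted arithmetic mean over sites of the site-level gender
        share; a site contributes only if all its nonzero gender cells for
        the entity are unsuppressed (otherwise its shares are unknowable
        from the exported aggregate).
    """
    if estimator == "pooled":
        out: dict[str, dict[str, float]] = {}
        for entity in sorted({e for e, _ in result.combined_cells}):
            reported = {
                g: v
                for (e, g), v in result.combined_cells.items()
                if e == entity and v is not SUPPRESSED
            }
            denom = sum(reported.values())
            if denom > 0:
                out[entity] = {
                    g: round_half_up(100.0 * v / denom) for g, v in sorted(reported.items())
                }
        return out
    if estimator == "mean_of_sites":
        out = {}
        entities = sorted({e for e, _ in result.combined_cells})
        for entity in entities:
            per_site_shares: list[dict[str, float]] = []
            for agg in result.per_site:
                cells = {g: v for (e, g), v in agg.cells.items() if e == entity}
                if not cells:
                    continue  # entity absent at this site
                if any(v is SUPPRESSED for v in cells.values()):
                    continue  # excluded: shares not computable from export
                denom = sum(cells.values())
                per_site_shares.append({g: v / denom for g, v in cells.items()})
            if not per_site_shares:
                continue
            genders = sorted({g for s in per_site_shares for g in s})
            out[entity] = {
                g: round_half_up(
                    100.0 * sum(s.get(g, 0.0) for s in per_site_shares) / len(per_site_shares)
                )
                for g in genders
            }
        return out
    raise ValueError(f"unknown estimator {estimator!r}")


def q2_excluded_sites(result: FederatedResult, entity: str) -> list[str]:
    """Sites excluded from the mean-of-sites estimator for an entity."""
    excluded = []
    for agg in result.per_site:
        cells = {g: v for (e, g), v in agg.cells.items() if e == entity}
        if cells and any(v is SUPPRESSED for v in cells.values()):
            excluded.append(agg.site_id)
    return excluded


# ---------------------------------------------------------------------------
# JSON serialization (the export format; checked for non-disclosure)


def _cells_to_nested(cells: Mapping) -> dict:
    nested: dict[str, dict[str, object]] = {}
    for (entity, gender), value in sorted(cells.items()):
        nested.setdefault(entity, {})[gender] = (
            SUPPRESSION_MARKER if value is SUPPRESSED else value
        )
    return nested


def _marginals_to_plain(marginals: Mapping) -> dict:
    return {
        k: (SUPPRESSION_MARKER if v is SUPPRESSED else v)
        for k, v in sorted(marginals.items())
    }


def _nested_to_cells(nested: Mapping) -> dict:
    return {
        (entity, gender): (SUPPRESSED if value == SUPPRESSION_MARKER else int(value))
        for entity, genders in nested.items()
        for gender, value in genders.items()
    }


def _plain_to_marginals(plain: Mapping) -> dict:
    return {
        k: (SUPPRESSED if v == SUPPRESSION_MARKER else int(v)) for k, v in plain.items()
    }


def aggregate_to_dict(agg: SiteAggregate) -> dict:
    return {
        "site_id": agg.site_id,
        "total_cases": agg.total_cases,
        "cells": _cells_to_nested(agg.cells),
        "entity_marginals": _marginals_to_plain(agg.entity_marginals),
        "gender_marginals": _marginals_to_plain(agg.gender_marginals),
    }


def aggregate_from_dict(data: Mapping) -> SiteAggregate:
    return SiteAggregate(
        site_id=data["site_id"],
        total_cases=int(data["total_cases"]),
        cells=_nested_to_cells(data["cells"]),
        entity_marginals=_plain_to_marginals(data["entity_marginals"]),
        gender_marginals=_plain_to_marginals(data["gender_marginals"]),
    )


def result_to_dict(result: FederatedResult) -> dict:
    return {
        "policy": {
            "min_cell": result.policy.min_cell,
            "strict_zeros": result.policy.strict_zeros,
        },
        "combined_total": result.combined_total,
        "combined_cells": _cells_to_nested(result.combined_cells),
        "combined_entity_marginals": _marginals_to_plain(result.combined_entity_marginals),
        "combined_gender_marginals": _marginals_to_plain(result.combined_gender_marginals),
        "per_site": [aggregate_to_dict(a) for a in result.per_site],
    }


def result_from_dict(data: Mapping) -> FederatedResult:
    policy = DisclosurePolicy(
        min_cell=int(data["policy"]["min_cell"]),
        strict_zeros=bool(data["policy"]["strict_zeros"]),
    )
    return FederatedResult(
        per_site=[aggregate_from_dict(a) for a in data["per_site"]],
        combined_cells=_nested_to_cells(data["combined_cells"]),
        combined_entity_marginals=_plain_to_marginals(data["combined_entity_marginals"]),
        combined_gender_marginals=_plain_to_marginals(data["combined_gender_marginals"]),
        combined_total=int(data["combined_total"]),
        policy=policy,
    )


def assert_nondisclosive(data, min_cell: int, _path: str = "$") -> None:
    """Recursively verify that no serialized count lies in (0, min_cell).

    ``total_cases``/``combined_total`` keys are exempt: totals are
    pre-suppression by design and a total below min_cell would already be
    disclosive at the level of participation, which the policy does not
    model.
    """
    if isinstance(data, Mapping):
        for key, value in data.items():
            if key in ("total_cases", "combined_total", "min_cell"):
                continue
            assert_nondisclosive(value, min_cell, f"{_path}.{key}")
    elif isinstance(data, (list, tuple)):
        for i, value in enumerate(data):
            assert_nondisclosive(value, min_cell, f"{_path}[{i}]")
    elif isinstance(data, bool):
        return
    elif isinstance(data, int):
        if 0 < data < min_cell:
            raise DisclosureError(f"count {data} at {_path} is below min_cell={min_cell}")


def save_result(result: FederatedResult, path: str | Path) -> Path:
    payload = result_to_dict(result)
    assert_nondisclosive(payload, result.policy.min_cell)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def load_result(path: str | Path) -> FederatedResult:
    return result_from_dict(json.loads(Path(path).read_text()))


def save_aggregate(agg: SiteAggregate, policy: DisclosurePolicy, path: str | Path) -> Path:
    payload = aggregate_to_dict(agg)
    assert_nondisclosive(payload, policy.min_cell)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def load_aggregate(path: str | Path) -> SiteAggregate:
    return aggregate_from_dict(json.loads(Path(path).read_text()))
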