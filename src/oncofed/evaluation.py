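"""Validation metrics: entity-wise deviation, MAPE, and count-table comparison.

The pipeline's headline validity check compares the federated per-entity
counts (the *predicted* values, ŷᵢ) against the counts recorded in the
site's tumor documentation system (the *gold standard*, yᵢ):

    deviationᵢ = |ŷᵢ − yᵢ| / yᵢ

and the mean absolute percentage error (MAPE) is the unweighted arithmetic
mean of the deviations over all entities with a positive gold count.
Entities with a zero (or missing) gold count are excluded with a warning
rather than mapped to infinity, keeping the mean finite and auditable.

A second comparison contrasts two count tables' relative shares (e.g. a
federation's combined counts against a state registry's annual report),
each against its own total.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .federated import round_half_up
from .tabular import EntityGroupMap

log = logging.getLogger(__name__)


class ZeroGoldError(ValueError):
    """Deviation is undefined for a zero gold count; the entity is excluded."""


def entity_deviation(predicted: int | float, gold: int | float) -> float:
    """Absolute relative deviation |predicted − gold| / gold."""
    if gold <= 0:
        raise ZeroGoldError(f"gold count must be positive, got {gold}")
    return abs(predicted - gold) / gold


@dataclass(frozen=True)
class EntityDeviation:
    entity: str
    predicted: float
    gold: float
    deviation: float  # fraction, not percent


@dataclass(frozen=True)
class DeviationReport:
    deviations: tuple[EntityDeviation, ...]
    excluded: tuple[str, ...]  # entities with zero/missing gold

    @property
    def mape(self) -> float:
        """Unweighted mean deviation over included entities (fraction)."""
        if not self.deviations:
            return 0.0
        return sum(d.deviation for d in self.deviations) / len(self.deviations)

    @property
    def mape_percent(self) -> float:
        return 100.0 * self.mape

    def formatted_mape(self) -> str:
        """One decimal, except two decimals below 2% where precision matters."""
        pct = self.mape_percent
        return f"{round_half_up(pct, 2):.2f}%" if pct < 2.0 else f"{round_half_up(pct, 1):.1f}%"


def mape(
    predicted_table: Mapping[str, int],
    gold_table: Mapping[str, int],
    entities: Sequence[str] | EntityGroupMap | None = None,
) -> DeviationReport:
    """Entity-wise deviations and their mean between two count tables.

    ``entities`` fixes the evaluation universe (defaults to every entity in
    the gold table, sorted); an entity present only in the predicted table
    is treated as gold 0 and excluded with a warning.
    """
    if isinstance(entities, EntityGroupMap):
        universe: Sequence[str] = entities.labels
    elif entities is not None:
        universe = list(entities)
    else:
        universe = sorted(set(gold_table) | set(predicted_table))
    deviations = []
    excluded = []
    for entity in universe:
        gold = gold_table.get(entity, 0)
        predicted = predicted_table.get(entity, 0)
        if gold <= 0:
            excluded.append(entity)
            log.warning("mape: entity %r has zero gold count; excluded", entity)
            continue
        deviations.append(
            EntityDeviation(entity, predicted, gold, entity_deviation(predicted, gold))
        )
    return DeviationReport(tuple(deviations), tuple(excluded))


@dataclass(frozen=True)
class ComparisonRow:
    entity: str
    count_a: int
    share_a: float  # percent, one decimal
    count_b: int
    share_b: float
    difference: float  # share_a - share_b, percentage points


@dataclass(frozen=True)
class RegistryComparison:
    label_a: str
    label_b: str
    total_a: int
    total_b: int
    rows: tuple[ComparisonRow, ...]

    def row(self, entity: str) -> ComparisonRow:
        for r in self.rows:
            if r.entity == entity:
                return r
        raise KeyError(entity)


def compare_distributions(
    table_a: Mapping[str, int],
    table_b: Mapping[str, int],
    labels: tuple[str, str] = ("A", "B"),
) -> RegistryComparison:
    """Per-entity shares of each table against its own total, with differences.

    Rows are sorted by table A's share, largest first.
    """
    if not table_a or not table_b:
        raise ValueError("both tables must be nonempty")
    total_a = sum(table_a.values())
    total_b = sum(table_b.values())
    rows = []
    for entity in sorted(set(table_a) | set(table_b)):
        count_a = table_a.get(entity, 0)
        count_b = table_b.get(entity, 0)
        share_a = round_half_up(100.0 * count_a / total_a)
        share_b = round_half_up(100.0 * count_b / total_b)
        rows.append(
            ComparisonRow(
                entity, count_a, share_a, count_b, share_b,
                round_half_up(share_a - share_b),
            )
        )
    rows.sort(key=lambda r: (-r.share_a, r.entity))
    return RegistryComparison(labels[0], labels[1], total_a, total_b, tuple(rows))


# ---------------------------------------------------------------------------
# count-table I/O


def read_count_table(path: str | Path) -> dict[str, int]:
    """Read an ``entity_group,count`` CSV into an ordered dict."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["entity_group", "count"]:
            raise ValueError(f"expected header entity_group,count; got {header}")
        return {row[0]: int(row[1]) for row in reader if row}


def write_count_table(table: Mapping[str, int], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["entity_group", "count"])
        for entity, count in sorted(table.items()):
            writer.writerow([entity, count])
    return path


def load_bavarian_registry_2019() -> dict[str, int]:
    """The 2019 Bavarian Cancer Registry annual-report counts (total 63,771).

    The ten most frequent entities as printed in the report, with the
    remainder pooled under ``other``.
    """
    text = (
        importlib.resources.files("oncofed.data")
        .joinpath("bavarian_registry_2019.csv")
        .read_text()
    )
    rows = [line.split(",") for line in text.strip().splitlines()[1:]]
    return {entity: int(count) for entity, count in rows}


# ---------------------------------------------------------------------------
# report rendering


def deviation_report_to_dict(report: DeviationReport) -> dict:
    return {
        "mape_percent": report.mape_percent,
        "mape_formatted": report.formatted_mape(),
        "excluded": list(report.excluded),
        "entities": [
            {
                "entity": d.entity,
                "predicted": d.predicted,
                "gold": d.gold,
                "deviation_percent": 100.0 * d.deviation,
            }
            for d in report.deviations
        ],
    }


def deviation_report_to_markdown(report: DeviationReport, title: str = "Deviation report") -> str:
    lines = [f"# {title}", "", f"MAPE: **{report.formatted_mape()}**", ""]
    lines += ["| entity | predicted | gold | deviation |", "| --- | ---: | ---: | ---: |"]
    for d in report.deviations:
        lines.append(
            f"| {d.entity} | {d.predicted:g} | {d.gold:g} | {100 * d.deviation:.2f}% |"
        )
    if report.excluded:
        lines += ["", f"Excluded (zero gold count): {', '.join(report.excluded)}"]
    return "\n".join(lines) + "\n"


def comparison_to_markdown(cmp: RegistryComparison) -> str:
    lines = [
        f"# {cmp.label_a} vs {cmp.label_b}",
        "",
        f"Totals: {cmp.label_a} n={cmp.total_a:,}; {cmp.label_b} n={cmp.total_b:,}",
        "",
        f"| entity | {cmp.label_a} n | {cmp.label_a} % | {cmp.label_b} n | {cmp.label_b} % | diff (pp) |",
        "| --- | ---: | ---: | ---: | ---: | ---: |",
    ]
    for r in cmp.rows:
        lines.append(
            f"| {r.entity} | {r.count_a:,} | {r.share_a:.1f} | {r.count_b:,} "
            f"| {r.share_b:.1f} | {r.difference:+.1f} |"
        )
    return "\n".join(lines) + "\n"


def save_deviation_report(report: DeviationReport, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(deviation_report_to_dict(report), indent=2) + "\n")
    return path
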