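"""Folder-manifest orchestration of the pipeline stages.

Each stage reads the previous stage's folder, writes its own artifacts and a
JSON manifest (input/output hashes, config hash, in/out counts, rejections).
Manifests make re-runs idempotent — unchanged inputs produce identical
hashes — and let the whole run be reconciled: cases generated equals rows
flattened plus rejections plus year-filtered.

Stage layout under the run's working directory::

    stage0_obds/            one collection XML per site
    gold/gold_counts.csv    generated gold-standard entity counts
    rejected/               quarantined reports + reasons.csv
    stage1_decomposed/      one single-report XML per case
    stage2_fhir/<site>.ndjson
    stage3_pseudonymized/<site>.ndjson
    stage4_tables/<site>.csv
    stage5_aggregates/<site>.json
    stage6_results/federated.json, deviation.json, deviation.md
    reports/                Q1/Q2 CSVs and a Markdown summary
    manifests/<stage>.json
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import yaml

from . import deidentify, evaluation, federated, fhir_mapping, obds_io, synthetic_data, tabular

log = logging.getLogger(__name__)

STAGES = (
    "generate",
    "decompose",
    "to-fhir",
    "deidentify",
    "flatten",
    "aggregate",
    "combine",
    "evaluate",
    "report",
)

_UPSTREAM = {STAGES[i]: STAGES[i - 1] for i in range(1, len(STAGES))}


class PipelineError(RuntimeError):
    pass


class StageOrderError(PipelineError):
    """Upstream stage has not produced its manifest yet."""


@dataclass
class RunConfig:
    """One run's configuration; resolvable to concrete configs and folders."""

    workdir: Path
    federation_profile: str = "builtin:paper_federation"
    entity_map: str = "builtin"
    deident_rules: str = "builtin"
    pseudonym_secret: str = "oncofed-demo-secret"
    supported_versions: tuple[str, ...] = ("2.2.2",)
    year_filter: tuple[int, ...] = (2021, 2022)
    min_cell: int = 5
    seed: int = 1
    reference_date: str = "2026-01-01"

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)
        if not self.year_filter:
            raise PipelineError("year_filter must be nonempty")

    # -- resolution ---------------------------------------------------------

    def load_federation(self) -> synthetic_data.FederationProfile:
        if self.federation_profile == "builtin:paper_federation":
            return synthetic_data.paper_federation()
        path = Path(self.federation_profile)
        if not path.exists():
            raise PipelineError(f"federation profile not found: {path}")
        return synthetic_data.load_federation_profile(path)

    def load_entity_map(self) -> tabular.EntityGroupMap:
        if self.entity_map == "builtin":
            return tabular.EntityGroupMap.default()
        return tabular.EntityGroupMap.from_yaml(self.entity_map)

    def load_deident_config(self) -> deidentify.DeidentConfig:
        if self.deident_rules == "builtin":
            return deidentify.DeidentConfig.default()
        return deidentify.DeidentConfig.from_yaml(self.deident_rules)

    def provider(self) -> deidentify.HashingPseudonymProvider:
        return deidentify.HashingPseudonymProvider(self.pseudonym_secret)

    def policy(self) -> federated.DisclosurePolicy:
        return federated.DisclosurePolicy(min_cell=self.min_cell)

    def ref_date(self) -> dt.date:
        return dt.date.fromisoformat(self.reference_date)

    # -- folders ------------------------------------------------------------

    def folder(self, name: str) -> Path:
        path = self.workdir / name
        path.mkdir(parents=True, exist_ok=True)
        return path

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(self).items()
                if k != "pseudonym_secret"  # key material never enters manifests
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- YAML ---------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["workdir"] = Path(data["workdir"])
        for key in ("supported_versions", "year_filter"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        data = dataclasses.asdict(self)
        data["workdir"] = str(self.workdir)
        data["supported_versions"] = list(self.supported_versions)
        data["year_filter"] = list(self.year_filter)
        path = Path(path)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path


# ---------------------------------------------------------------------------
# manifests


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _hash_folder(folder: Path, patterns: tuple[str, ...] = ("*",)) -> dict[str, str]:
    hashes: dict[str, str] = {}
    for pattern in patterns:
        for path in sorted(folder.glob(pattern)):
            if path.is_file():
                hashes[path.name] = _hash_file(path)
    return hashes


def _write_manifest(
    config: RunConfig,
    stage: str,
    inputs: dict[str, str],
    outputs: dict[str, str],
    counts: dict[str, int],
) -> dict:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "inputs": inputs,
        "outputs": outputs,
        "counts": counts,
    }
    path = config.folder("manifests") / f"{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _require_upstream(config: RunConfig, stage: str) -> None:
    upstream = _UPSTREAM.get(stage)
    if upstream is None:
        return
    manifest = config.workdir / "manifests" / f"{upstream}.json"
    if not manifest.exists():
        raise StageOrderError(
            f"stage {stage!r} requires upstream stage {upstream!r}; "
            f"run `oncofed {upstream}` first (missing {manifest})"
        )


def read_manifest(config: RunConfig, stage: str) -> dict:
    return json.loads((config.workdir / "manifests" / f"{stage}.json").read_text())


# ---------------------------------------------------------------------------
# stages


def stage_generate(config: RunConfig) -> dict:
    federation = config.load_federation()
    entity_map = config.load_entity_map()
    out = config.folder("stage0_obds")
    collections = synthetic_data.generate_federation(
        federation, entity_map, out_dir=out, seed=config.seed
    )
    gold = synthetic_data.federation_entity_counts(collections.values(), entity_map)
    gold_path = config.folder("gold") / "gold_counts.csv"
    evaluation.write_count_table(gold, gold_path)
    return _write_manifest(
        config,
        "generate",
        inputs={"federation_profile": config.federation_profile},
        outputs={**_hash_folder(out), "gold/gold_counts.csv": _hash_file(gold_path)},
        counts={
            "sites": len(collections),
            "reports": sum(len(c.reports) for c in collections.values()),
        },
    )


def stage_decompose(config: RunConfig) -> dict:
    _require_upstream(config, "decompose")
    src = config.folder("stage0_obds")
    out = config.folder("stage1_decomposed")
    rejected_dir = config.folder("rejected")
    supported = obds_io.SupportedVersions(frozenset(config.supported_versions))
    n_in = n_out = 0
    rejections: list[tuple[str, str, str]] = []
    for path in obds_io.list_import_folder(src):
        result = obds_io.read_collection(path, reference_date=config.ref_date())
        check = obds_io.check_version(result.collection, supported)
        if not check.ok:
            raise PipelineError(f"{path.name}: {check.message}")
        for rejection in result.rejections:
            rejections.append((result.collection.site_id, rejection.report_id, rejection.code))
        n_in += len(result.collection.reports) + len(result.rejections)
        for report in obds_io.decompose_collection(result.collection):
            obds_io.write_single_report(report, out)
            n_out += 1
    if rejections:
        with open(rejected_dir / "reasons.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["site_id", "report_id", "code"])
            writer.writerows(rejections)
    return _write_manifest(
        config,
        "decompose",
        inputs=_hash_folder(src),
        outputs={"stage1_decomposed": _digest_of(_hash_folder(out))},
        counts={"reports_in": n_in, "reports_out": n_out, "rejected": len(rejections)},
    )


def _digest_of(hashes: dict[str, str]) -> str:
    return hashlib.sha256(json.dumps(hashes, sort_keys=True).encode()).hexdigest()[:16]


def stage_to_fhir(config: RunConfig) -> dict:
    _require_upstream(config, "to-fhir")
    src = config.folder("stage1_decomposed")
    out = config.folder("stage2_fhir")
    by_site: dict[str, list] = defaultdict(list)
    for path in obds_io.list_import_folder(src):
        report = obds_io.parse_single_report(path.read_bytes())
        by_site[report.site_id].append(fhir_mapping.map_report(report))
    for site_id, bundles in sorted(by_site.items()):
        fhir_mapping.write_bundles(bundles, out / f"{site_id}.ndjson")
    return _write_manifest(
        config,
        "to-fhir",
        inputs={"stage1_decomposed": _digest_of(_hash_folder(src))},
        outputs=_hash_folder(out),
        counts={"bundles": sum(len(b) for b in by_site.values())},
    )


def stage_deidentify(config: RunConfig) -> dict:
    _require_upstream(config, "deidentify")
    src = config.folder("stage2_fhir")
    out = config.folder("stage3_pseudonymized")
    deident_config = config.load_deident_config()
    provider = config.provider()
    n = 0
    for path in sorted(src.glob("*.ndjson")):
        bundles, rejections = fhir_mapping.read_bundles(path)
        if rejections:
            raise PipelineError(f"{path.name}: {len(rejections)} malformed line(s)")
        deidentified = deidentify.deidentify_bundles(bundles, deident_config, provider)
        fhir_mapping.write_bundles(deidentified, out / path.name)
        n += len(deidentified)
    return _write_manifest(
        config,
        "deidentify",
        inputs=_hash_folder(src),
        outputs=_hash_folder(out),
        counts={"bundles": n},
    )


def stage_flatten(config: RunConfig) -> dict:
    _require_upstream(config, "flatten")
    src = config.folder("stage3_pseudonymized")
    out = config.folder("stage4_tables")
    entity_map = config.load_entity_map()
    n_rows = n_filtered = 0
    for path in sorted(src.glob("*.ndjson")):
        bundles, rejections = fhir_mapping.read_bundles(path)
        if rejections:
            raise PipelineError(f"{path.name}: {len(rejections)} malformed line(s)")
        table = tabular.flatten(bundles, entity_map, config.year_filter)
        tabular.write_case_table(table, out / f"{table.site_id}.csv")
        n_rows += len(table.rows)
        n_filtered += table.provenance["year_filtered"]
    return _write_manifest(
        config,
        "flatten",
        inputs=_hash_folder(src),
        outputs=_hash_folder(out),
        counts={"rows": n_rows, "year_filtered": n_filtered},
    )


def stage_aggregate(config: RunConfig) -> dict:
    _require_upstream(config, "aggregate")
    src = config.folder("stage4_tables")
    out = config.folder("stage5_aggregates")
    policy = config.policy()
    total = 0
    for path in sorted(src.glob("*.csv")):
        table = tabular.read_case_table(path)
        aggregate = federated.aggregate_site(table, policy)
        federated.save_aggregate(aggregate, policy, out / f"{aggregate.site_id}.json")
        total += aggregate.total_cases
    return _write_manifest(
        config,
        "aggregate",
        inputs=_hash_folder(src),
        outputs=_hash_folder(out),
        counts={"total_cases": total},
    )


def stage_combine(config: RunConfig) -> dict:
    _require_upstream(config, "combine")
    src = config.folder("stage5_aggregates")
    out = config.folder("stage6_results")
    policy = config.policy()
    aggregates = [federated.load_aggregate(p) for p in sorted(src.glob("*.json"))]
    if not aggregates:
        raise PipelineError("combine: no site aggregates found")
    result = federated.combine(aggregates, policy)
    federated.save_result(result, out / "federated.json")
    return _write_manifest(
        config,
        "combine",
        inputs=_hash_folder(src),
        outputs=_hash_folder(out, ("federated.json",)),
        counts={"sites": len(aggregates), "combined_total": result.combined_total},
    )


def stage_evaluate(config: RunConfig, gold_path: str | Path | None = None) -> dict:
    _require_upstream(config, "evaluate")
    out = config.folder("stage6_results")
    result = federated.load_result(out / "federated.json")
    predicted = {
        entity: value
        for entity, value in result.combined_entity_marginals.items()
        if value is not federated.SUPPRESSED
    }
    gold_path = Path(gold_path) if gold_path else config.workdir / "gold" / "gold_counts.csv"
    if not gold_path.exists():
        raise PipelineError(f"gold-standard table not found: {gold_path}")
    gold = evaluation.read_count_table(gold_path)
    report = evaluation.mape(predicted, gold)
    evaluation.save_deviation_report(report, out / "deviation.json")
    (out / "deviation.md").write_text(
        evaluation.deviation_report_to_markdown(report, "Federated result vs gold standard")
    )
    return _write_manifest(
        config,
        "evaluate",
        inputs={"federated.json": _hash_file(out / "federated.json"),
                "gold": _hash_file(gold_path)},
        outputs=_hash_folder(out, ("deviation.*",)),
        counts={"entities": len(report.deviations), "excluded": len(report.excluded)},
    )


def stage_report(config: RunConfig) -> dict:
    _require_upstream(config, "report")
    results_dir = config.folder("stage6_results")
    out = config.folder("reports")
    result = federated.load_result(results_dir / "federated.json")

    with open(out / "q1_entity_shares.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scope", "entity", "share_percent"])
        for scope in ["combined"] + [a.site_id for a in result.per_site]:
            for entity, share in federated.entity_shares(result, scope):
                writer.writerow([scope, entity, share])

    with open(out / "q2_gender_shares.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["estimator", "entity", "gender", "share_percent"])
        for estimator in ("mean_of_sites", "pooled"):
            for entity, genders in federated.gender_shares(result, estimator).items():
                for gender, share in genders.items():
                    writer.writerow([estimator, entity, gender, share])

    lines = [
        "# Federated analysis summary",
        "",
        f"Combined total: **{result.combined_total:,} cases** across "
        f"{len(result.per_site)} sites (min_cell={result.policy.min_cell}).",
        "",
        "## Q1 — entity distribution (combined)",
        "",
        "| entity | share |",
        "| --- | ---: |",
    ]
    for entity, share in federated.entity_shares(result, "combined"):
        lines.append(f"| {entity} | {share:.1f}% |")
    suppressed = federated.suppressed_entities(result, "combined")
    if suppressed:
        lines += ["", f"Suppressed entities: {', '.join(suppressed)}"]
    lines += ["", "## Q2 — gender distribution per entity (mean of sites)", ""]
    lines += ["| entity | " + " | ".join(("female", "male", "other", "unknown")) + " |",
              "| --- | ---: | ---: | ---: | ---: |"]
    for entity, genders in federated.gender_shares(result, "mean_of_sites").items():
        cells = " | ".join(
            f"{genders[g]:.1f}%" if g in genders else "—"
            for g in ("female", "male", "other", "unknown")
        )
        lines.append(f"| {entity} | {cells} |")
    (out / "summary.md").write_text("\n".join(lines) + "\n")

    return _write_manifest(
        config,
        "report",
        inputs={"federated.json": _hash_file(results_dir / "federated.json")},
        outputs=_hash_folder(out),
        counts={},
    )


_STAGE_FUNCTIONS: dict[str, Callable[[RunConfig], dict]] = {
    "generate": stage_generate,
    "decompose": stage_decompose,
    "to-fhir": stage_to_fhir,
    "deidentify": stage_deidentify,
    "flatten": stage_flatten,
    "aggregate": stage_aggregate,
    "combine": stage_combine,
    "evaluate": stage_evaluate,
    "report": stage_report,
}


def run_stage(name: str, config: RunConfig) -> dict:
    if name not in _STAGE_FUNCTIONS:
        raise PipelineError(f"unknown stage {name!r}; stages: {', '.join(STAGES)}")
    log.info("running stage %s in %s", name, config.workdir)
    return _STAGE_FUNCTIONS[name](config)


def run_all(config: RunConfig) -> dict[str, dict]:
    return {name: run_stage(name, config) for name in STAGES}


def load_federated_result(config: RunConfig) -> federated.FederatedResult:
    return federated.load_result(config.workdir / "stage6_results" / "federated.json")
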