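"""Synthetic-export generator: exact and multinomial count structure."""

from collections import Counter

import numpy as np
import pytest

from oncofed.obds_io import collection_to_xml
from oncofed.synthetic_data import (
    FederationProfile,
    ProfileError,
    SiteProfile,
    collection_entity_counts,
    federation_entity_counts,
    generate_federation,
    generate_site,
    paper_federation,
    perturb_gold,
)


def _profile(cells, site_id="s1", mode="exact", total=None, seed=7, year=2022):
    return SiteProfile(
        site_id=site_id,
        year=year,
        cell_counts=tuple(sorted(cells.items())),
        mode=mode,
        total=total,
        seed=seed,
    )


MELANOMA_CELLS = {("melanoma", "M"): 2, ("melanoma", "W"): 1}


class TestExactMode:
    def test_reproduces_cell_counts_exactly(self, entity_map):
        collection = generate_site(_profile(MELANOMA_CELLS), entity_map)
        assert len(collection.reports) == 3
        assert all(r.icd10_code.startswith("C43") for r in collection.reports)
        assert Counter(r.gender for r in collection.reports) == {"M": 2, "W": 1}

    def test_dates_fall_in_profile_year(self, entity_map):
        collection = generate_site(_profile(MELANOMA_CELLS, year=2021), entity_map)
        assert {r.diagnosis_date.year for r in collection.reports} == {2021}

    def test_patient_ids_unique_and_quasi_identifiers_present(self, entity_map):
        collection = generate_site(_profile({("breast", "W"): 20}), entity_map)
        pids = [r.patient_id for r in collection.reports]
        assert len(set(pids)) == len(pids)
        assert all(r.quasi_identifier for r in collection.reports)

    def test_seeded_generation_is_byte_identical(self, entity_map):
        a = generate_site(_profile(MELANOMA_CELLS), entity_map)
        b = generate_site(_profile(MELANOMA_CELLS), entity_map)
        assert collection_to_xml(a) == collection_to_xml(b)

    def test_different_seed_changes_internals_not_counts(self, entity_map):
        a = generate_site(_profile(MELANOMA_CELLS, seed=1), entity_map)
        b = generate_site(_profile(MELANOMA_CELLS, seed=2), entity_map)
        assert collection_entity_counts(a, entity_map) == collection_entity_counts(
            b, entity_map
        )

    @pytest.mark.parametrize(
        "cells, match",
        [
            ({("not_a_group", "M"): 3}, "unknown entity"),
            ({("melanoma", "M"): 0}, "at least one case"),
        ],
    )
    def test_config_errors(self, entity_map, cells, match):
        with pytest.raises(ProfileError, match=match):
            generate_site(_profile(cells), entity_map)


class TestMultinomialMode:
    def test_total_is_exact_and_cells_near_expectation(self, entity_map):
        """Per-cell counts stay within 3 standard errors of n*p over 100 seeds."""
        cells = {("melanoma", "M"): 3, ("breast", "W"): 5, ("lung", "M"): 2}
        n, n_seeds = 1000, 100
        weights = np.array([v for _, v in sorted(cells.items())], dtype=float)
        p = weights / weights.sum()
        sums = np.zeros(len(p))
        for seed in range(n_seeds):
            profile = _profile(cells, mode="multinomial", total=n, seed=seed)
            collection = generate_site(profile, entity_map)
            assert len(collection.reports) == n
            observed = Counter(
                (entity_map.assign(r.icd10_code), r.gender) for r in collection.reports
            )
            sums += [observed.get(k, 0) for k in sorted(cells)]
        mean = sums / n_seeds
        sd = np.sqrt(n * p * (1 - p))  # binomial sampling error per cell
        assert np.all(np.abs(mean - n * p) <= 3 * sd / np.sqrt(n_seeds))

    def test_requires_positive_total(self):
        with pytest.raises(ProfileError, match="positive total"):
            _profile(MELANOMA_CELLS, mode="multinomial", total=None)


class TestFederation:
    def test_one_file_per_site(self, entity_map, tmp_path):
        sites = tuple(
            _profile(MELANOMA_CELLS, site_id=f"s{i}", seed=i) for i in range(6)
        )
        fed = FederationProfile("six", sites)
        collections = generate_federation(fed, entity_map, out_dir=tmp_path)
        assert len(collections) == 6
        assert len(list(tmp_path.glob("*.xml"))) == 6

    def test_empty_federation_warns_and_writes_nothing(self, entity_map, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            collections = generate_federation(
                FederationProfile("empty", ()), entity_map, out_dir=tmp_path
            )
        assert collections == {}
        assert list(tmp_path.glob("*.xml")) == []
        assert any("empty" in r.message for r in caplog.records)

    def test_duplicate_site_ids_rejected(self):
        with pytest.raises(ProfileError, match="duplicate"):
            FederationProfile("dup", (_profile(MELANOMA_CELLS), _profile(MELANOMA_CELLS)))

    def test_site_errors_carry_site_context(self, entity_map):
        bad = _profile({("nope", "M"): 1}, site_id="siteX")
        with pytest.raises(ProfileError, match="siteX"):
            generate_federation(FederationProfile("f", (bad,)), entity_map)


class TestPaperFederation:
    def test_packaged_profile_structure(self, entity_map):
        fed = paper_federation()
        assert len(fed.sites) == 6
        total = sum(sum(p.cells.values()) for p in fed.sites)
        assert total == 17885
        site5 = fed.site("site5")
        assert sum(site5.cells.values()) == 2045
        melanoma = sum(v for (e, _), v in site5.cell_counts if e == "melanoma")
        assert melanoma == 500

    def test_generated_totals_conserve_profile_totals(self, entity_map):
        fed = paper_federation()
        collections = generate_federation(fed, entity_map, seed=3)
        counts = federation_entity_counts(collections.values(), entity_map)
        assert sum(counts.values()) == 17885
        assert counts["prostate"] == 2476
        assert counts["melanoma"] == 1921


class TestPerturbGold:
    @pytest.fixture()
    def collection(self, entity_map):
        return generate_site(
            _profile({("melanoma", "M"): 10, ("breast", "W"): 15}), entity_map
        )

    def test_zero_perturbation_equals_pipeline_counts(self, collection, entity_map):
        _, gold = perturb_gold(collection, 0, seed=5, entity_map=entity_map)
        assert gold == collection_entity_counts(collection, entity_map)

    def test_injection_is_one_sided(self, collection, entity_map):
        pipeline_counts = collection_entity_counts(collection, entity_map)
        _, gold = perturb_gold(collection, 25, seed=5, entity_map=entity_map)
        assert all(gold[e] >= pipeline_counts.get(e, 0) for e in gold)

    @pytest.mark.parametrize("add_late", [0, 1, 7, 40])
    def test_total_conservation(self, collection, entity_map, add_late):
        _, gold = perturb_gold(collection, add_late, seed=5, entity_map=entity_map)
        assert sum(gold.values()) - len(collection.reports) == add_late

    def test_collection_itself_is_unmodified(self, collection, entity_map):
        returned, _ = perturb_gold(collection, 9, seed=5, entity_map=entity_map)
        assert returned is collection

    def test_negative_add_late_rejected(self, collection, entity_map):
        with pytest.raises(ValueError):
            perturb_gold(collection, -1, seed=5, entity_map=entity_map)
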