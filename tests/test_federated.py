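"""Disclosure-controlled aggregation, combination and the Q1/Q2 estimators."""

from collections import Counter

import numpy as np
import pytest

from oncofed.federated import (
    SUPPRESSED,
    DisclosureError,
    DisclosurePolicy,
    aggregate_from_dict,
    aggregate_site,
    aggregate_to_dict,
    assert_nondisclosive,
    combine,
    entity_shares,
    gender_shares,
    load_result,
    result_from_dict,
    result_to_dict,
    round_half_up,
    save_result,
    suppressed_entities,
)
from oncofed.tabular import CaseRow, CaseTable

from conftest import make_random_table


def _table(cells: dict, site_id="s1") -> CaseTable:
    rows = []
    i = 0
    for (entity, gender), n in cells.items():
        for _ in range(n):
            rows.append(
                CaseRow(f"tok{site_id}{i:05d}", gender, "C50", 2022, entity, site_id)
            )
            i += 1
    return CaseTable(rows=tuple(rows), site_id=site_id)


class TestAggregateSite:
    def test_threshold_semantics(self):
        agg = aggregate_site(
            _table({("melanoma", "male"): 7, ("melanoma", "female"): 3}),
            DisclosurePolicy(min_cell=5),
        )
        assert agg.cells[("melanoma", "male")] == 7
        assert agg.cells[("melanoma", "female")] is SUPPRESSED
        assert agg.entity_marginals["melanoma"] == 10
        assert agg.total_cases == 10

    def test_min_cell_one_never_suppresses(self):
        agg = aggregate_site(
            _table({("melanoma", "male"): 1, ("breast", "female"): 2}),
            DisclosurePolicy(min_cell=1),
        )
        assert SUPPRESSED not in agg.cells.values()
        assert SUPPRESSED not in agg.entity_marginals.values()

    @pytest.mark.parametrize("seed", range(5))
    def test_total_equals_row_count(self, seed):
        table = make_random_table(np.random.default_rng(seed), "s1", 57)
        agg = aggregate_site(table, DisclosurePolicy(min_cell=5))
        assert agg.total_cases == len(table.rows)

    def test_mixed_site_table_rejected(self):
        # a mixed table can't be built through CaseTable; fake one
        class Mixed:
            site_id = "s1"
            rows = (
                CaseRow("a", "male", "C50", 2022, "breast", "s1"),
                CaseRow("b", "male", "C50", 2022, "breast", "s2"),
            )

        with pytest.raises(ValueError, match="mixed"):
            aggregate_site(Mixed(), DisclosurePolicy())


class TestCombine:
    def test_published_split_recombines(self):
        """Melanoma 500 + 1421 over totals 2045 + 15,840 -> 1921 of 17,885."""
        policy = DisclosurePolicy(min_cell=5)
        a = aggregate_site(
            _table({("melanoma", "male"): 500, ("other", "male"): 1545}, "site5"), policy
        )
        b = aggregate_site(
            _table({("melanoma", "male"): 1421, ("other", "male"): 14419}, "rest"), policy
        )
        result = combine([a, b], policy)
        assert result.combined_total == 17885
        assert result.combined_entity_marginals["melanoma"] == 1921
        assert dict(entity_shares(result, "combined"))["melanoma"] == 10.7
        assert dict(entity_shares(result, "site5"))["melanoma"] == 24.4

    def test_single_site_identity(self):
        policy = DisclosurePolicy(min_cell=5)
        agg = aggregate_site(_table({("breast", "female"): 20}), policy)
        result = combine([agg], policy)
        assert result.combined_cells == agg.cells
        assert result.combined_total == agg.total_cases

    @pytest.mark.parametrize("seed", range(5))
    def test_commutativity(self, seed):
        policy = DisclosurePolicy(min_cell=5)
        rng = np.random.default_rng(seed)
        aggs = [
            aggregate_site(make_random_table(rng, f"s{i}", int(rng.integers(10, 80))), policy)
            for i in range(3)
        ]
        forward = combine(aggs, policy)
        backward = combine(list(reversed(aggs)), policy)
        assert forward.combined_cells == backward.combined_cells
        assert forward.combined_total == backward.combined_total

    def test_suppressed_site_cell_poisons_combined_cell(self):
        policy = DisclosurePolicy(min_cell=5)
        a = aggregate_site(_table({("melanoma", "male"): 3, ("breast", "female"): 9}, "s1"), policy)
        b = aggregate_site(_table({("melanoma", "male"): 50}, "s2"), policy)
        result = combine([a, b], policy)
        assert result.combined_cells[("melanoma", "male")] is SUPPRESSED
        assert result.combined_cells[("breast", "female")] == 9

    def test_true_zero_does_not_poison(self):
        policy = DisclosurePolicy(min_cell=5)
        a = aggregate_site(_table({("breast", "female"): 9}, "s1"), policy)
        b = aggregate_site(_table({("lung", "male"): 7}, "s2"), policy)
        result = combine([a, b], policy)
        assert result.combined_cells[("breast", "female")] == 9
        assert result.combined_cells[("lung", "male")] == 7

    def test_duplicate_sites_and_empty_list_rejected(self):
        policy = DisclosurePolicy()
        agg = aggregate_site(_table({("breast", "female"): 9}), policy)
        with pytest.raises(ValueError, match="duplicate"):
            combine([agg, agg], policy)
        with pytest.raises(ValueError, match="at least one"):
            combine([], policy)


class TestShares:
    def test_single_entity_is_hundred_percent(self):
        policy = DisclosurePolicy(min_cell=5)
        result = combine([aggregate_site(_table({("breast", "female"): 30}), policy)], policy)
        assert entity_shares(result, "combined") == [("breast", 100.0)]

    def test_prostate_share_of_combined_fixture_total(self):
        policy = DisclosurePolicy(min_cell=5)
        agg = aggregate_site(
            _table({("prostate", "male"): 2476, ("other", "female"): 15409}), policy
        )
        result = combine([agg], policy)
        assert dict(entity_shares(result, "combined"))["prostate"] == 13.8

    def test_suppressed_marginals_reported_not_shared(self):
        policy = DisclosurePolicy(min_cell=5)
        agg = aggregate_site(
            _table({("breast", "female"): 30, ("larynx", "male"): 2}), policy
        )
        result = combine([agg], policy)
        assert suppressed_entities(result, "combined") == ["larynx"]
        shares = dict(entity_shares(result, "combined"))
        assert "larynx" not in shares
        # reported shares sum to < 100%; the gap is the suppressed share
        assert sum(shares.values()) < 100.0

    def test_gender_shares_single_site_both_estimators(self):
        policy = DisclosurePolicy(min_cell=5)
        agg = aggregate_site(
            _table({("lung", "male"): 80, ("lung", "female"): 20}), policy
        )
        result = combine([agg], policy)
        for estimator in ("pooled", "mean_of_sites"):
            shares = gender_shares(result, estimator)["lung"]
            assert shares == {"male": 80.0, "female": 20.0}

    def test_mean_of_sites_is_unweighted(self):
        policy = DisclosurePolicy(min_cell=5)
        a = aggregate_site(
            _table({("lung", "male"): 60, ("lung", "female"): 40}, "s1"), policy
        )
        b = aggregate_site(
            _table({("lung", "male"): 800, ("lung", "female"): 200}, "s2"), policy
        )
        result = combine([a, b], policy)
        assert gender_shares(result, "mean_of_sites")["lung"] == {
            "male": 70.0,
            "female": 30.0,
        }
        # pooled weighs by size instead
        pooled = gender_shares(result, "pooled")["lung"]
        assert pooled == {"male": round_half_up(100 * 860 / 1100), "female": round_half_up(100 * 240 / 1100)}

    @pytest.mark.parametrize("seed", range(5))
    def test_pooled_equals_centralized_recount(self, seed):
        rng = np.random.default_rng(seed)
        policy = DisclosurePolicy(min_cell=1)  # no suppression: exact oracle
        tables = [make_random_table(rng, f"s{i}", int(rng.integers(20, 60))) for i in range(4)]
        result = combine([aggregate_site(t, policy) for t in tables], policy)
        all_rows = [row for t in tables for row in t.rows]
        recount = Counter((r.entity_group, r.gender) for r in all_rows)
        for entity, genders in gender_shares(result, "pooled").items():
            denom = sum(v for (e, _), v in recount.items() if e == entity)
            for gender, pct in genders.items():
                assert pct == round_half_up(100.0 * recount[(entity, gender)] / denom)

    def test_unknown_estimator_rejected(self):
        policy = DisclosurePolicy()
        result = combine([aggregate_site(_table({("breast", "female"): 9}), policy)], policy)
        with pytest.raises(ValueError, match="estimator"):
            gender_shares(result, "median")


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(24.4499, 24.4), (24.45, 24.5), (13.85, 13.9), (0.05, 0.1), (10.74, 10.7)],
    )
    def test_half_up_one_decimal(self, value, expected):
        assert round_half_up(value) == expected


class TestSerialization:
    def test_result_json_round_trip(self, tmp_path):
        policy = DisclosurePolicy(min_cell=5)
        aggs = [
            aggregate_site(make_random_table(np.random.default_rng(i), f"s{i}", 40), policy)
            for i in range(3)
        ]
        result = combine(aggs, policy)
        path = save_result(result, tmp_path / "r.json")
        loaded = load_result(path)
        assert loaded.combined_cells == result.combined_cells
        assert loaded.combined_total == result.combined_total
        assert [a.site_id for a in loaded.per_site] == [a.site_id for a in result.per_site]

    def test_aggregate_dict_round_trip(self):
        policy = DisclosurePolicy(min_cell=5)
        agg = aggregate_site(
            _table({("melanoma", "male"): 7, ("melanoma", "female"): 3}), policy
        )
        back = aggregate_from_dict(aggregate_to_dict(agg))
        assert back.cells == agg.cells
        assert back.entity_marginals == agg.entity_marginals

    def test_nondisclosive_guard_catches_planted_small_count(self):
        with pytest.raises(DisclosureError, match="below min_cell"):
            assert_nondisclosive({"cells": {"breast": {"female": 3}}}, min_cell=5)

    def test_totals_are_exempt_from_the_guard(self):
        assert_nondisclosive({"total_cases": 3, "combined_total": 2}, min_cell=5)
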