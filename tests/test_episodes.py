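"""Episode collapsing, deduplication, severity hierarchy, scope and labels."""

import itertools
from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from lynchledger.episodes import (
    EPISODE_WINDOW_DAYS,
    collapse_episodes,
    deduplicate,
    gene_combination,
    most_significant_result,
)
from lynchledger.harmonise import CdmRecord

D0 = date(2010, 1, 1)


def rec(day_offset: int = 0, gene: str = "MLH1", scope: str = "full_gene",
        derived: bool = False, **kw) -> CdmRecord:
    defaults = dict(
        pseudo_id1="a" * 32, pseudo_id2="b" * 32, lab_code="LX",
        authorised_date=D0 + timedelta(days=day_offset),
        scope=scope, scope_derived=derived, gene=gene, result_label="negative")
    defaults.update(kw)
    return CdmRecord(**defaults)


def oracle_partition(offsets: list[int]) -> list[list[int]]:
    """Independent characterisation of anchored-window collapsing.

    Enumerate every contiguous partition of the sorted dates and keep the
    one where each block spans <= 365 days AND cannot absorb the next
    date (maximality).  Exactly one partition satisfies both, and it is
    the greedy-anchor answer.
    """
    days = sorted(offsets)
    n = len(days)
    valid = []
    for cuts in itertools.chain.from_iterable(
            itertools.combinations(range(1, n), k) for k in range(n)):
        bounds = [0, *cuts, n]
        blocks = [days[a:b] for a, b in zip(bounds, bounds[1:])]
        ok = True
        for i, block in enumerate(blocks):
            if block[-1] - block[0] > EPISODE_WINDOW_DAYS:
                ok = False
                break
            nxt = blocks[i + 1][0] if i + 1 < len(blocks) else None
            if nxt is not None and nxt - block[0] <= EPISODE_WINDOW_DAYS:
                ok = False
                break
        if ok:
            valid.append(blocks)
    assert len(valid) == 1, "anchored-window partition must be unique"
    return valid[0]


class TestCollapse:
    def test_within_window_single_episode(self):
        eps = collapse_episodes([rec(0), rec(300, gene="MSH2")])
        assert len(eps) == 1 and eps[0].episode_date == D0

    def test_beyond_window_two_episodes(self):
        eps = collapse_episodes([rec(0), rec(366)])
        assert [e.episode_date for e in eps] == [D0, D0 + timedelta(days=366)]

    def test_anchored_not_rolling(self):
        # d+400 is within 365 of d+300 but not of the anchor d
        eps = collapse_episodes([rec(0), rec(300), rec(400)])
        assert [len(e.member_records) for e in eps] == [2, 1]
        assert eps[1].episode_date == D0 + timedelta(days=400)

    def test_boundary_day_inclusive(self):
        assert len(collapse_episodes([rec(0), rec(365)])) == 1
        assert len(collapse_episodes([rec(0), rec(366)])) == 2

    def test_mixed_patients_rejected(self):
        with pytest.raises(ValueError):
            collapse_episodes([rec(0), rec(1, pseudo_id1="c" * 32)])

    def test_empty(self):
        assert collapse_episodes([]) == []

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=5))
    @settings(max_examples=400, deadline=None)
    def test_matches_partition_oracle(self, offsets):
        eps = collapse_episodes([rec(o) for o in offsets])
        got = [sorted((r.authorised_date - D0).days for r in e.member_records)
               for e in eps]
        assert got == oracle_partition(offsets)

    def test_idempotent_structure(self):
        eps = collapse_episodes([rec(0), rec(100), rec(500), rec(900)])
        again = collapse_episodes(
            [r for e in eps for r in e.member_records])
        assert [e.episode_date for e in again] == [e.episode_date for e in eps]
        assert [len(e.member_records) for e in again] == \
            [len(e.member_records) for e in eps]

    def test_partition_conserves_records(self):
        records = [rec(o, gene=g) for o in (0, 100, 400, 800)
                   for g in ("MLH1", "MSH2")]
        eps = collapse_episodes(records)
        assert sum(len(e.member_records) for e in eps) == len(records)


class TestDeduplicate:
    def test_identical_rows_reduced(self):
        assert len(deduplicate([rec(0), rec(0)])) == 1

    def test_different_variants_kept(self):
        a = rec(0, result_label="positive", variant_cdna="c.100A>G")
        b = rec(0, result_label="positive", variant_cdna="c.200A>G")
        assert len(deduplicate([a, b])) == 2

    def test_empty(self):
        assert deduplicate([]) == []


class TestMostSignificant:
    ORDER = ["P", "LP", "VUS", "abnormal_unclassified", "normal"]

    def test_all_subsets_match_order_oracle(self):
        for k in range(1, 6):
            for subset in itertools.combinations(self.ORDER, k):
                expected = min(subset, key=self.ORDER.index)
                assert most_significant_result(subset) == expected

    def test_paper_hierarchy_examples(self):
        assert most_significant_result({"P", "VUS"}) == "P"
        assert most_significant_result(["normal", "normal"]) == "normal"
        assert most_significant_result(["abnormal_unclassified", "LB"]) == \
            "abnormal_unclassified"

    def test_benign_ranks_as_normal(self):
        assert most_significant_result(["B", "LB"]) == "normal"

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            most_significant_result([])

    def test_adding_members_never_lowers(self):
        for base in self.ORDER:
            for extra in self.ORDER:
                combined = most_significant_result([base, extra])
                assert self.ORDER.index(combined) <= self.ORDER.index(base)


class TestScopeAndCombination:
    def test_mapped_scope_wins(self):
        eps = collapse_episodes([rec(0, scope="targeted", derived=False)])
        assert eps[0].scope == "targeted" and not eps[0].scope_derived

    def test_multigene_derived_full_gene(self):
        records = [rec(0, gene=g, scope="targeted", derived=True)
                   for g in ("MLH1", "MSH2", "MSH6", "PMS2")]
        eps = collapse_episodes(records)
        assert eps[0].scope == "full_gene" and eps[0].scope_derived

    def test_ambiguous_single_gene_flagged(self):
        eps = collapse_episodes([rec(0, scope="full_gene", derived=True)])
        assert eps[0].scope == "full_gene" and eps[0].scope_derived

    def test_gene_combination_canonical_order(self):
        eps = collapse_episodes([rec(0, gene="MSH2"), rec(1, gene="MLH1")])
        assert gene_combination(eps[0]) == "MLH1+MSH2"

    def test_gene_combination_all_four(self):
        records = [rec(0, gene=g) for g in ("PMS2", "MSH6", "MSH2", "MLH1")]
        assert gene_combination(collapse_episodes(records)[0]) == \
            "MLH1+MSH2+MSH6+PMS2"

    def test_gene_combination_targeted_rejected(self):
        eps = collapse_episodes([rec(0, scope="targeted")])
        with pytest.raises(ValueError):
            gene_combination(eps[0])

    def test_episode_severity_aggregation(self):
        records = [
            rec(0, gene="MLH1", result_label="positive",
                variant_cdna="c.100A>G", classification="VUS"),
            rec(10, gene="MSH2", result_label="positive",
                variant_cdna="c.200A>G", classification="P"),
            rec(20, gene="MSH6"),
        ]
        eps = collapse_episodes(records)
        assert eps[0].most_significant == "P"
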