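"""Naive-LCA read classification: hit filtering, assignment, min-support."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kefirmeta.classify import (
    PRESETS,
    UNASSIGNED,
    AlignmentHit,
    LcaParams,
    apply_min_support,
    assign_read,
    filter_hits,
    summarize_assignments,
)

from conftest import brute_force_lca, make_random_tree


def make_hit(read="r1", subject="s", taxon="t", bitscore=120.0, evalue=1e-10,
             identity=99.0, align_length=200, query_length=200):
    return AlignmentHit(
        read_id=read,
        subject_id=subject,
        subject_taxon=taxon,
        percent_identity=identity,
        align_length=align_length,
        query_length=query_length,
        bitscore=bitscore,
        evalue=evalue,
    )


PARAMS = LcaParams(min_score=100.0, max_expected=0.01, top_percent=10.0, min_support=0)


class TestFilterHits:
    def test_floor_then_top_percent_window(self):
        hits = [make_hit(subject=f"s{i}", bitscore=b) for i, b in enumerate([120, 110, 105, 99])]
        kept = filter_hits(hits, PARAMS)
        assert [h.bitscore for h in kept] == [120, 110]

    def test_all_below_min_score_gives_empty(self):
        hits = [make_hit(bitscore=b) for b in (50, 80, 99.9)]
        assert filter_hits(hits, PARAMS) == []

    def test_evalue_ceiling_applies(self):
        hits = [make_hit(bitscore=120, evalue=0.5), make_hit(bitscore=110)]
        kept = filter_hits(hits, PARAMS)
        assert [h.bitscore for h in kept] == [110]

    def test_boundary_tie_is_retained(self):
        # cutoff = 0.9 * 200 = 180 exactly
        hits = [make_hit(bitscore=200), make_hit(bitscore=180), make_hit(bitscore=179)]
        kept = filter_hits(hits, PARAMS)
        assert [h.bitscore for h in kept] == [200, 180]

    def test_matches_brute_force_two_pass_filter(self, rng):
        for _ in range(200):
            hits = [
                make_hit(subject=f"s{i}", bitscore=float(rng.uniform(50, 300)),
                         evalue=float(10 ** rng.uniform(-30, 1)))
                for i in range(int(rng.integers(0, 12)))
            ]
            kept = filter_hits(hits, PARAMS)
            floor = [h for h in hits
                     if h.bitscore >= PARAMS.min_score and h.evalue <= PARAMS.max_expected]
            if floor:
                best = max(h.bitscore for h in floor)
                expect = [h for h in floor
                          if h.bitscore >= (1 - PARAMS.top_percent / 100) * best]
            else:
                expect = []
            assert kept == expect

    def test_idempotent(self, rng):
        hits = [make_hit(subject=f"s{i}", bitscore=float(rng.uniform(80, 200)))
                for i in range(8)]
        once = filter_hits(hits, PARAMS)
        assert filter_hits(once, PARAMS) == once

    @given(
        scores=st.lists(st.floats(50, 300), max_size=10),
        raise_floor=st.floats(0, 50),
        tighten_e=st.floats(1, 1e6),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_tightening_floors_never_grows_retained_set(self, scores, raise_floor, tighten_e):
        hits = [make_hit(subject=f"s{i}", bitscore=b) for i, b in enumerate(scores)]
        loose = {h.subject_id for h in filter_hits(hits, PARAMS)}
        strict_params = LcaParams(
            min_score=PARAMS.min_score + raise_floor,
            max_expected=PARAMS.max_expected / tighten_e,
            top_percent=PARAMS.top_percent,
            min_support=0,
        )
        strict = {h.subject_id for h in filter_hits(hits, strict_params)}
        assert strict <= loose


class TestAssignRead:
    def test_single_retained_hit_gives_its_taxon(self, simple_tree):
        a = assign_read([make_hit(taxon="spA1")], simple_tree, PARAMS)
        assert a.taxon == "spA1"

    def test_sibling_species_give_their_genus(self, simple_tree):
        hits = [make_hit(subject="x", taxon="spA1"), make_hit(subject="y", taxon="spA2")]
        assert assign_read(hits, simple_tree, PARAMS).taxon == "genA"

    def test_no_surviving_hit_gives_unassigned(self, simple_tree):
        a = assign_read([make_hit(taxon="spA1", bitscore=10)], simple_tree, PARAMS)
        assert a.taxon == UNASSIGNED

    def test_mixed_reads_rejected(self, simple_tree):
        hits = [make_hit(read="r1"), make_hit(read="r2")]
        with pytest.raises(ValueError):
            assign_read(hits, simple_tree, PARAMS)

    def test_agrees_with_lca_over_filtered_taxa_on_random_inputs(self, rng):
        for _ in range(100):
            tree = make_random_tree(rng, int(rng.integers(5, 60)))
            ids = tree.taxon_ids()
            hits = [
                make_hit(subject=f"s{i}", taxon=ids[int(rng.integers(0, len(ids)))],
                         bitscore=float(rng.uniform(50, 250)))
                for i in range(int(rng.integers(1, 8)))
            ]
            got = assign_read(hits, tree, PARAMS).taxon
            retained = filter_hits(hits, PARAMS)
            if not retained:
                assert got == UNASSIGNED
            else:
                assert got == brute_force_lca(tree, {h.subject_taxon for h in retained})

    def test_preset_b_limit_equals_plain_lca_over_floor_survivors(self, simple_tree):
        # top_percent=100, min_support=0: every hit passing the floors counts.
        params = LcaParams(min_score=80.0, max_expected=0.01, top_percent=100.0, min_support=0)
        hits = [
            make_hit(subject="x", taxon="spA1", bitscore=250),
            make_hit(subject="y", taxon="spB1", bitscore=81),
        ]
        assert assign_read(hits, simple_tree, params).taxon == "fam"

    def test_weighted_lca_percent_rejected(self):
        with pytest.raises(NotImplementedError):
            LcaParams(min_score=100, max_expected=0.01, top_percent=10, min_support=0,
                      lca_percent=80.0)


class TestMinSupport:
    def test_weak_genus_pushes_to_supported_family(self, simple_tree):
        # 149 reads at genus A, 451 at its sibling genus B: family clade total
        # 600 once A's reads arrive, so A's reads surface at the family.
        assignments = {f"a{i}": "genA" for i in range(149)}
        assignments.update({f"b{i}": "genB" for i in range(451)})
        out = apply_min_support(assignments, simple_tree, 150)
        counts = Counter(out.values())
        assert counts["genB"] == 451
        assert counts["fam"] == 149
        assert UNASSIGNED not in counts

    def test_all_above_threshold_is_identity(self, simple_tree):
        assignments = {f"r{i}": "spA1" for i in range(200)}
        assert apply_min_support(assignments, simple_tree, 150) == assignments

    def test_insufficient_total_becomes_unassigned(self, simple_tree):
        assignments = {"r0": "spA1", "r1": "spB1"}
        out = apply_min_support(assignments, simple_tree, 150)
        assert set(out.values()) == {UNASSIGNED}

    def test_unassign_mode_drops_weak_taxa(self, simple_tree):
        assignments = {f"a{i}": "spA1" for i in range(5)}
        assignments.update({f"b{i}": "spA2" for i in range(10)})
        out = apply_min_support(assignments, simple_tree, 10, mode="unassign")
        counts = Counter(out.values())
        assert counts[UNASSIGNED] == 5 and counts["spA2"] == 10

    def test_invariant_no_weakly_supported_taxon_survives_on_random_tables(self, rng):
        for _ in range(100):
            tree = make_random_tree(rng, int(rng.integers(5, 40)))
            ids = tree.taxon_ids()
            n = int(rng.integers(1, 300))
            threshold = int(rng.integers(1, 50))
            assignments = {
                f"r{i}": ids[int(rng.integers(0, len(ids)))] for i in range(n)
            }
            out = apply_min_support(assignments, tree, threshold)
            assert set(out) == set(assignments)  # read conservation
            direct = Counter(t for t in out.values() if t != UNASSIGNED)
            clade = Counter()
            for taxon, c in direct.items():
                for anc in tree.root_path(taxon):
                    clade[anc] += c
            # every taxon retaining reads must be clade-supported
            for taxon in direct:
                assert clade[taxon] >= threshold


class TestSummarize:
    def test_percentages_use_all_reads_as_denominator(self):
        assignments = {f"r{i}": "G" for i in range(3)}
        s = summarize_assignments(assignments, total_reads=10)
        assert s.percentages["G"] == 30.0
        assert s.counts[UNASSIGNED] == 7

    def test_no_assignments_is_fully_unassigned(self):
        s = summarize_assignments({}, total_reads=5)
        assert s.percentages[UNASSIGNED] == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            summarize_assignments({}, total_reads=0)

    def test_counts_conserve_total(self, rng):
        assignments = {f"r{i}": f"t{int(rng.integers(0, 5))}" for i in range(50)}
        s = summarize_assignments(assignments, total_reads=80)
        assert sum(s.counts.values()) == 80


def test_presets_encode_published_parameter_sets():
    main = PRESETS["megan-main"]
    assert (main.min_score, main.max_expected, main.top_percent, main.min_support) == (
        100.0, 0.01, 10.0, 150)
    marker = PRESETS["megan-marker"]
    assert (marker.min_score, marker.max_expected, marker.top_percent,
            marker.min_support) == (80.0, 0.01, 100.0, 10)
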