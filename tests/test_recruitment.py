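"""Fragment recruitment: top-hit selection, percentages, matrices, presence."""

import numpy as np
import pandas as pd
import pytest

from kefirmeta.recruitment import (
    PresenceCall,
    RecruitmentParams,
    ReferenceDB,
    ReferenceGenome,
    build_matrix,
    call_presence,
    genus_percentage_total,
    plot_recruitment,
    recruit_top_hits,
    recruitment_percentages,
)


@pytest.fixture
def db():
    return ReferenceDB(
        [
            ReferenceGenome("gA1", "spA1", "genusA", 100_000),
            ReferenceGenome("gA2", "spA2", "genusA", 80_000),
            ReferenceGenome("gB1", "spB1", "genusB", 120_000),
        ]
    )


def hit_row(read="r1", subject="gA1", identity=99.0, align_length=200,
            query_length=200, bitscore=200.0, evalue=1e-20, sstart=1000, send=1199):
    return {
        "read_id": read, "subject_id": subject, "percent_identity": identity,
        "align_length": align_length, "query_length": query_length,
        "bitscore": bitscore, "evalue": evalue,
        "subject_start": sstart, "subject_end": send,
    }


PARAMS = RecruitmentParams()


class TestRecruitTopHits:
    def test_below_identity_floor_unrecruited(self, db):
        hits = pd.DataFrame([hit_row(identity=59.9)])
        assert recruit_top_hits(hits, db, PARAMS).empty

    def test_top_hit_low_coverage_discards_read_even_if_other_hit_covers(self, db):
        # Frozen order: the top hit is chosen first; its 55% coverage kills
        # the read even though a weaker hit covers 80%.
        hits = pd.DataFrame([
            hit_row(subject="gA1", bitscore=200, align_length=110, query_length=200),
            hit_row(subject="gB1", bitscore=150, align_length=160, query_length=200),
        ])
        assert recruit_top_hits(hits, db, PARAMS).empty

    def test_highest_bitscore_wins_then_evalue_then_subject(self, db):
        hits = pd.DataFrame([
            hit_row(subject="gB1", bitscore=100, evalue=1e-5),
            hit_row(subject="gA2", bitscore=100, evalue=1e-9),
            hit_row(subject="gA1", bitscore=100, evalue=1e-9),
        ])
        rec = recruit_top_hits(hits, db, PARAMS)
        assert list(rec["genome_id"]) == ["gA1"]

    def test_midpoint_position_strand_symmetric(self, db):
        fwd = recruit_top_hits(pd.DataFrame([hit_row(sstart=100, send=299)]), db, PARAMS)
        rev = recruit_top_hits(pd.DataFrame([hit_row(sstart=299, send=100)]), db, PARAMS)
        assert fwd["position"].iloc[0] == rev["position"].iloc[0] == 199.5

    def test_concat_position_offsets_by_db_order(self, db):
        hits = pd.DataFrame([hit_row(subject="gB1", sstart=1, send=200)])
        rec = recruit_top_hits(hits, db, PARAMS)
        assert rec["concat_position"].iloc[0] == pytest.approx(100.5 + 180_000)

    def test_unknown_subject_named_in_error(self, db):
        with pytest.raises(KeyError, match="mystery"):
            recruit_top_hits(pd.DataFrame([hit_row(subject="mystery")]), db, PARAMS)

    def test_each_read_recruited_at_most_once(self, db, rng):
        rows = []
        for i in range(300):
            for _ in range(int(rng.integers(1, 4))):
                subject = ["gA1", "gA2", "gB1"][int(rng.integers(0, 3))]
                rows.append(hit_row(
                    read=f"r{i}", subject=subject,
                    identity=float(rng.uniform(55, 100)),
                    bitscore=float(rng.uniform(50, 300)),
                ))
        rec = recruit_top_hits(pd.DataFrame(rows), db, PARAMS)
        assert rec["read_id"].is_unique
        assert set(rec["read_id"]) <= {f"r{i}" for i in range(300)}

    def test_raising_min_identity_monotone(self, db, rng):
        rows = [hit_row(read=f"r{i}", identity=float(rng.uniform(55, 100)))
                for i in range(200)]
        hits = pd.DataFrame(rows)
        sizes = []
        for floor in (60.0, 70.0, 80.0, 90.0):
            p = RecruitmentParams(min_identity=floor)
            sizes.append(len(recruit_top_hits(hits, db, p)))
        assert sizes == sorted(sizes, reverse=True)


class TestPercentages:
    def test_empty_recruitment_all_zero(self, db):
        rec = recruit_top_hits(pd.DataFrame([hit_row(identity=10)]), db, PARAMS)
        pct = recruitment_percentages(rec, total_reads=100, db=db)
        assert (pct["percent_of_all_reads"] == 0.0).all()

    def test_total_is_sum_of_genus_rows(self, db):
        rows = [hit_row(read=f"a{i}", subject="gA1") for i in range(31)]
        rows += [hit_row(read=f"b{i}", subject="gB1") for i in range(23)]
        rec = recruit_top_hits(pd.DataFrame(rows), db, PARAMS)
        pct = recruitment_percentages(rec, total_reads=90, db=db)
        by = dict(zip(pct["genus"], pct["percent_of_all_reads"]))
        assert by["TOTAL"] == pytest.approx(by["genusA"] + by["genusB"])

    def test_zero_total_reads_rejected(self, db):
        with pytest.raises(ValueError):
            recruitment_percentages(pd.DataFrame(), total_reads=0, db=db)

    def test_genus_total_aggregation(self):
        assert genus_percentage_total({"a": 1.25, "b": 2.5}) == 3.75


class TestMatrix:
    def test_all_reads_in_one_cell(self, db):
        rec = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(7)],
            "genome_id": ["gA1"] * 7,
            "genus": ["genusA"] * 7,
            "position": [1200.0] * 7,
            "concat_position": [1200.0] * 7,
            "identity": [99.5] * 7,
        })
        m = build_matrix(rec, db, ["gA1"], PARAMS)
        norm = m.normalized
        assert norm.max() == 1.0
        assert (norm > 0).sum() == 1
        assert m.counts.sum() == 7

    def test_empty_recruitment_gives_zero_matrix_without_nan(self, db):
        m = build_matrix(pd.DataFrame(columns=["genome_id", "position", "identity"]),
                         db, ["gA1"], PARAMS)
        assert m.counts.sum() == 0
        assert not np.isnan(m.normalized).any()

    def test_matches_brute_force_double_loop(self, db, rng):
        n = 500
        rec = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(n)],
            "genome_id": rng.choice(["gA1", "gA2"], size=n),
            "genus": ["genusA"] * n,
            "position": rng.uniform(0, 79_999, size=n),
            "concat_position": np.zeros(n),
            "identity": rng.uniform(60, 100, size=n),
        })
        selection = ["gA1", "gA2"]
        m = build_matrix(rec, db, selection, PARAMS)
        offsets = {"gA1": 0, "gA2": 100_000}
        expected = np.zeros_like(m.counts)
        for _, row in rec.iterrows():
            x = row["position"] + offsets[row["genome_id"]]
            i = int(x // PARAMS.pos_bin_size)
            j = int((row["identity"] - PARAMS.min_identity) // PARAMS.id_bin_size)
            j = min(j, m.counts.shape[1] - 1)  # histogram closes the top edge
            expected[i, j] += 1
        assert (m.counts == expected).all()
        assert m.counts.sum() == n

    def test_nonpositive_bins_rejected(self):
        with pytest.raises(ValueError):
            RecruitmentParams(pos_bin_size=0)


def uniform_recruits(rng, genome_id, genus, length, n, ident_mean, ident_sd):
    ident = np.clip(rng.normal(ident_mean, ident_sd, size=n), 50.001, 100.0)
    return pd.DataFrame({
        "read_id": [f"r{i}" for i in range(n)],
        "genome_id": [genome_id] * n,
        "genus": [genus] * n,
        "position": rng.uniform(0, length - 1, size=n),
        "concat_position": np.zeros(n),
        "identity": ident,
    })


class TestPresence:
    def test_high_identity_uniform_coverage_is_present(self, db, rng):
        rec = uniform_recruits(rng, "gA1", "genusA", 100_000, 2000, 99.0, 0.5)
        call = call_presence(rec, db, "gA1", PARAMS)
        assert call.status == "present"
        assert call.breadth_high >= 0.6

    def test_novel_band_uniform_coverage_is_novel_relative(self, db, rng):
        rec = uniform_recruits(rng, "gA1", "genusA", 100_000, 2000, 77.0, 3.0)
        call = call_presence(rec, db, "gA1", PARAMS)
        assert call.status == "novel_relative"
        assert 70 <= call.median_identity <= 90

    def test_conserved_region_only_recruitment_is_absent(self, db, rng):
        # 100%-identity reads confined to the first 10% of position windows
        rec = uniform_recruits(rng, "gA1", "genusA", 10_000, 500, 100.0, 0.0)
        call = call_presence(rec, db, "gA1", PARAMS)
        assert call.status == "absent"
        assert call.breadth_high <= 0.11

    def test_no_recruits_is_absent_with_zero_breadth(self, db):
        call = call_presence(pd.DataFrame(columns=["genome_id", "position", "identity"]),
                             db, "gA1", PARAMS)
        assert call.status == "absent"
        assert call.breadth_high == call.breadth_novel == 0.0
        assert call.n_recruited == 0


class TestPlot:
    def test_zero_matrix_renders(self, db, tmp_path):
        m = build_matrix(pd.DataFrame(columns=["genome_id", "position", "identity"]),
                         db, ["gA1"], PARAMS)
        out = plot_recruitment(m, tmp_path / "zero.png")
        assert out.exists() and out.stat().st_size > 0

    def test_output_stable_across_two_runs(self, db, rng, tmp_path):
        rec = uniform_recruits(rng, "gA1", "genusA", 100_000, 300, 95.0, 2.0)
        m = build_matrix(rec, db, ["gA1"], PARAMS)
        p1 = plot_recruitment(m, tmp_path / "a.png")
        p2 = plot_recruitment(m, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()
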