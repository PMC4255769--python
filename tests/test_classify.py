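"""Hit ranking, exclusions and arm-pattern classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from armshift.homoeology import ARM_NAMES
from armshift.classify import (
    BLAST6_COLUMNS,
    STATUS_ACCEPTED,
    STATUS_BOTH_ARMS,
    STATUS_FLAGGED,
    STATUS_INCOMPLETE,
    STATUS_NOT_HOMOEOLOGOUS,
    build_ortholog_set,
    classify_all,
    classify_gene,
    exclude_both_arms,
    secondary_hit_check,
    top_hits,
)
from armshift.errors import ValidationError


def make_hits(rows):
    """rows: (gene, library, bitscore[, evalue, pident, sstart])."""
    records = []
    for row in rows:
        gene, lib, score = row[:3]
        evalue = row[3] if len(row) > 3 else 1e-50
        pident = row[4] if len(row) > 4 else 95.0
        sstart = row[5] if len(row) > 5 else 1000
        records.append(
            dict(
                qseqid=gene, sseqid=lib, pident=pident, length=500, mismatch=10,
                gapopen=0, qstart=1, qend=500, sstart=sstart, send=sstart + 499,
                evalue=evalue, bitscore=score,
            )
        )
    return pd.DataFrame(records, columns=BLAST6_COLUMNS)


class TestOrthologSet:
    GENES = {
        "Brachypodium": ["b1", "b2"],
        "T_urartu": ["u1", "u2"],
        "Ae_tauschii": ["t1"],
    }

    def test_priority_representative(self):
        recs = build_ortholog_set(self.GENES, [("b1", "u1"), ("u1", "t1")])
        ids = {r.gene_id for r in recs}
        assert "b1" in ids and "u1" not in ids and "t1" not in ids

    def test_unpartnered_gene_retained(self):
        recs = build_ortholog_set(self.GENES, [("b1", "u1")])
        by_id = {r.gene_id: r.source for r in recs}
        assert by_id["u2"] == "T_urartu"  # no Brachypodium ortholog -> added

    def test_within_source_pair_is_error(self):
        with pytest.raises(ValidationError):
            build_ortholog_set(self.GENES, [("b1", "b2")])

    def test_unknown_gene_is_error(self):
        with pytest.raises(ValidationError):
            build_ortholog_set(self.GENES, [("b1", "zz")])

    def test_no_two_records_share_a_cluster(self):
        recs = build_ortholog_set(self.GENES, [("b1", "u1"), ("b2", "u2"), ("b2", "t1")])
        assert sorted(r.gene_id for r in recs) == ["b1", "b2"]


class TestTopHits:
    def test_distinct_bitscores(self):
        hits = make_hits([("g", lib, s) for lib, s in
                          [("1AS", 10), ("1BS", 50), ("1DS", 30), ("2AS", 40), ("2BS", 20)]])
        assert list(top_hits(hits, 3)["sseqid"]) == ["1BS", "2AS", "1DS"]

    def test_tie_break_is_total_and_deterministic(self):
        hits = make_hits([
            ("g", "1BS", 50, 1e-50, 95.0),
            ("g", "1AS", 50, 1e-50, 95.0),   # identical scores: library id decides
            ("g", "1DS", 50, 1e-50, 97.0),   # higher identity wins first
            ("g", "2AS", 50, 1e-60, 90.0),   # lower e-value wins over all
        ])
        assert list(top_hits(hits, 4)["sseqid"]) == ["2AS", "1DS", "1AS", "1BS"]

    def test_k_larger_than_available(self):
        hits = make_hits([("g", "1AS", 10), ("g", "1BS", 20)])
        assert len(top_hits(hits, 10)) == 2

    def test_empty(self):
        assert top_hits(make_hits([]), 3).empty


class TestBothArmExclusion:
    @pytest.mark.parametrize(
        "libs,excluded",
        [
            (["1AS", "1AL", "1BL"], True),
            (["1AS", "1BL", "1DL"], False),
            (["1AS", "2AL"], False),  # different chromosomes
            (["3B", "1AS"], False),   # unresolved whole-chromosome id ignored
        ],
    )
    def test_rule(self, libs, excluded):
        assert exclude_both_arms(libs) is excluded


class TestClassifyGene:
    def test_inferred_transfer_from_minority_arm(self):
        p = classify_gene(["1AL", "1BL", "1DS"])
        assert p.classification == "nonstandard"
        assert p.transfer == "1DL->1DS"
        assert p.chromosome == "1D"
        assert p.triplet == "1AL/1BL/1DS"

    def test_standard_triplet(self):
        p = classify_gene(["2AS", "2BS", "2DS"])
        assert p.classification == "standard" and p.transfer is None

    def test_group4_standard_respects_swap(self):
        p = classify_gene(["4AL", "4BS", "4DS"])
        assert p.classification == "standard"

    def test_group4_all_long_is_nonstandard(self):
        # 4AL/4BL/4DL: modern 4AS segment transferred to modern 4AL
        p = classify_gene(["4AL", "4BL", "4DL"])
        assert p.classification == "nonstandard"
        assert p.transfer == "4AS->4AL"

    def test_mixed_groups_excluded(self):
        p = classify_gene(["1AL", "1BL", "3BS"])
        assert p.status == STATUS_NOT_HOMOEOLOGOUS

    def test_fewer_than_three_hits(self):
        assert classify_gene(["1AL", "1BL"]).status == STATUS_INCOMPLETE

    def test_unknown_library_rejected(self):
        with pytest.raises(ValidationError):
            classify_gene(["1AL", "1BL", "9ZZ"])

    @given(
        st.integers(1, 7),
        st.sampled_from("SL"),
        st.sampled_from("SL"),
        st.sampled_from("SL"),
    )
    def test_triplet_never_mixes_groups_and_transfer_iff_nonstandard(
        self, group, a1, a2, a3
    ):
        p = classify_gene([f"{group}A{a1}", f"{group}B{a2}", f"{group}D{a3}"])
        assert p.status == STATUS_ACCEPTED and p.group == group
        assert (p.transfer is not None) == (p.classification == "nonstandard")


class TestSecondaryHitCheck:
    TRIPLET = {"A": "L", "B": "L", "D": "S"}

    def test_opposite_arm_within_window_flags(self):
        sec = pd.DataFrame({"library": ["1DL"], "bitscore": [95.0]})
        assert secondary_hit_check(sec, self.TRIPLET, 1, rank3_bitscore=100.0)

    def test_opposite_arm_below_window_does_not_flag(self):
        sec = pd.DataFrame({"library": ["1DL"], "bitscore": [80.0]})
        assert not secondary_hit_check(sec, self.TRIPLET, 1, rank3_bitscore=100.0)

    def test_unrelated_group_does_not_flag(self):
        sec = pd.DataFrame({"library": ["5AS"], "bitscore": [99.0]})
        assert not secondary_hit_check(sec, self.TRIPLET, 1, rank3_bitscore=100.0)

    def test_no_secondary_hits(self):
        sec = pd.DataFrame({"library": [], "bitscore": []})
        assert not secondary_hit_check(sec, self.TRIPLET, 1, rank3_bitscore=100.0)


class TestClassifyAll:
    def test_statuses_and_conservation(self):
        hits = make_hits(
            [("ns", "1AL", 90), ("ns", "1BL", 80), ("ns", "1DS", 70)]
            + [("both", "1AS", 90), ("both", "1AL", 80), ("both", "1BS", 70)]
            + [("two", "2AS", 90), ("two", "2BS", 80)]
            + [("mix", "1AL", 90), ("mix", "2BL", 80), ("mix", "3DL", 70)]
        )
        res = classify_all(hits, genes=["ns", "both", "two", "mix", "nohit"])
        by_gene = res.patterns.set_index("gene")["status"]
        assert by_gene["ns"] == STATUS_ACCEPTED
        assert by_gene["both"] == STATUS_BOTH_ARMS
        assert by_gene["two"] == STATUS_INCOMPLETE
        assert by_gene["mix"] == STATUS_NOT_HOMOEOLOGOUS
        assert by_gene["nohit"] == STATUS_INCOMPLETE
        assert sum(res.summary["status_counts"].values()) == res.summary["n_genes"] == 5

    def test_evalue_filter_applies(self):
        hits = make_hits([
            ("g", "1AS", 90), ("g", "1BS", 80), ("g", "1DS", 70, 1e-3),
        ])
        res = classify_all(hits)
        assert res.patterns.iloc[0]["status"] == STATUS_INCOMPLETE

    def test_3b_hits_resolved_by_midpoint(self):
        # subject 3B at 100 Mb -> 3BS; at 500 Mb -> 3BL
        hits = make_hits([
            ("g", "3B", 90, 1e-50, 95.0, 100_000_000),
            ("g", "3A", 80, 1e-50, 95.0, 1000),
            ("g", "3D", 70, 1e-50, 95.0, 1000),
        ])
        hits.loc[hits["sseqid"] == "3A", "sseqid"] = "3AS"
        hits.loc[hits["sseqid"] == "3D", "sseqid"] = "3DS"
        res = classify_all(hits)
        row = res.patterns.iloc[0]
        assert row["status"] == STATUS_ACCEPTED
        assert row["triplet"] == "3AS/3BS/3DS"

    def test_centromeric_3b_hit_dropped(self):
        hits = make_hits([
            ("g", "3B", 90, 1e-50, 95.0, 300_000_000),
            ("g", "3AS", 80), ("g", "3DS", 70),
        ])
        res = classify_all(hits)
        assert res.patterns.iloc[0]["status"] == STATUS_INCOMPLETE
        assert res.summary["n_3b_hits_dropped_centromeric"] == 1

    def test_unknown_library_named_in_error(self):
        hits = make_hits([("g", "1AX", 90)])
        with pytest.raises(ValidationError, match="1AX"):
            classify_all(hits)

    def test_duplicate_gene_ids_rejected(self):
        hits = make_hits([("g", "1AS", 90)])
        with pytest.raises(ValidationError, match="duplicate"):
            classify_all(hits, genes=["g", "g"])

    def test_opposite_arm_secondary_hit_causes_both_arm_exclusion(self):
        # the both-arm rule takes precedence over flagging: a significant
        # opposite-arm hit at any rank excludes the gene outright
        hits = make_hits(
            [("g", "1AL", 90), ("g", "1BL", 85), ("g", "1DS", 80), ("g", "1DL", 79)]
        )
        res = classify_all(hits)
        assert res.patterns.iloc[0]["status"] == STATUS_BOTH_ARMS

    def test_determinism_byte_identical(self):
        rng = np.random.default_rng(0)
        libs = list(ARM_NAMES)
        rows = []
        for i in range(50):
            for lib in rng.choice(libs, size=6, replace=False):
                rows.append((f"g{i:02d}", lib, float(rng.integers(50, 150))))
        hits = make_hits(rows)
        r1 = classify_all(hits.sample(frac=1.0, random_state=1))
        r2 = classify_all(hits.sample(frac=1.0, random_state=2))
        pd.testing.assert_frame_equal(
            r1.patterns.reset_index(drop=True), r2.patterns.reset_index(drop=True)
        )
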