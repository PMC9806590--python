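"""Hit-table parsing, redundancy merging, length filtering, classification."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from tirscape.domain_assembly import (
    DomainHit,
    HitTableParseError,
    ProteinRecord,
    classify_architecture,
    filter_domain_length,
    merge_overlapping_hits,
    parse_hit_table,
    tabulate_architectures,
)

from conftest import merge_oracle, random_hit_set

CLASS_MAP = {
    "TIR_hmm1": "TIR",
    "TIR_hmm2": "TIR",
    "NBARC_hmm": "NBARC",
    "LRR_hmm": "LRR",
    "TPR_hmm1": "TPR",
}


def hit(cls="TIR", start=1, end=120, ev=1e-10, name="TIR_hmm1", pid="p1"):
    return DomainHit(pid, name, cls, start, end, ev)


class TestParseHitTable:
    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert parse_hit_table(path, CLASS_MAP, 0.01) == []

    def test_evalue_inclusion_cutoff_is_applied(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "p1\tTIR_hmm1\t1\t100\t0.005\t300\n"
            "p1\tTIR_hmm2\t1\t100\t0.02\t300\n"
        )
        hits = parse_hit_table(path, CLASS_MAP, max_evalue=0.01)
        assert [h.evalue for h in hits] == [0.005]

    def test_tsv_fields_roundtrip_verbatim(self, tiny_hit_fixture):
        """Parsed hits equal an independent line-by-line read of the fixture."""
        path, rows = tiny_hit_fixture
        hits = parse_hit_table(path, CLASS_MAP, max_evalue=0.01)
        expected = [r for r in rows if r[4] <= 0.01]
        assert len(hits) == len(expected)
        for h, (pid, name, s, e, ev, _len) in zip(hits, expected):
            assert (h.protein_id, h.hmm_name, h.env_start, h.env_end, h.evalue) == (
                pid, name, s, e, ev,
            )

    def test_unknown_hmm_maps_to_other(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("p1\tmystery_hmm\t1\t100\t1e-5\t300\n")
        (h,) = parse_hit_table(path, CLASS_MAP, 0.01)
        assert h.domain_class == "OTHER"

    def test_domtblout_dialect(self, tmp_path):
        # 23-column HMMER3 per-domain row; env coords in columns 20-21,
        # i-Evalue in column 13
        row = (
            "protA - 400 TIR_hmm1 PF01582.20 175 1.2e-30 105.3 0.1 1 2 "
            "2.1e-18 4.2e-15 50.1 0.0 3 170 12 180 10 185 0.92 -"
        )
        path = tmp_path / "hits.domtblout"
        path.write_text("# comment line\n" + row + "\n")
        (h,) = parse_hit_table(path, CLASS_MAP, 0.01)
        assert (h.protein_id, h.hmm_name) == ("protA", "TIR_hmm1")
        assert (h.env_start, h.env_end) == (10, 185)
        assert h.evalue == 4.2e-15

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("p1\tTIR_hmm1\t1\t100\t1e-5\t300\np2\tbad\tx\ty\tz\t1\n")
        with pytest.raises(HitTableParseError, match="line 2"):
            parse_hit_table(path, CLASS_MAP, 0.01)

    def test_negative_coordinates_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("p1\tTIR_hmm1\t-3\t100\t1e-5\t300\n")
        with pytest.raises(HitTableParseError, match="line 1"):
            parse_hit_table(path, CLASS_MAP, 0.01)


class TestMergeOverlappingHits:
    def test_disjoint_hits_both_retained(self):
        hits = [hit(start=1, end=120), hit(start=130, end=200, name="TIR_hmm2")]
        assert len(merge_overlapping_hits(hits)) == 2

    def test_overlap_21_keeps_lower_evalue(self):
        a = hit(start=1, end=120, ev=1e-10)
        b = hit(start=100, end=200, ev=1e-5, name="TIR_hmm2")
        assert merge_overlapping_hits([a, b]) == [a]

    def test_overlap_exactly_20_is_not_redundant(self):
        a = hit(start=1, end=120)
        b = hit(start=101, end=200, name="TIR_hmm2")
        assert len(merge_overlapping_hits([a, b])) == 2

    def test_different_classes_never_suppress(self):
        a = hit(cls="TIR", start=1, end=120, ev=1e-3)
        b = hit(cls="NBARC", start=1, end=120, ev=1e-20, name="NBARC_hmm")
        assert len(merge_overlapping_hits([a, b])) == 2

    def test_transitive_chain_keeps_single_representative(self):
        # a-b overlap > 20, b-c overlap > 20, a-c disjoint: one survivor
        a = hit(start=1, end=100, ev=1e-5)
        b = hit(start=50, end=160, ev=1e-9, name="TIR_hmm2")
        c = hit(start=140, end=240, ev=1e-7, name="TIR_like")
        assert merge_overlapping_hits([a, b, c]) == [b]

    def test_tie_break_longer_envelope_then_name(self):
        a = hit(start=1, end=100, ev=1e-5, name="zzz")
        b = hit(start=1, end=150, ev=1e-5, name="aaa")
        assert merge_overlapping_hits([a, b]) == [b]
        c = hit(start=1, end=100, ev=1e-5, name="aaa")
        d = hit(start=1, end=100, ev=1e-5, name="zzz")
        assert merge_overlapping_hits([c, d]) == [c]

    def test_mixed_protein_ids_rejected(self):
        with pytest.raises(ValueError, match="multiple proteins"):
            merge_overlapping_hits([hit(pid="p1"), hit(pid="p2")])

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_oracle(self, seed):
        hits = random_hit_set(seed)
        assert merge_overlapping_hits(hits) == merge_oracle(hits)

    @pytest.mark.parametrize("seed", range(20))
    def test_idempotent(self, seed):
        merged = merge_overlapping_hits(random_hit_set(seed))
        assert merge_overlapping_hits(merged) == merged


class TestFilterDomainLength:
    MIN_LEN = {"TIR": 50, "NBARC": 150}

    @pytest.mark.parametrize(
        "cls,length,kept",
        [("TIR", 49, False), ("TIR", 50, True), ("NBARC", 149, False),
         ("NBARC", 150, True), ("LRR", 10, True)],
    )
    def test_length_boundaries(self, cls, length, kept):
        h = hit(cls=cls, start=1, end=length, name="x")
        assert (filter_domain_length([h], self.MIN_LEN) == [h]) is kept


class TestClassifyArchitecture:
    def prot(self, length=300, pid="p1"):
        return ProteinRecord(pid, "sp1", length)

    def test_short_single_tir_is_tir_only(self):
        arch = classify_architecture(self.prot(200), [hit(start=10, end=120)])
        assert arch.label == "TIR_ONLY"

    def test_tir_nbarc_tpr_is_tnp_even_with_lrr(self):
        domains = [
            hit(cls="TIR", start=10, end=120),
            hit(cls="NBARC", start=150, end=400, name="NBARC_hmm"),
            hit(cls="LRR", start=420, end=600, name="LRR_hmm"),
            hit(cls="TPR", start=620, end=720, name="TPR_hmm1"),
        ]
        arch = classify_architecture(self.prot(800), domains)
        assert arch.label == "TNP"

    def test_long_single_tir_is_tir_other(self):
        arch = classify_architecture(self.prot(450), [hit(start=10, end=120)])
        assert arch.label == "TIR_OTHER"

    def test_tir_with_other_domain_is_tir_other(self):
        domains = [hit(start=10, end=120),
                   hit(cls="OTHER", start=150, end=250, name="misc")]
        arch = classify_architecture(self.prot(300), domains)
        assert arch.label == "TIR_OTHER"

    @pytest.mark.parametrize(
        "classes,label",
        [(["TIR", "NBARC", "LRR"], "TNL"), (["TIR", "NBARC"], "TN"),
         ([], "NON_TIR"), (["NBARC", "LRR"], "NON_TIR")],
    )
    def test_rule_order(self, classes, label):
        domains = [
            hit(cls=c, start=1 + 200 * i, end=180 + 200 * i, name=f"h{i}")
            for i, c in enumerate(classes)
        ]
        assert classify_architecture(self.prot(900), domains).label == label

    @pytest.mark.parametrize("seed", range(10))
    def test_label_invariant_under_domain_order(self, seed):
        rng = random.Random(seed)
        domains = [
            hit(cls=rng.choice(["TIR", "NBARC", "LRR", "TPR"]),
                start=1 + 150 * i, end=130 + 150 * i, name=f"h{i}")
            for i in range(rng.randint(0, 4))
        ]
        base = classify_architecture(self.prot(900), domains).label
        for _ in range(5):
            rng.shuffle(domains)
            assert classify_architecture(self.prot(900), domains).label == base

    def test_foreign_hit_rejected(self):
        with pytest.raises(ValueError):
            classify_architecture(self.prot(300, pid="p1"), [hit(pid="p2")])


class TestTabulate:
    def test_empty_input_all_zero(self):
        table = tabulate_architectures([], {}, ["sp1", "sp2"])
        assert (table.values == 0).all()
        assert list(table.columns) == ["TNL", "TN", "TIR_ONLY", "TNP"]

    def test_tnp_counted_only_in_its_own_column(self):
        arch = classify_architecture(
            ProteinRecord("p1", "sp1", 900),
            [hit(cls="TIR", start=10, end=120),
             hit(cls="NBARC", start=150, end=400, name="NBARC_hmm"),
             hit(cls="TPR", start=500, end=600, name="TPR_hmm1")],
        )
        table = tabulate_architectures([arch], {"p1": "sp1"}, ["sp1"])
        assert table.loc["sp1", "TNP"] == 1
        assert table.loc["sp1", ["TNL", "TN", "TIR_ONLY"]].sum() == 0

    def test_unknown_species_rejected(self):
        arch = classify_architecture(ProteinRecord("p1", "spX", 200),
                                     [hit(start=10, end=120)])
        with pytest.raises(ValueError, match="taxonomy"):
            tabulate_architectures([arch], {"p1": "spX"}, ["sp1"])


@given(
    st.lists(
        st.tuples(
            st.integers(1, 300), st.integers(1, 150),
            st.floats(0, 1, allow_nan=False), st.sampled_from("abcd"),
        ),
        max_size=12,
    )
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_merge_survivors_never_over_overlap(raw):
    """Property: no retained same-class pair overlaps by more than the limit."""
    hits = [
        DomainHit("p1", f"hmm_{name}", "TIR", s, s + ln - 1, ev)
        for s, ln, ev, name in raw
    ]
    merged = merge_overlapping_hits(hits, max_overlap=20)
    for i, a in enumerate(merged):
        for b in merged[i + 1:]:
            ov = min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1
            assert ov <= 20
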