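"""Global alignment, length classification, and the per-species census."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sporekit as sk
from sporekit.census import (
    AlignmentScoring,
    HomologCall,
    ProteinRecord,
    census,
    classify_length,
    global_align,
)
from sporekit.synth import AMINO_ACIDS

from _oracles import enumerate_alignment_score, nw_linear_score

LINEAR = AlignmentScoring(matrix=None, match=2.0, mismatch=-1.0, gap_open=2.0, gap_extend=2.0)


class TestGlobalAlign:
    def test_self_alignment_is_full_identity(self):
        rng = np.random.Generator(np.random.PCG64(1))
        for _ in range(10):
            s = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(10, 120))))
            r = global_align(s, s)
            assert r.percent_identity == 100.0
            assert r.query_coverage == 100.0

    def test_single_substitution_identity(self):
        r = global_align("AAAA", "AATA", LINEAR)
        assert r.percent_identity == 75.0
        assert r.query_coverage == 100.0

    def test_score_matches_brute_force_on_small_pairs(self):
        seqs = ["".join(p) for n in (1, 2, 3, 4) for p in itertools.product("AR", repeat=n)]
        for a in seqs[::3]:
            for b in seqs[::3]:
                got = global_align(a, b, LINEAR).score
                want = nw_linear_score(a, b, 2.0, -1.0, 2.0)
                assert got == pytest.approx(want)

    def test_dp_oracle_agrees_with_literal_enumeration(self):
        # sanity-check the test oracle itself on a handful of pairs
        for a, b in [("AR", "RA"), ("AAR", "AR"), ("R", "AAA"), ("ARAR", "RRA")]:
            assert nw_linear_score(a, b, 2.0, -1.0, 2.0) == pytest.approx(
                enumerate_alignment_score(a, b, 2.0, -1.0, 2.0)
            )

    def test_terminal_gaps_excluded_from_identity(self):
        # identical core, one extended terminus: identity stays 100
        r = global_align("MKVLAT", "MKVLATGGG", LINEAR)
        assert r.percent_identity == 100.0
        assert r.query_coverage == 100.0

    def test_score_symmetric_under_symmetric_scoring(self):
        rng = np.random.Generator(np.random.PCG64(2))
        for _ in range(10):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=30))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=25))
            assert global_align(a, b).score == pytest.approx(global_align(b, a).score)

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            global_align("ACDB1", "ACD")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            global_align("", "ACD")


class TestClassifyLength:
    @pytest.mark.parametrize(
        "length,expected",
        [(231, "YetF-like"), (286, "2Duf-like"), (400, "unclassified"),
         (210, "YetF-like"), (253, "YetF-like"), (254, "unclassified"),
         (285, "2Duf-like"), (290, "2Duf-like")],
    )
    def test_length_windows(self, length, expected):
        assert classify_length(length) == expected

    def test_every_length_maps_to_exactly_one_class(self):
        for length in range(1, 500):
            assert classify_length(length) in ("YetF-like", "2Duf-like", "unclassified")

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_length(231, {"yetf": (210, 290), "duf2": (285, 290)})


def _call(pid, species, length, cov=95.0, ident=40.0, evalue=None):
    return HomologCall(
        protein_id=pid, species=species, length=length, query="YetF",
        percent_identity=ident, query_coverage=cov,
        homolog_class=classify_length(length), evalue=evalue,
    )


class TestCensus:
    def test_counts_by_class(self):
        calls = [_call("a", "sp1", 231), _call("b", "sp1", 235), _call("c", "sp1", 286)]
        table, _ = census(calls)
        row = table.set_index("species").loc["sp1"]
        assert row["n_yetf_like"] == 2 and row["n_2duf_like"] == 1

    def test_low_coverage_filtered_out(self):
        calls = [_call("a", "sp1", 231, cov=80.0), _call("b", "sp1", 231, cov=90.0)]
        table, _ = census(calls)
        assert table.set_index("species").loc["sp1", "n_yetf_like"] == 1

    def test_evalue_filter_applied_when_hit_table_given(self):
        calls = [_call("a", "sp1", 231), _call("b", "sp1", 231)]
        hits = pd.DataFrame(
            {"protein_id": ["a", "b"], "evalue": [1e-40, 1e-20]}
        )
        table, best = census(calls, hit_table=hits)
        assert table.set_index("species").loc["sp1", "n_yetf_like"] == 1
        assert best.iloc[0]["protein_id"] == "a"

    def test_best_hit_most_significant_vs_literal_max(self):
        calls = [_call("a", "sp1", 231, evalue=None), _call("b", "sp1", 231, evalue=None)]
        hits = pd.DataFrame({"protein_id": ["a", "b"], "evalue": [1e-40, 1e-35]})
        _, best = census(calls, hit_table=hits)
        assert best.iloc[0]["protein_id"] == "a"
        _, best = census(calls, hit_table=hits, best_hit_rule="literal_max")
        assert best.iloc[0]["protein_id"] == "b"

    def test_counts_permutation_invariant(self):
        rng = np.random.Generator(np.random.PCG64(4))
        calls = [
            _call(f"p{i}", f"sp{i % 3}", int(rng.choice([231, 286, 400])))
            for i in range(30)
        ]
        t1, _ = census(list(calls))
        shuffled = [calls[i] for i in rng.permutation(len(calls))]
        t2, _ = census(shuffled)
        pd.testing.assert_frame_equal(
            t1.reset_index(drop=True), t2.reset_index(drop=True)
        )

    def test_round_trip_with_generated_labels(self):
        records, labels = sk.generate_protein_set(6, 4, 3, seed=9)
        calls = sk.call_homologs(records)
        table, _ = census(calls)
        assert table["n_yetf_like"].sum() == 6
        assert table["n_2duf_like"].sum() == 4
        assert table["n_unclassified"].sum() == 3


class TestProteinRecord:
    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            ProteinRecord(id="p", species="sp", sequence="ACDEFZ")

    def test_ambiguous_x_allowed_and_flagged(self):
        rec = ProteinRecord(id="p", species="sp", sequence="ACDXF")
        assert rec.has_ambiguous
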