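"""Suffix-structure construction against definition-level oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colormove import (
    Document,
    ReferenceCollection,
    StrandMode,
    build_bwt,
    build_document_array,
    build_lcp,
    build_suffix_array,
    compute_thresholds,
    run_length_encode,
)
from colormove.collection import NO_DOCUMENT, concatenate_documents
from colormove.suffix import (
    RangeMinSparseTable,
    _suffix_array_doubling,
    suffix_array_naive,
)
from colormove.alphabet import encode

from conftest import oracle_bwt, oracle_lcp, oracle_suffix_array, random_collection


class TestSuffixArray:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("AACAAG$", [6, 0, 3, 1, 4, 2, 5]),
            ("ACG$", [3, 0, 1, 2]),
            ("$", [0]),
        ],
    )
    def test_known_values(self, text, expected):
        assert build_suffix_array(text).tolist() == expected

    def test_rejects_missing_terminator(self):
        with pytest.raises(ValueError):
            build_suffix_array("ACGT")
        with pytest.raises(ValueError):
            build_suffix_array("AC$G$")

    @given(st.text(alphabet="ACGT", min_size=0, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_sorted_suffix_oracle(self, body):
        text = body + "$"
        assert build_suffix_array(text).tolist() == oracle_suffix_array(text)

    @given(st.text(alphabet="ACGT", min_size=0, max_size=300))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_doubling_equals_naive(self, body):
        text = body + "$"
        got = _suffix_array_doubling(encode(text).astype(np.int64))
        assert got.tolist() == suffix_array_naive(text).tolist()


class TestBwtAndLcp:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("AACAAG$", "G$CAAAA"),
            ("ACG$", "G$AC"),
            ("A$", "A$"),
        ],
    )
    def test_bwt_known_values(self, text, expected):
        sa = build_suffix_array(text)
        assert build_bwt(text, sa) == expected

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("AACAAG$", [0, 0, 2, 1, 1, 0, 0]),
            ("AAAA$", [0, 0, 1, 2, 3]),
            ("$", [0]),
        ],
    )
    def test_lcp_known_values(self, text, expected):
        sa = build_suffix_array(text)
        assert build_lcp(text, sa).tolist() == expected

    @given(st.text(alphabet="ACGT", min_size=0, max_size=150))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bwt_and_lcp_match_oracles(self, body):
        text = body + "$"
        sa = build_suffix_array(text)
        assert build_bwt(text, sa) == oracle_bwt(text)
        assert build_lcp(text, sa).tolist() == oracle_lcp(text, sa.tolist())

    def test_lf_round_trip_reconstructs_text(self):
        """Iterating LF from the terminator row inverts the BWT."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            coll = random_collection(rng)
            text = concatenate_documents(coll)
            sa = build_suffix_array(text)
            bwt = build_bwt(text, sa)
            from conftest import oracle_lf

            lf = oracle_lf(bwt)
            row = 0  # the terminator row is rank 0 ('$' smallest)
            rebuilt = []
            for _ in range(len(bwt)):
                rebuilt.append(bwt[row])
                row = lf[row]
            # the walk visits text characters right to left, ending on '$'
            assert "".join(reversed(rebuilt[:-1])) + "$" == text.text


class TestDocumentArray:
    def test_toy_documents(self, toy_text):
        sa = build_suffix_array(toy_text)
        doc = build_document_array(sa, toy_text)
        assert doc.tolist() == [NO_DOCUMENT, 0, 1, 0, 1, 0, 1]

    def test_single_document(self):
        coll = ReferenceCollection(
            [Document(0, "D", ["ACGTT"])], StrandMode.FORWARD_ONLY
        )
        text = concatenate_documents(coll)
        doc = build_document_array(build_suffix_array(text), text)
        assert sorted(doc.tolist()) == [NO_DOCUMENT] + [0] * 5

    def test_terminator_only_row(self):
        from colormove.collection import ConcatenatedText

        text = ConcatenatedText("$", [])
        doc = build_document_array(build_suffix_array("$"), text)
        assert doc.tolist() == [NO_DOCUMENT]


class TestRuns:
    @pytest.mark.parametrize(
        "bwt,expected",
        [
            ("G$CAAAA", [("G", 1), ("$", 1), ("C", 1), ("A", 4)]),
            ("AAAA", [("A", 4)]),
            ("ACGT", [("A", 1), ("C", 1), ("G", 1), ("T", 1)]),
        ],
    )
    def test_run_length_encode(self, bwt, expected):
        runs = run_length_encode(bwt)
        assert [(r.char, r.length) for r in runs] == expected
        assert sum(r.length for r in runs) == len(bwt)

    @given(st.text(alphabet="ACGT$", min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_runs_partition_rows(self, bwt):
        runs = run_length_encode(bwt)
        assert sum(r.length for r in runs) == len(bwt)
        assert all(a.char != b.char for a, b in zip(runs, runs[1:]))
        pos = 0
        for r in runs:
            assert r.start == pos
            pos += r.length


class TestThresholds:
    def test_single_direction_is_trivial(self):
        # BWT G$CAAAA: the A-run (rows 3-6) sees C and G only above
        bwt = "G$CAAAA"
        sa = build_suffix_array("AACAAG$")
        lcp = build_lcp("AACAAG$", sa)
        runs = run_length_encode(bwt)
        thr = compute_thresholds(runs, lcp)
        a_run = 3
        from colormove.alphabet import CHAR_TO_CODE

        assert thr[a_run, CHAR_TO_CODE["C"]] == 4  # always up
        assert thr[a_run, CHAR_TO_CODE["G"]] == 4  # always up

    def test_tie_breaks_upward(self):
        # text CACG$ -> BWT GC$AC; rows 2-3 sit between the two C rows and
        # tie on LCP both ways, so both go up
        text = "CACG$"
        sa = build_suffix_array(text)
        bwt = build_bwt(text, sa)
        assert bwt == "GC$AC"
        lcp = build_lcp(text, sa)
        runs = run_length_encode(bwt)
        thr = compute_thresholds(runs, lcp)
        from colormove.alphabet import CHAR_TO_CODE

        c = CHAR_TO_CODE["C"]
        # rows 2 ($-run) and 3 (A-run) are single-row runs: threshold 1 = up
        for run_idx, r in enumerate(runs):
            if r.start in (2, 3):
                assert thr[run_idx, c] == r.length  # everything repositions up


class TestRangeMin:
    @given(
        st.lists(st.integers(0, 100), min_size=1, max_size=80),
        st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_direct_min(self, values, data):
        table = RangeMinSparseTable(np.array(values))
        lo = data.draw(st.integers(0, len(values) - 1))
        hi = data.draw(st.integers(lo, len(values) - 1))
        assert table.query(lo, hi) == min(values[lo : hi + 1])
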