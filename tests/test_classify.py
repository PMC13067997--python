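"""PML computation, color tallying and the classification pipeline."""

import numpy as np
import pytest

from colormove import (
    QueryEngine,
    RepositionStrategy,
    assign_taxon,
    average_pml,
    binary_classify,
    calibrate_cutoff,
    classify_read,
    classify_reads,
    compute_pmls_with_colors,
    report_documents,
)
from colormove.index import build_index
from colormove.collection import concatenate_documents

from conftest import oracle_matching_statistic, random_collection, random_read


class TestPml:
    def test_toy_trace(self, toy_index):
        """Hand trace on the AAC/AAG index: read AAG gives PMLs [2,1,0]
        and tallies {D1:2, D2:2} (the tie case)."""
        for strategy in RepositionStrategy:
            result, scores = compute_pmls_with_colors("AAG", toy_index, strategy)
            assert result.lengths == [2, 1, 0]
            assert scores == {0: 2, 1: 2}

    def test_absent_character_read(self, toy_index):
        result, scores = compute_pmls_with_colors("TTT", toy_index)
        assert result.lengths == [0, 0, 0]
        assert scores == {}

    def test_unknown_symbol_resets(self, toy_index):
        result, _ = compute_pmls_with_colors("ANA", toy_index)
        assert result.lengths[1] == 0

    def test_empty_read_rejected(self, toy_index):
        with pytest.raises(ValueError):
            compute_pmls_with_colors("", toy_index)

    def test_zero_pml_positions_have_no_color(self, toy_index):
        result, _ = compute_pmls_with_colors("AAG", toy_index)
        for length, cid in zip(result.lengths, result.color_ids):
            assert (length > 0) == (cid is not None)


class TestPmlSoundness:
    """Substring soundness and MS under-approximation, all strategies."""

    @pytest.mark.parametrize("strategy", list(RepositionStrategy))
    def test_matches_occur_and_underapproximate(self, strategy):
        rng = np.random.default_rng(47)
        for _ in range(15):
            coll = random_collection(rng)
            text = concatenate_documents(coll)
            idx = build_index(coll, keep_suffix_structures=True)
            engine = QueryEngine(idx, strategy)
            for _ in range(4):
                if rng.random() < 0.5:
                    read = random_read(rng, int(rng.integers(5, 40)))
                else:  # embedded substring with a few errors
                    start = int(rng.integers(0, max(1, text.n - 30)))
                    read = text.text[start : start + 30].replace("$", "A")
                if not read:
                    continue
                result, _ = engine.pml(read)
                for k, length in enumerate(result.lengths):
                    assert 0 <= length <= len(read) - k
                    if length > 0:
                        assert read[k : k + length] in text.text
                    assert length <= oracle_matching_statistic(
                        read, text.text, k
                    )

    def test_tracked_document_always_in_color(self, pangenome_index):
        """The tracked row's document contains the match and belongs to the
        run's color, so every tallied color intersects the true match set —
        the guarantee that keeps the true document's score growing through a
        case-1 streak."""
        engine = QueryEngine(pangenome_index, RepositionStrategy.LCP_THRESHOLDS)
        rng = np.random.default_rng(3)
        doc0 = pangenome_index.full.text
        read = doc0.text[1000:1600].replace("$", "A")
        trace = engine.fidelity_trace(read, min_length=1)
        assert trace, "expected at least one positive PML"
        for rec in trace:
            assert rec.truth, "recorded match must occur somewhere"
            assert rec.color & rec.truth
            # the score-supported set never loses the tracked document
            assert rec.supported & rec.truth
            assert rec.supported <= rec.color


class TestAveragePml:
    def test_known_values(self):
        assert average_pml([2, 1, 0], 3) == pytest.approx(1.0)
        assert average_pml([0, 0, 0, 0], 4) == 0.0

    def test_full_match_closed_form(self):
        # an uninterrupted case-1 sweep yields lengths m..1: average (m+1)/2
        m = 17
        lengths = list(range(m, 0, -1))
        assert average_pml(lengths, m) == pytest.approx((m + 1) / 2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            average_pml([], 0)


class TestCutoff:
    def test_constant_sample(self):
        assert calibrate_cutoff([3.0] * 10) == 3.0

    def test_nearest_rank(self):
        assert calibrate_cutoff(list(range(1, 101)), alpha=0.05) == 95
        assert calibrate_cutoff([1, 2, 3], alpha=0.5) == 2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            calibrate_cutoff([])
        with pytest.raises(ValueError):
            calibrate_cutoff([1.0], alpha=1.5)

    def test_binary_gate_strict(self):
        assert binary_classify(10.0, 3.0)
        assert not binary_classify(3.0, 3.0)  # strictly above
        assert not binary_classify(0.0, 0.5)


class TestReportDocuments:
    def test_tie_keeps_both(self):
        assert report_documents({0: 2, 1: 2}) == [0, 1]

    def test_runner_up_threshold(self):
        assert report_documents({0: 100, 1: 94}) == [0]
        assert report_documents({0: 100, 1: 95}) == [0, 1]  # inclusive >=

    def test_max_extra_caps_report(self):
        scores = {0: 100, 1: 99, 2: 98}
        assert report_documents(scores, max_extra=1) == [0, 1]
        assert report_documents(scores, max_extra=2) == [0, 1, 2]

    def test_empty_and_zero_scores(self):
        assert report_documents({}) == []
        assert report_documents({0: 0, 1: 0}) == []

    def test_best_tie_smallest_id(self):
        assert report_documents({3: 5, 1: 5, 2: 1})[0] == 1


class TestAssignTaxon:
    def test_single_document(self, toy_index, toy_taxonomy):
        assert assign_taxon([0], toy_index.doc_taxa, toy_taxonomy) == 101

    def test_two_species_meet_at_genus(self, toy_index, toy_taxonomy):
        assert assign_taxon([0, 1], toy_index.doc_taxa, toy_taxonomy) == 10

    def test_missing_mapping(self, toy_taxonomy):
        with pytest.raises(KeyError):
            assign_taxon([0], [-1], toy_taxonomy)


class TestClassifyRead:
    def test_toy_composition(self, toy_index):
        engine = QueryEngine(toy_index, RepositionStrategy.ALWAYS_UP)
        rec = classify_read("r1", "AAG", engine, cutoff=0.5)
        assert rec.status == "C"
        assert rec.documents == [0, 1]
        assert rec.taxon_id == 10  # genus LCA of the two species
        assert rec.taxon_rank == "genus"

    def test_gate_blocks_low_average(self, toy_index):
        engine = QueryEngine(toy_index, RepositionStrategy.ALWAYS_UP)
        rec = classify_read("r1", "AAG", engine, cutoff=100.0)
        assert rec.status == "U" and rec.taxon_id is None

    def test_empty_scores_unclassified(self, toy_index):
        engine = QueryEngine(toy_index, RepositionStrategy.ALWAYS_UP)
        rec = classify_read("r1", "TTTT", engine, cutoff=None)
        assert rec.status == "U"

    def test_batch_matches_sequential(self, toy_index):
        reads = [("a", "AAG"), ("b", "AAC"), ("c", "TTT")]
        batch = classify_reads(reads, toy_index, RepositionStrategy.ALWAYS_UP)
        engine = QueryEngine(toy_index, RepositionStrategy.ALWAYS_UP)
        single = [classify_read(rid, seq, engine) for rid, seq in reads]
        assert [(r.status, r.documents, r.taxon_id) for r in batch] == [
            (r.status, r.documents, r.taxon_id) for r in single
        ]
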