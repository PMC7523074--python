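import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oracles import brute_force_scan, sw_reference

from prepromine import motif_search as ms
from prepromine.seqio import SequenceRecord
from prepromine.signal_peptide import SignalAnnotation, predict_signal_peptide
from prepromine.synthetic_data import DEFAULT_FAMILY_MIX, generate_precursor

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


class TestScanMotifs:
    def test_single_hit_example(self):
        rec = SequenceRecord(id="r", residues="QPPGLWGRS")
        motif = ms.MotifDefinition("glw", r"GLWG(KR|R)")
        hits = ms.scan_motifs([rec], [motif])
        assert [(h.start, h.end, h.matched) for h in hits] == [(3, 8, "GLWGR")]

    def test_anchored_motif_needs_signal(self):
        rec = SequenceRecord(id="r", residues="QGLRWGKR" + "A" * 20)
        motif = ms.MotifDefinition("rw", r"Q[A-Z]{0,9}RWG(KR|R)", ms.POST_SIGNAL)
        assert ms.scan_motifs([rec], [motif]) == []
        signals = {"r": SignalAnnotation("r", 0, 0.0)}
        assert len(ms.scan_motifs([rec], [motif], signals)) == 1

    def test_overlapping_matches_reported(self):
        rec = SequenceRecord(id="r", residues="QQ")
        hits = ms.scan_motifs([rec], [ms.MotifDefinition("q", r"Q")])
        assert [(h.start, h.end) for h in hits] == [(0, 1), (1, 2)]

    @pytest.mark.parametrize(
        "pattern",
        [r"GLWG(KR|R)", r"F[A-Z]{1,8}RNG(KR|RR|R)", r"Q{1,3}G?R[WF]"],
    )
    def test_equals_brute_force_on_random_sequences(self, pattern):
        rng = np.random.default_rng(17)
        motif = ms.MotifDefinition("m", pattern)
        for _ in range(20):
            residues = "".join(rng.choice(list("QGRFWLNKA"), size=200))
            rec = SequenceRecord(id="r", residues=residues)
            got = sorted((h.start, h.end) for h in ms.scan_motifs([rec], [motif]))
            assert got == brute_force_scan(pattern, residues)

    def test_bad_pattern_rejected_at_load(self):
        with pytest.raises(ms.MotifConfigError):
            ms.MotifDefinition("bad", r"Q(")

    def test_library_round_trip(self, tmp_path):
        path = tmp_path / "motifs.tsv"
        ms.write_motif_library(ms.DEFAULT_MOTIFS, path)
        back = ms.read_motif_library(path)
        assert tuple(back) == ms.DEFAULT_MOTIFS


class TestSearchByAlignment:
    def test_exact_substring_scores_diagonal_sum(self):
        target = SequenceRecord(id="t", residues="AAAAQGLRWGKRFFLLAAAA")
        query = SequenceRecord(id="q", residues="QGLRWGKRFFLL")
        hits = ms.search_by_alignment([query], [target], min_score=10)
        assert len(hits) == 1
        expected = sum(BLOSUM62[a, a] for a in query.residues)
        assert hits[0].score == expected
        assert hits[0].identity == 1.0

    def test_dissimilar_pair_below_threshold(self):
        q = SequenceRecord(id="q", residues="QGRF")
        t = SequenceRecord(id="t", residues="AAAA")
        assert ms.search_by_alignment([q], [t], min_score=20) == []

    def test_score_symmetry(self):
        a, b = "QGLRWGKRFFLL", "QGRFGREDQGRF"
        assert ms.local_alignment_score(a, b) == ms.local_alignment_score(b, a)

    def test_equals_dp_reference_on_short_pairs(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(5, 50))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(5, 50))))
            assert ms.local_alignment_score(a, b) == pytest.approx(sw_reference(a, b))


class TestFindSingleCopy:
    def _planted(self, rng, family_id):
        spec = next(s for s in DEFAULT_FAMILY_MIX if s.family_id == family_id)
        rec, entry = generate_precursor(spec, rng, f"single_{family_id}")
        ann = predict_signal_peptide(rec.residues, rec.id)
        return rec, entry, {rec.id: ann}

    @pytest.mark.parametrize(
        "family_id,expected",
        [
            (7, "phelac-LRNamide"),
            (8, "phelac-YRVamide"),
            (9, "phelac-FKAamide"),
            (10, "pQGLRWamide"),
        ],
    )
    def test_planted_single_copy_recovered(self, rng, family_id, expected):
        rec, entry, signals = self._planted(rng, family_id)
        calls = ms.find_single_copy([rec], signals=signals)
        assert len(calls) == 1
        call = calls[0]
        assert call.top_copy_number == 1
        assert call.completeness == "complete"
        assert call.matured[0].display == expected

    def test_multicopy_record_excluded(self, rng):
        # three identical post-signal copies: the exclusivity rule applies
        spec = next(s for s in DEFAULT_FAMILY_MIX if s.family_id == 10)
        rec, _ = generate_precursor(spec, rng, "multi")
        extra = rec.residues + ("QGLRWGKR" * 2)
        rec2 = SequenceRecord(id="multi", residues=extra)
        ann = predict_signal_peptide(rec2.residues, rec2.id)
        assert ms.find_single_copy([rec2], signals={"multi": ann}) == []

    def test_no_signal_no_call(self):
        rec = SequenceRecord(id="x", residues="QGLRWGKR" + "A" * 30)
        assert ms.find_single_copy([rec], signals={}) == []
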