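
import numpy as np
import pytest

from oracles import lcs_len, oracle_sites

from prepromine import precursor_scan as ps
from prepromine.synthetic_data import PrecursorSpec, generate_precursor
from prepromine.signal_peptide import predict_signal_peptide


class TestFindProcessingSites:
    @pytest.mark.parametrize(
        "residues,expected",
        [
            ("QGRFGRE", [(2, 3, "R", True), (5, 6, "R", True)]),
            ("AAAA", []),
            ("PGLWGKRS", [(5, 7, "KR", True)]),
            ("AKRRA", [(1, 3, "KR", False)]),  # KRR run: one dibasic, no extra mono
            ("AKA", []),  # isolated K is not a site
            ("AGRRA", [(2, 4, "RR", True)]),
        ],
    )
    def test_examples(self, residues, expected):
        got = [
            (s.basic_start, s.basic_end, s.kind, s.amidation_donor)
            for s in ps.find_processing_sites(residues)
        ]
        assert got == expected

    def test_matches_enumeration_oracle_on_random_sequences(self):
        rng = np.random.default_rng(11)
        # K/R/G-rich alphabet to hit many overlapping runs
        alphabet = list("KRGAEQF")
        for _ in range(200):
            residues = "".join(rng.choice(alphabet, size=int(rng.integers(5, 60))))
            got = [
                (s.basic_start, s.basic_end, s.kind, s.amidation_donor)
                for s in ps.find_processing_sites(residues)
            ]
            assert got == oracle_sites(residues), residues


class TestPeptideIdentity:
    def test_matches_lcs_dp_reference(self):
        rng = np.random.default_rng(3)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(100):
            a = "".join(rng.choice(alphabet, size=int(rng.integers(1, 25))))
            b = "".join(rng.choice(alphabet, size=int(rng.integers(1, 25))))
            assert ps.peptide_identity(a, b) == pytest.approx(
                lcs_len(a, b) / max(len(a), len(b))
            )


class TestClusterPeptides:
    def _peptides(self, seqs):
        site = ps.ProcessingSite(0, 1, "R", True)
        return [
            ps.CandidatePeptide("r", 0, len(s), s, False, site) for s in seqs
        ]

    def test_identical_sequences_single_cluster(self):
        clusters = ps.cluster_peptides(self._peptides(["QGRFG"] * 3))
        assert len(clusters) == 1
        assert len(clusters[0]) == 3
        assert clusters[0].representative == "QGRFG"
        assert clusters[0].mean_identity == 1.0

    def test_dissimilar_sequences_stay_apart(self):
        # alignment identity 2/5 = 0.4 < 0.6
        clusters = ps.cluster_peptides(self._peptides(["QGRFG", "APRGG"]))
        assert [len(c) for c in clusters] == [1, 1]

    def test_order_invariance(self):
        seqs = ["QGRFG", "QGRFG", "EQGRFG", "APRGG", "QGRFG"]
        base = ps.cluster_peptides(self._peptides(seqs))
        perm = ps.cluster_peptides(self._peptides(seqs[::-1]))
        assert [sorted(p.residues for p in c.members) for c in base] == [
            sorted(p.residues for p in c.members) for c in perm
        ]


class TestSegmentPeptides:
    def test_repeat_consistent_segmentation(self):
        residues = "QGRFGRE" * 3
        sites = ps.find_processing_sites(residues)
        peptides = ps.segment_peptides(residues, sites)
        assert [p.end for p in peptides] == [5, 12, 19]  # internal GRs not selected
        assert peptides[0].residues == "QGRFG"
        assert all(p.residues.endswith("QGRFG") for p in peptides)

    def test_single_site_single_peptide(self):
        residues = "DDDDQGLWGR"
        sites = ps.find_processing_sites(residues)
        peptides = ps.segment_peptides(residues, sites)
        assert len(peptides) == 1
        assert (peptides[0].start, peptides[0].end) == (0, 9)

    def test_no_sites_no_peptides(self):
        assert ps.segment_peptides("AAAA", []) == []

    def test_overlong_span_truncated_at_max(self):
        residues = "L" * 40 + "GR"
        sites = ps.find_processing_sites(residues)
        peptides = ps.segment_peptides(residues, sites)
        assert len(peptides) == 1
        assert peptides[0].end - peptides[0].start == ps.DEFAULT_MAX_PEPTIDE_LEN

    def test_overlong_span_truncated_after_acidic(self):
        residues = "L" * 12 + "E" + "L" * 28 + "GR"
        sites = ps.find_processing_sites(residues)
        peptides = ps.segment_peptides(residues, sites)
        assert len(peptides) == 1
        assert peptides[0].start == 13  # right after the acidic residue

    def test_spans_are_substrings_and_disjoint(self, rng):
        for i in range(10):
            spec = PrecursorSpec(2, "QGRF", 5, substitution_rate=0.1)
            rec, _ = generate_precursor(spec, rng, f"r{i}")
            sites = ps.find_processing_sites(rec.residues)
            peptides = ps.segment_peptides(rec.residues, sites, record_id=rec.id)
            prev_end = 0
            for p in sorted(peptides, key=lambda q: q.start):
                assert rec.residues[p.start : p.end] == p.residues
                assert p.start >= prev_end
                prev_end = p.end

    def test_greedy_equals_exhaustive_on_generator_records(self, rng):
        specs = [
            PrecursorSpec(2, "QGRF", 4),
            PrecursorSpec(1, "GPRG", 5),
            PrecursorSpec(3, "QQPPGLW", 4),
            PrecursorSpec(4, "LPPGPLPRP", 3),
            PrecursorSpec(5, "QSITRF", 5),
            PrecursorSpec(6, "QPPYLDLTPSYFHIR", 3),
        ]
        for i, spec in enumerate(specs):
            rec, _ = generate_precursor(spec, rng, f"g{i}")
            signal = predict_signal_peptide(rec.residues, rec.id)
            sites = ps.find_processing_sites(rec.residues)
            assert sum(s.kind == "R" for s in sites) <= 20
            exhaustive = ps.segment_peptides(
                rec.residues, sites, signal, record_id=rec.id, strategy="exhaustive"
            )
            greedy = ps.segment_peptides(
                rec.residues, sites, signal, record_id=rec.id, strategy="greedy"
            )
            assert [(p.start, p.end) for p in exhaustive] == [
                (p.start, p.end) for p in greedy
            ]


class TestCallMulticopy:
    def test_planted_precursor_called_complete(self, rng):
        spec = PrecursorSpec(2, "QGRF", 5)
        rec, entry = generate_precursor(spec, rng, "p0")
        signal = predict_signal_peptide(rec.residues, rec.id)
        call = ps.call_multicopy(rec, signal)
        assert call is not None
        assert call.top_copy_number == 5
        assert call.completeness == "complete"
        assert call.n_amidated_sites >= 3

    def test_two_copies_not_called(self, rng):
        spec = PrecursorSpec(2, "QGRF", 2)
        rec, _ = generate_precursor(spec, rng, "p0")
        signal = predict_signal_peptide(rec.residues, rec.id)
        assert ps.call_multicopy(rec, signal) is None

    def test_missing_signal_caps_completeness(self, rng):
        spec = PrecursorSpec(2, "QGRF", 5)
        rec, _ = generate_precursor(spec, rng, "p0")
        call = ps.call_multicopy(rec, signal=None)
        assert call is not None
        assert call.completeness == "fragment"

    def test_calls_stable_across_runs(self, rng):
        spec = PrecursorSpec(5, "QSITRF", 6, substitution_rate=0.1)
        rec, _ = generate_precursor(spec, rng, "p0")
        a = ps.call_multicopy(rec, None)
        b = ps.call_multicopy(rec, None)
        assert a == b
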