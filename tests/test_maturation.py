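import pytest
from hypothesis import given, settings, strategies as st

from prepromine import maturation as mat
from prepromine.precursor_scan import CandidatePeptide, ProcessingSite

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_candidate(residues: str, follows_signal: bool = False) -> CandidatePeptide:
    site = ProcessingSite(len(residues), len(residues) + 1, "R", residues.endswith("G"))
    return CandidatePeptide("rec", 0, len(residues), residues, follows_signal, site)


class TestTrimNTerminus:
    @pytest.mark.parametrize(
        "before,after",
        [
            ("EDQGRFG", "QGRFG"),   # acidic trimmed, pQ precursor protects
            ("QGRFG", "QGRFG"),     # already protected
            ("GPRGG", "GPRGG"),     # X-P protection at position 2
            ("ATEFGPRG", "GPRG"),   # F precedes a protected motif, so it goes too
            ("STSAGLW", "GLW"),     # hydrophilic/small residues trimmed to the floor
        ],
    )
    def test_examples(self, before, after):
        assert mat.trim_n_terminus(before) == after

    def test_never_below_min_core_len(self):
        assert len(mat.trim_n_terminus("EEEE")) >= mat.DEFAULT_RULES.min_core_len

    @given(st.text(alphabet=AA, min_size=1, max_size=25))
    @settings(max_examples=200, deadline=None)
    def test_protected_motifs_never_trimmed(self, residues):
        trimmed = mat.trim_n_terminus(residues)
        # result is a suffix, respects the length floor, and a protected
        # input is returned unchanged
        assert residues.endswith(trimmed)
        assert len(trimmed) >= min(len(residues), mat.DEFAULT_RULES.min_core_len)
        if mat.is_protected(residues):
            assert trimmed == residues

    def test_trim_set_excludes_protecting_residues(self):
        with pytest.raises(ValueError):
            mat.ProcessingRules(trim_set=frozenset("DEQ"))


class TestMaturePeptide:
    def test_pyroglutamate_amidated(self):
        p = mat.mature_peptide(make_candidate("QGRFG"))
        assert (p.core, p.n_mod, p.c_amidated) == ("QGRF", "pyroglutamate", True)
        assert p.display == "pQGRFamide"

    def test_phenyllactyl_after_signal(self):
        p = mat.mature_peptide(make_candidate("FYRVG", follows_signal=True))
        assert (p.core, p.n_mod, p.c_amidated) == ("FYRV", "phenyllactyl", True)
        assert p.display == "phelac-YRVamide"

    def test_initial_f_unmodified_away_from_signal(self):
        p = mat.mature_peptide(make_candidate("FYRVG", follows_signal=False))
        assert p.n_mod == "none"

    def test_non_amidated_when_no_donor(self):
        p = mat.mature_peptide(make_candidate("QGRF"))
        assert (p.display, p.c_amidated) == ("pQGRF", False)

    def test_trimming_then_pyroglutamate(self):
        p = mat.mature_peptide(make_candidate("EDQGRFG"))
        assert p.display == "pQGRFamide"

    def test_core_is_contiguous_substring_of_immature(self):
        for residues in ["EDQGRFG", "ATEFGPRGG", "STSAGLWG", "QGRF"]:
            p = mat.mature_peptide(make_candidate(residues))
            assert p.core in residues

    def test_idempotent_on_mature_core(self):
        # a matured core (no donor G left) passes through unchanged
        for display_core in ["QGRF", "QSITRF", "LPPGPLPRP"]:
            p = mat.mature_peptide(make_candidate(display_core))
            assert p.core == display_core


class TestDigestProhormone:
    def test_rfamide_dimer_resolves_to_monomers(self):
        peps = mat.digest_prohormone("QGRFGREDQGRFGR")
        assert [p.display for p in peps] == ["pQGRFamide", "pQGRFamide"]

    def test_prgamide_dimer_resolves_to_monomers(self):
        peps = mat.digest_prohormone("GPRGGRATEFGPRGGR")
        assert [p.display for p in peps] == ["GPRGamide", "GPRGamide"]

    def test_no_sites_no_peptides(self):
        assert mat.digest_prohormone("AAAA") == []

    def test_acid_flanked_monobasic_splits_candidate(self):
        # a single terminating site, with an internal R|E convertase site
        cand = make_candidate("QGRFGREDQGRFG")
        pieces = mat._acid_split(cand, cand.residues)
        assert [p.residues for p in pieces] == ["QGRFG", "EDQGRFG"]


class TestDisplayFormat:
    @pytest.mark.parametrize(
        "core,n_mod,c_amidated,expected",
        [
            ("QGRF", "pyroglutamate", True, "pQGRFamide"),
            ("GPRG", "none", True, "GPRGamide"),
            ("QGRF", "pyroglutamate", False, "pQGRF"),
            ("FLRN", "phenyllactyl", True, "phelac-LRNamide"),
        ],
    )
    def test_format(self, core, n_mod, c_amidated, expected):
        assert mat.format_peptide(mat.MaturePeptide(core, n_mod, c_amidated)) == expected

    @given(
        core=st.text(alphabet=AA, min_size=1, max_size=20),
        n_mod=st.sampled_from(["none", "pyroglutamate", "phenyllactyl"]),
        c_amidated=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, core, n_mod, c_amidated):
        if n_mod == "pyroglutamate":
            core = "Q" + core[1:]
        elif n_mod == "phenyllactyl":
            core = "F" + core[1:]
        p = mat.MaturePeptide(core, n_mod, c_amidated)
        parsed = mat.parse_peptide(mat.format_peptide(p))
        assert (parsed.core, parsed.n_mod, parsed.c_amidated) == (
            p.core,
            p.n_mod,
            p.c_amidated,
        )

    def test_invalid_modification_state_rejected(self):
        with pytest.raises(ValueError):
            mat.MaturePeptide("GRF", "pyroglutamate", True)
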