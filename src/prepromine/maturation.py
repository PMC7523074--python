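"""Peptide maturation chemistry.

Immature peptide copies excised from a prohormone are converted into
predicted mature neuropeptides:

* C-terminus: a glycine left at the end of the span (immediately before
  the basic cleavage site) is turned into a C-terminal amide by
  peptidylglycine monooxygenase — the G is removed and the peptide is
  flagged amidated.
* N-terminus: unspecific aminopeptidases trim residues until a
  protecting motif is reached — an N-terminal glutamine (which cyclizes
  to pyroglutamate, pQ) or a proline at position 2 (X-P, which covers
  X-P-P). A phenylalanine positioned directly after the signal peptide
  is instead converted to an L-3-phenyllactyl group (phelac) inside the
  rough ER, before any trimming can occur.

The trim set is D/E (acidic), S/T (hydrophilic) plus A/G; additionally
any residue directly preceding a protected motif may be removed, which
is what resolves processing intermediates such as ...ATEF|GPRGamide to
the protected mature peptide.
"""

from __future__ import annotations

from dataclasses import dataclass

from .precursor_scan import (
    ACIDIC,
    CandidatePeptide,
    ProcessingSite,
    ScanParams,
    find_processing_sites,
    segment_peptides,
)
from .signal_peptide import SignalAnnotation

N_NONE = "none"
N_PYROGLUTAMATE = "pyroglutamate"
N_PHENYLLACTYL = "phenyllactyl"


class DegeneratePeptideError(ValueError):
    """A candidate peptide with an empty core after processing."""


@dataclass(frozen=True)
class ProcessingRules:
    """Tunable maturation chemistry.

    ``trim_set`` are the residues freely removable from the N-terminus;
    Q and P are excluded by construction since they form the protecting
    motifs that stop trimming.
    """

    trim_set: frozenset = frozenset("DESTAG")
    amide_donor: str = "G"
    basic_set: frozenset = frozenset("KR")
    min_core_len: int = 3

    def __post_init__(self) -> None:
        if self.trim_set & {"Q", "P"}:
            raise ValueError("trim_set must not contain the protecting residues Q/P")


DEFAULT_RULES = ProcessingRules()


@dataclass(frozen=True)
class MaturePeptide:
    """A processed peptide: ``core`` keeps the first residue even when it
    is modified (Q of pQ, F of phelac)."""

    core: str
    n_mod: str  # none | pyroglutamate | phenyllactyl
    c_amidated: bool
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.n_mod == N_PYROGLUTAMATE and not self.core.startswith("Q"):
            raise ValueError("pyroglutamate requires a Q core start")
        if self.n_mod == N_PHENYLLACTYL and not self.core.startswith("F"):
            raise ValueError("phenyllactyl requires an F core start")

    @property
    def display(self) -> str:
        return format_peptide(self)


def is_protected(residues: str) -> bool:
    """Q first (pyroglutamate precursor) or P at position 2 (X-P; the
    X-P-P motif is a special case of X-P)."""
    if not residues:
        return False
    return residues[0] == "Q" or (len(residues) >= 2 and residues[1] == "P")


def trim_n_terminus(residues: str, rules: ProcessingRules = DEFAULT_RULES) -> str:
    """Aminopeptidase trimming of the N-terminus.

    The first residue is removed while (a) no protecting motif holds,
    (b) it is in the trim set or the remainder would itself be
    protected, and (c) the peptide stays longer than ``min_core_len``.
    """
    if not residues:
        raise DegeneratePeptideError("empty peptide")
    while (
        len(residues) > rules.min_core_len
        and not is_protected(residues)
        and (residues[0] in rules.trim_set or is_protected(residues[1:]))
    ):
        residues = residues[1:]
    return residues


def mature_peptide(
    candidate: CandidatePeptide, rules: ProcessingRules = DEFAULT_RULES
) -> MaturePeptide:
    """Convert an immature candidate span into a predicted mature peptide."""
    immature = candidate.residues
    if not immature:
        raise DegeneratePeptideError(f"{candidate.record_id}: empty candidate span")
    if immature.endswith(rules.amide_donor):
        c_amidated = True
        core = immature[:-1]
    else:
        c_amidated = False
        core = immature
    if not core:
        raise DegeneratePeptideError(f"{candidate.record_id}: core empty after amidation")
    if candidate.follows_signal and core[0] == "F":
        n_mod = N_PHENYLLACTYL
    elif core[0] == "Q":
        n_mod = N_PYROGLUTAMATE
    else:
        core = trim_n_terminus(core, rules)
        n_mod = N_PYROGLUTAMATE if core[0] == "Q" else N_NONE
    return MaturePeptide(
        core=core,
        n_mod=n_mod,
        c_amidated=c_amidated,
        provenance=f"{candidate.record_id}:{candidate.start}-{candidate.end}",
    )


def _acid_split(candidate: CandidatePeptide, residues: str) -> list[CandidatePeptide]:
    """Cleave a candidate span internally at monobasic R sites that are
    immediately followed by D or E.

    The cnidarian prohormone convertase cleaves between R and an acidic
    residue, so a span like QGRFG·R·EDQGRFG (a dimeric processing
    intermediate) resolves into its two monomers.
    """
    pieces: list[CandidatePeptide] = []
    start = candidate.start
    for p in range(candidate.start + 1, candidate.end - 1):
        if residues[p] == "R" and residues[p + 1] in ACIDIC and p > start:
            site = ProcessingSite(
                basic_start=p,
                basic_end=p + 1,
                kind="R",
                amidation_donor=residues[p - 1] == "G",
            )
            pieces.append(
                CandidatePeptide(
                    record_id=candidate.record_id,
                    start=start,
                    end=p,
                    residues=residues[start:p],
                    follows_signal=candidate.follows_signal and start == candidate.start,
                    site_ref=site,
                )
            )
            start = p + 1
    if start == candidate.start:
        return [candidate]
    pieces.append(
        CandidatePeptide(
            record_id=candidate.record_id,
            start=start,
            end=candidate.end,
            residues=residues[start : candidate.end],
            follows_signal=False,
            site_ref=candidate.site_ref,
        )
    )
    return pieces


def digest_prohormone(
    residues: str,
    signal: SignalAnnotation | None = None,
    rules: ProcessingRules = DEFAULT_RULES,
    params: ScanParams = ScanParams(),
    record_id: str = "",
) -> list[MaturePeptide]:
    """Full maturation pass over a prohormone sequence.

    Runs site finding, repeat-consistent segmentation, internal
    acid-flanked monobasic cleavage (so dimeric intermediates resolve to
    monomers), and per-candidate maturation.
    """
    sites = find_processing_sites(residues)
    candidates = segment_peptides(residues, sites, signal, params, record_id=record_id)
    matured: list[MaturePeptide] = []
    for cand in candidates:
        for piece in _acid_split(cand, residues):
            matured.append(mature_peptide(piece, rules))
    return matured


def format_peptide(p: MaturePeptide) -> str:
    """Canonical display string: pQGRFamide, phelac-YRVamide, GPRGamide, pQGRF..."""
    if p.n_mod == N_PYROGLUTAMATE:
        body = "pQ" + p.core[1:]
    elif p.n_mod == N_PHENYLLACTYL:
        body = "phelac-" + p.core[1:]
    else:
        body = p.core
    return body + ("amide" if p.c_amidated else "")


def parse_peptide(display: str) -> MaturePeptide:
    """Invert :func:`format_peptide`."""
    c_amidated = display.endswith("amide")
    body = display[: -len("amide")] if c_amidated else display
    if body.startswith("pQ"):
        return MaturePeptide("Q" + body[2:], N_PYROGLUTAMATE, c_amidated)
    if body.startswith("phelac-"):
        return MaturePeptide("F" + body[len("phelac-"):], N_PHENYLLACTYL, c_amidated)
    return MaturePeptide(body, N_NONE, c_amidated)
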