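"""Single-copy precursor search: motif grammar plus alignment homology.

Multi-copy calling misses precursors that carry exactly one neuropeptide
(the Antho-RWamides and the phenyllactyl peptides), so those are found
by pattern matching — a motif in precursor form, mature C-terminus plus
the amidation/cleavage signal G(KR|RR|R), anchored directly after the
signal peptide — and, complementarily, by local-alignment homology
against known neuropeptide queries (BLOSUM62, affine gaps with the
BLAST protein defaults: a gap of length k costs 11 + k).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .precursor_scan import (
    BASIC,
    CandidatePeptide,
    PeptideCluster,
    PreprohormoneCall,
    ProcessingSite,
    ScanParams,
    find_processing_sites,
    peptide_identity,
    segment_peptides,
)
from .maturation import DEFAULT_RULES, ProcessingRules, mature_peptide
from .signal_peptide import SignalAnnotation

POST_SIGNAL = "post_signal"
ANYWHERE = "anywhere"

# Longest substring a motif is allowed to match; bounds the per-start
# enumeration of match ends so that overlapping matches of every length
# are reported, matching a brute-force all-substring scan.
MAX_MOTIF_SPAN = 40

POST_SIGNAL_WINDOW = 2


class MotifConfigError(ValueError):
    """A motif pattern that does not compile, or a malformed library file."""


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    pattern: str
    anchor: str = ANYWHERE  # post_signal | anywhere
    family_id: int | None = None

    def __post_init__(self) -> None:
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise MotifConfigError(f"motif {self.name!r}: {exc}") from exc
        if self.anchor not in (POST_SIGNAL, ANYWHERE):
            raise MotifConfigError(f"motif {self.name!r}: unknown anchor {self.anchor!r}")

    @property
    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    record_id: str
    start: int
    end: int
    matched: str
    motif_name: str


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    score: float
    identity: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]


# Precursor-form patterns for the ten hexacorallian families,
# reconstructed from each family's reported consensus. Families with
# single-copy precursors are anchored directly after the signal peptide.
DEFAULT_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition("XPRXamide_precursor", r"[A-Z]PR[GSAP]G(KR|RR|R)", ANYWHERE, 1),
    MotifDefinition("GRFamide_precursor", r"QGRFG(KR|RR|R)", ANYWHERE, 2),
    MotifDefinition("GLWamide_precursor", r"G[LV]WG(KR|RR|R)", ANYWHERE, 3),
    MotifDefinition("RPamide_precursor", r"[A-Z]RPG(KR|RR|R)", ANYWHERE, 4),
    MotifDefinition("TRFamide_precursor", r"TR[FIY]G(KR|RR|R)", ANYWHERE, 5),
    MotifDefinition("FHIRamide_precursor", r"[FY]G?HIRG(KR|RR|R)", ANYWHERE, 6),
    MotifDefinition("phelac_RNamide_precursor", r"F[A-Z]{1,8}RNG(KR|RR|R)", POST_SIGNAL, 7),
    MotifDefinition("phelac_RIamide_precursor", r"F[A-Z]{1,8}(R[IV]|KI)G(KR|RR|R)", POST_SIGNAL, 8),
    MotifDefinition("phelac_KAamide_precursor", r"F[A-Z]{1,8}KAG(KR|RR|R)", POST_SIGNAL, 9),
    MotifDefinition("RWamide_precursor", r"[QF][A-Z]{0,9}R[WF]G(KR|RR|R)", POST_SIGNAL, 10),
)


def read_motif_library(path) -> list[MotifDefinition]:
    """One motif per line: ``name <TAB> anchor <TAB> family_id <TAB> pattern``.
    '#' comments and blank lines are ignored; family_id '-' means none."""
    motifs: list[MotifDefinition] = []
    with open(Path(path)) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise MotifConfigError(f"{path}:{lineno}: expected 4 tab-separated fields")
            name, anchor, family, pattern = parts
            family_id = None if family.strip() == "-" else int(family)
            motifs.append(MotifDefinition(name.strip(), pattern.strip(), anchor.strip(), family_id))
    return motifs


def write_motif_library(motifs, path) -> None:
    with open(Path(path), "wt") as out:
        out.write("# name\tanchor\tfamily_id\tpattern\n")
        for m in motifs:
            fam = "-" if m.family_id is None else str(m.family_id)
            out.write(f"{m.name}\t{m.anchor}\t{fam}\t{m.pattern}\n")


def _matches_at(pattern: re.Pattern, residues: str, start: int) -> list[int]:
    """All match end positions for matches beginning at ``start``."""
    ends = []
    hi = min(len(residues), start + MAX_MOTIF_SPAN)
    for end in range(start + 1, hi + 1):
        if pattern.fullmatch(residues, start, end):
            ends.append(end)
    return ends


def scan_motifs(
    records,
    motifs=DEFAULT_MOTIFS,
    signals: dict[str, SignalAnnotation] | None = None,
) -> list[MotifHit]:
    """All motif matches, including overlapping ones and every match
    length at a shared start (equivalent to testing every substring).

    post_signal-anchored motifs require a signal annotation for the
    record and only match within ``POST_SIGNAL_WINDOW`` residues of the
    signal cleavage position.
    """
    signals = signals or {}
    hits: list[MotifHit] = []
    for rec in records:
        for motif in motifs:
            pattern = motif.compiled
            if motif.anchor == POST_SIGNAL:
                ann = signals.get(rec.id)
                if ann is None:
                    continue
                starts = range(
                    ann.mature_start,
                    min(ann.mature_start + POST_SIGNAL_WINDOW + 1, len(rec.residues)),
                )
            else:
                # candidate starts via zero-width lookahead, then all
                # admissible ends at each start
                starts = sorted(
                    {
                        m.start()
                        for m in re.finditer(f"(?=({motif.pattern}))", rec.residues)
                    }
                )
            for start in starts:
                for end in _matches_at(pattern, rec.residues, start):
                    hits.append(
                        MotifHit(
                            record_id=rec.id,
                            start=start,
                            end=end,
                            matched=rec.residues[start:end],
                            motif_name=motif.name,
                        )
                    )
    return hits


def _make_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST convention: a length-k gap costs 11 + k
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner

_LOCAL_ALIGNER = _make_local_aligner()


def local_alignment_score(a: str, b: str) -> float:
    """Optimal local alignment score (BLOSUM62, gap open 11 / extend 1)."""
    return float(_LOCAL_ALIGNER.score(a, b))


def search_by_alignment(queries, targets, min_score: float = 40.0) -> list[AlignmentHit]:
    """Local-alignment homology hits with score >= min_score, sorted by
    score descending (ties: query id, target id)."""
    hits: list[AlignmentHit] = []
    for query in queries:
        for target in targets:
            score = local_alignment_score(query.residues, target.residues)
            if score < min_score:
                continue
            aln = _LOCAL_ALIGNER.align(query.residues, target.residues)[0]
            qseq, tseq = aln[0], aln[1]
            matches = sum(1 for x, y in zip(qseq, tseq) if x == y and x != "-")
            identity = matches / len(qseq) if len(qseq) else 0.0
            q_aligned = aln.aligned[0]
            t_aligned = aln.aligned[1]
            hits.append(
                AlignmentHit(
                    query_id=query.id,
                    target_id=target.id,
                    score=score,
                    identity=identity,
                    query_span=(int(q_aligned[0][0]), int(q_aligned[-1][1])),
                    target_span=(int(t_aligned[0][0]), int(t_aligned[-1][1])),
                )
            )
    hits.sort(key=lambda h: (-h.score, h.query_id, h.target_id))
    return hits


def _ends_at_cleavage(matched: str) -> bool:
    """The motif hit must end in the amidation-capable signal G + basic."""
    if len(matched) < 3:
        return False
    if matched.endswith(("KR", "RR")):
        return matched[-3] == "G"
    return matched[-1] == "R" and matched[-2] == "G"


def _immature_span(hit: MotifHit, residues: str) -> tuple[int, int]:
    """Strip the basic residues from a hit, keeping the donor G."""
    end = hit.end
    while end > hit.start and residues[end - 1] in BASIC:
        end -= 1
    return hit.start, end


def find_single_copy(
    records,
    motifs=DEFAULT_MOTIFS,
    signals: dict[str, SignalAnnotation] | None = None,
    rules: ProcessingRules = DEFAULT_RULES,
    params: ScanParams = ScanParams(),
) -> list[PreprohormoneCall]:
    """Single-copy preprohormone calls from post-signal motif hits.

    A call is emitted when a post_signal-anchored motif matches directly
    after the signal cleavage, ends at a G+basic site, and the record
    contains no additional similar peptide copy (the single-copy /
    multi-copy call sets are disjoint per record).
    """
    signals = signals or {}
    post_signal = [m for m in motifs if m.anchor == POST_SIGNAL]
    calls: list[PreprohormoneCall] = []
    for rec in records:
        ann = signals.get(rec.id)
        if ann is None:
            continue
        hits = scan_motifs([rec], post_signal, signals)
        hits = [h for h in hits if _ends_at_cleavage(h.matched)]
        if not hits:
            continue
        # longest admissible hit wins; ties by motif order in the library
        order = {m.name: i for i, m in enumerate(post_signal)}
        hits.sort(key=lambda h: (-(h.end - h.start), order.get(h.motif_name, 99)))
        hit = hits[0]
        start, end = _immature_span(hit, rec.residues)
        immature = rec.residues[start:end]

        # exclusivity: no other similar copy anywhere in the record
        sites = find_processing_sites(rec.residues)
        others = [
            p
            for p in segment_peptides(rec.residues, sites, ann, params, record_id=rec.id)
            if not (p.start == start and p.end == end)
        ]
        if any(
            peptide_identity(immature, p.residues) >= params.identity_threshold
            for p in others
        ):
            continue
        site = ProcessingSite(
            basic_start=end,
            basic_end=hit.end,
            kind=rec.residues[end : hit.end] if hit.end - end == 2 else "R",
            amidation_donor=rec.residues[end - 1] == "G",
        )
        candidate = CandidatePeptide(
            record_id=rec.id,
            start=start,
            end=end,
            residues=immature,
            follows_signal=True,
            site_ref=site,
        )
        matured = mature_peptide(candidate, rules)
        cluster = PeptideCluster(
            members=(candidate,), representative=immature, mean_identity=1.0
        )
        calls.append(
            PreprohormoneCall(
                record_id=rec.id,
                signal=ann,
                n_amidated_sites=sum(s.amidation_donor for s in sites),
                clusters=(cluster,),
                top_copy_number=1,
                completeness="complete",
                peptides=(candidate,),
                matured=(matured,),
            )
        )
    return calls
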