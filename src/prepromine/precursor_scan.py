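"""Multi-copy preprohormone calling.

Cnidarian neuropeptide precursors carry many identical or similar
peptide copies, each ending in an amidation-donor glycine followed by a
prohormone-convertase cleavage site (GKR, GRR, GR). This module
implements the caller: locate basic cleavage sites, choose a
repeat-consistent subset of them (monobasic R sites are ambiguous —
an R inside a peptide like QGRF must not be cleaved), cluster the
delimited peptides by similarity, and emit a call when a record has at
least ``min_sites`` amidated sites and a cluster of at least
``min_copies`` similar peptides.

Similarity between two peptides is the number of matches in an optimal
global alignment scored match=1, mismatch=0, gap=0 — i.e. the length of
the longest common subsequence — divided by the longer length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import combinations

import numpy as np
from Bio import Align
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .signal_peptide import SignalAnnotation

BASIC = set("KR")
ACIDIC = set("DE")

DEFAULT_MIN_SITES = 3
DEFAULT_MIN_COPIES = 3
DEFAULT_IDENTITY_THRESHOLD = 0.6
DEFAULT_MAX_PEPTIDE_LEN = 30
# immature span floor: maturation min core (3) + the amide-donor G
MIN_PEPTIDE_LEN = 4
DEFAULT_EXHAUSTIVE_LIMIT = 12
POST_SIGNAL_WINDOW = 2


@dataclass(frozen=True)
class ProcessingSite:
    """A basic cleavage site. ``[basic_start, basic_end)`` covers the
    basic residue(s); ``amidation_donor`` marks a G immediately before."""

    basic_start: int
    basic_end: int
    kind: str  # KR | RR | R
    amidation_donor: bool
    selected: bool = True


@dataclass(frozen=True)
class CandidatePeptide:
    """An immature peptide span: includes its amide-donor G, excludes
    the basic residues of the site that terminates it."""

    record_id: str
    start: int
    end: int
    residues: str
    follows_signal: bool
    site_ref: ProcessingSite


@dataclass(frozen=True)
class PeptideCluster:
    members: tuple[CandidatePeptide, ...]
    representative: str
    mean_identity: float

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PreprohormoneCall:
    record_id: str
    signal: SignalAnnotation | None
    n_amidated_sites: int
    clusters: tuple[PeptideCluster, ...]
    top_copy_number: int
    completeness: str  # complete | fragment
    peptides: tuple[CandidatePeptide, ...] = field(default=())
    # filled by the maturation stage (pipeline) or by find_single_copy
    matured: tuple = field(default=())


@dataclass(frozen=True)
class ScanParams:
    min_sites: int = DEFAULT_MIN_SITES
    min_copies: int = DEFAULT_MIN_COPIES
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    max_peptide_len: int = DEFAULT_MAX_PEPTIDE_LEN
    min_peptide_len: int = MIN_PEPTIDE_LEN
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT


def _make_lcs_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner

_LCS_ALIGNER = _make_lcs_aligner()


@lru_cache(maxsize=1 << 18)
def _lcs_len(a: str, b: str) -> int:
    if not a or not b:
        return 0
    return int(_LCS_ALIGNER.score(a, b))


def peptide_identity(a: str, b: str) -> float:
    """Matches in an optimal (match 1 / mismatch 0 / gap 0) global
    alignment, normalized by the longer length."""
    if not a or not b:
        return 0.0
    if a > b:
        a, b = b, a
    return _lcs_len(a, b) / max(len(a), len(b))


def find_processing_sites(residues: str) -> list[ProcessingSite]:
    """All prohormone-convertase sites: KR and RR dibasic pairs and
    isolated monobasic R.

    Within a run of consecutive K/R residues, dibasic pairs are taken
    greedily left to right; a leftover single basic residue in a run
    that already yielded a dibasic site is not reported again (KRR is
    one KR site, not KR + R). An isolated K is not a cleavage site.
    """
    sites: list[ProcessingSite] = []
    n = len(residues)
    i = 0
    while i < n:
        if residues[i] not in BASIC:
            i += 1
            continue
        run_start = i
        while i < n and residues[i] in BASIC:
            i += 1
        run = residues[run_start:i]
        j = 0
        emitted_dibasic = False
        while j < len(run):
            pair = run[j : j + 2]
            if pair in ("KR", "RR"):
                start = run_start + j
                sites.append(
                    ProcessingSite(
                        basic_start=start,
                        basic_end=start + 2,
                        kind=pair,
                        amidation_donor=start > 0 and residues[start - 1] == "G",
                    )
                )
                emitted_dibasic = True
                j += 2
            else:
                if run[j] == "R" and not emitted_dibasic and len(run) == 1:
                    start = run_start + j
                    sites.append(
                        ProcessingSite(
                            basic_start=start,
                            basic_end=start + 1,
                            kind="R",
                            amidation_donor=start > 0 and residues[start - 1] == "G",
                        )
                    )
                j += 1
    return sites


def _truncate_start(residues: str, start: int, end: int, max_len: int) -> int:
    """Shorten an over-long span from the N side.

    Endoproteinases cleave next to acidic residues, so the new start is
    placed right after the first D/E that keeps the span within
    ``max_len``; with no such residue the span is cut at ``max_len``.
    """
    if end - start <= max_len:
        return start
    floor = end - max_len - 1  # an acidic residue here or later is admissible
    for p in range(max(start, floor), end):
        if residues[p] in ACIDIC:
            return p + 1
    return end - max_len


def _peptides_for_selection(
    residues: str,
    record_id: str,
    sites: list[ProcessingSite],
    selected: tuple[bool, ...],
    mature_start: int | None,
    params: ScanParams,
) -> list[CandidatePeptide]:
    n_start = mature_start if mature_start is not None else 0
    peptides: list[CandidatePeptide] = []
    prev_end = n_start
    for site, keep in zip(sites, selected):
        if not keep:
            continue
        start = _truncate_start(residues, prev_end, site.basic_start, params.max_peptide_len)
        length = site.basic_start - start
        if length >= params.min_peptide_len:
            follows = mature_start is not None and abs(start - mature_start) <= POST_SIGNAL_WINDOW
            peptides.append(
                CandidatePeptide(
                    record_id=record_id,
                    start=start,
                    end=site.basic_start,
                    residues=residues[start : site.basic_start],
                    follows_signal=follows,
                    site_ref=replace(site, selected=True),
                )
            )
        prev_end = site.basic_end
    return peptides


def _components(seqs: list[str], threshold: float) -> np.ndarray:
    """Single-linkage component labels at identity >= threshold."""
    n = len(seqs)
    if n == 0:
        return np.empty(0, dtype=int)
    rows, cols = [], []
    for i, j in combinations(range(n), 2):
        if peptide_identity(seqs[i], seqs[j]) >= threshold:
            rows.append(i)
            cols.append(j)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def _objective(
    peptides: list[CandidatePeptide], n_selected: int, threshold: float
) -> tuple[int, int, int, int, int, float]:
    """Segmentation objective, maximized lexicographically:
    (largest cluster, total clustered peptides, peptides ending at an
    amidation-donor site, total clustered residues, -selected sites,
    mean identity within the largest cluster).

    Every peptide belongs to a cluster (singletons allowed), so "total
    clustered" is the peptide count. The donor term prefers cleaving at
    GKR/GRR/GR over bare sites when cluster structure ties, matching the
    amidation grammar of these precursors. The coverage term prefers
    segmentations that account for more of the prohormone (cleaving an
    R inside a repeat unit wastes its C-terminal part), and the final
    mean-identity term breaks remaining ties toward tight repeat
    clusters rather than loosely chained ones.
    """
    seqs = [p.residues for p in peptides]
    labels = _components(seqs, threshold)
    if labels.size == 0:
        return (0, 0, 0, 0, -n_selected, 0.0)
    counts = np.bincount(labels)
    largest = int(counts.max())
    n_donor = sum(p.site_ref.amidation_donor for p in peptides)
    coverage = sum(len(s) for s in seqs)
    top_label = int(counts.argmax())
    members = [s for s, l in zip(seqs, labels) if l == top_label]
    if len(members) > 1:
        idents = [
            peptide_identity(a, b) for a, b in combinations(members, 2)
        ]
        tightness = round(float(np.mean(idents)), 12)
    else:
        tightness = 1.0
    return (largest, len(peptides), n_donor, coverage, -n_selected, tightness)


def cluster_peptides(
    peptides: list[CandidatePeptide], threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> list[PeptideCluster]:
    """Single-linkage clusters of peptides at >= threshold identity,
    sorted by size descending (ties: representative string).

    The representative is the most frequent immature sequence in the
    cluster, ties resolved lexicographically.
    """
    seqs = [p.residues for p in peptides]
    labels = _components(seqs, threshold)
    clusters: list[PeptideCluster] = []
    for label in set(labels.tolist()):
        members = tuple(p for p, l in zip(peptides, labels) if l == label)
        counts: dict[str, int] = {}
        for p in members:
            counts[p.residues] = counts.get(p.residues, 0) + 1
        representative = min(
            counts, key=lambda s: (-counts[s], s)
        )
        if len(members) > 1:
            idents = [
                peptide_identity(a.residues, b.residues)
                for a, b in combinations(members, 2)
            ]
            mean_identity = float(np.mean(idents))
        else:
            mean_identity = 1.0
        clusters.append(
            PeptideCluster(members=members, representative=representative,
                           mean_identity=mean_identity)
        )
    clusters.sort(key=lambda c: (-len(c.members), c.representative))
    return clusters


def segment_peptides(
    residues: str,
    sites: list[ProcessingSite],
    signal: SignalAnnotation | None = None,
    params: ScanParams = ScanParams(),
    record_id: str = "",
    strategy: str = "auto",
) -> list[CandidatePeptide]:
    """Repeat-consistent segmentation.

    Dibasic sites are always cleaved. Monobasic R sites are ambiguous
    (an R inside a repeated peptide must not be cleaved), so a subset of
    them is chosen to maximize, in order: the size of the largest
    similarity cluster of the resulting peptides, the number of peptides
    in clusters of size >= 2, and (fewest) selected sites. The subset
    search is exhaustive when the monobasic count is at most
    ``params.exhaustive_limit``, otherwise greedy deselection starting
    from all sites selected.
    """
    if not sites:
        return []
    mature_start = signal.mature_start if signal is not None else None
    mono_idx = [i for i, s in enumerate(sites) if s.kind == "R"]
    n = len(sites)

    def evaluate(selected: tuple[bool, ...]):
        peptides = _peptides_for_selection(
            residues, record_id, sites, selected, mature_start, params
        )
        n_selected = sum(selected)
        return _objective(peptides, n_selected, params.identity_threshold), peptides

    all_on = tuple([True] * n)
    if strategy == "exhaustive" or (
        strategy == "auto" and len(mono_idx) <= params.exhaustive_limit
    ):
        best_obj, best_peps = None, []
        for mask in range(1 << len(mono_idx)):
            selected = list(all_on)
            for b, idx in enumerate(mono_idx):
                if not (mask >> b) & 1:
                    selected[idx] = False
            obj, peps = evaluate(tuple(selected))
            if best_obj is None or obj > best_obj:
                best_obj, best_peps = obj, peps
        return best_peps

    # greedy deselection from the all-selected state
    selected = list(all_on)
    cur_obj, cur_peps = evaluate(tuple(selected))
    while True:
        best_move, best_obj, best_peps = None, cur_obj, cur_peps
        for idx in mono_idx:
            if not selected[idx]:
                continue
            trial = list(selected)
            trial[idx] = False
            obj, peps = evaluate(tuple(trial))
            if obj > best_obj:
                best_move, best_obj, best_peps = idx, obj, peps
        if best_move is None:
            return cur_peps
        selected[best_move] = False
        cur_obj, cur_peps = best_obj, best_peps


def call_multicopy(
    record,
    signal: SignalAnnotation | None = None,
    params: ScanParams = ScanParams(),
    has_start: bool = True,
    has_stop: bool = True,
) -> PreprohormoneCall | None:
    """Emit a multi-copy preprohormone call, or None.

    A call requires at least ``min_sites`` amidation-capable cleavage
    sites (GKR/GRR/GR) and a cluster of at least ``min_copies`` similar
    peptides. A missing signal peptide does not veto the call but caps
    completeness at "fragment", mirroring how incomplete precursors are
    reported in practice.
    """
    sites = find_processing_sites(record.residues)
    n_amidated = sum(s.amidation_donor for s in sites)
    if n_amidated < params.min_sites:
        return None
    peptides = segment_peptides(
        record.residues, sites, signal, params, record_id=record.id
    )
    clusters = cluster_peptides(peptides, params.identity_threshold)
    if not clusters or len(clusters[0]) < params.min_copies:
        return None
    complete = signal is not None and has_start and has_stop
    return PreprohormoneCall(
        record_id=record.id,
        signal=signal,
        n_amidated_sites=n_amidated,
        clusters=tuple(clusters),
        top_copy_number=len(clusters[0]),
        completeness="complete" if complete else "fragment",
        peptides=tuple(peptides),
    )
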