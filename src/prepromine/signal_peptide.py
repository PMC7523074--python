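"""Signal-peptide annotation.

Secretory preprohormones start with a signal peptide that is cleaved
off during translocation into the rough endoplasmic reticulum; every
post-signal rule in this package (single-copy peptides, phenyllactyl
conversion, precursor completeness) is anchored on that cleavage
position. Two sources of annotations are supported: a transparent
hydrophobicity heuristic, and imported calls from an external
predictor, which take precedence.

The heuristic looks, within the first 45 residues, for a hydrophobic
core (an 8-residue window with at least 6 residues from A,C,F,I,L,M,V,W)
and then applies the classic (-3,-1) small-residue rule to place the
cleavage site: the first position j, within 12 residues downstream of
the core, whose residues j-3 and j-1 are both small (A,G,S,C,T). The
reported score is the mean Kyte-Doolittle hydropathy of the core window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

HYDROPHOBIC = set("ACFILMVW")
SMALL = set("AGSCT")

# Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

CORE_LEN = 8
MIN_CORE_HYDROPHOBIC = 6
SEARCH_REGION = 45          # window must start within the N-terminal region
CLEAVAGE_LOOKAHEAD = 12     # j is at most this far past the core window
MIN_MATURE_START = 11
MAX_MATURE_START = 45


@dataclass(frozen=True)
class SignalAnnotation:
    """A signal-peptide call: ``mature_start`` is the 0-based index of the
    first residue after cleavage."""

    record_id: str
    mature_start: int
    score: float
    method: str = "heuristic"  # heuristic | imported


def predict_signal_peptide(
    residues: str, record_id: str = ""
) -> SignalAnnotation | None:
    """Heuristic signal-peptide call, or None if no signal is found.

    Candidate core windows are scanned left to right; for each, the
    smallest admissible cleavage position j is tried. The first
    (window, j) combination satisfying the (-3,-1) rule and the
    11 <= j <= 45 bound wins, which makes the call deterministic.
    """
    if len(residues) < 25:
        raise ValueError("predict_signal_peptide: sequence shorter than 25 residues")
    region_end = min(SEARCH_REGION, len(residues))
    for w in range(0, region_end - CORE_LEN + 1):
        window = residues[w : w + CORE_LEN]
        if sum(r in HYDROPHOBIC for r in window) < MIN_CORE_HYDROPHOBIC:
            continue
        core_end = w + CORE_LEN
        j_hi = min(core_end + CLEAVAGE_LOOKAHEAD, MAX_MATURE_START, len(residues) - 1)
        for j in range(max(core_end, MIN_MATURE_START), j_hi + 1):
            if residues[j - 3] in SMALL and residues[j - 1] in SMALL:
                score = sum(KYTE_DOOLITTLE.get(r, 0.0) for r in window) / CORE_LEN
                return SignalAnnotation(record_id=record_id, mature_start=j, score=score)
    return None


def import_signal_annotations(path) -> dict[str, SignalAnnotation]:
    """Read a two-column table ``id <TAB/space> mature_start_1based``.

    '#' comment lines and blank lines are ignored; for duplicate ids the
    last row wins (a warning is logged). The 1-based file coordinate is
    converted to the package's 0-based ``mature_start``.
    """
    path = Path(path)
    annotations: dict[str, SignalAnnotation] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id mature_start_1based'")
            rec_id, pos = parts[0], int(parts[1])
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: mature_start must be >= 1 (1-based)")
            if rec_id in annotations:
                logger.warning("duplicate signal annotation for %r: last row wins", rec_id)
            annotations[rec_id] = SignalAnnotation(
                record_id=rec_id, mature_start=pos - 1, score=float("nan"), method="imported"
            )
    return annotations


def annotate_signals(
    records, imported: dict[str, SignalAnnotation] | None = None
) -> dict[str, SignalAnnotation]:
    """Signal annotations for a collection of records.

    Imported annotations take precedence over heuristic calls for the
    same id; imported ids absent from the dataset are dropped with a
    warning at pipeline-join time.
    """
    records = list(records)
    known = {r.id for r in records}
    out: dict[str, SignalAnnotation] = {}
    for rec in records:
        if len(rec.residues) < 25:
            continue
        ann = predict_signal_peptide(rec.residues, rec.id)
        if ann is not None:
            out[rec.id] = ann
    if imported:
        for rec_id, ann in imported.items():
            if rec_id not in known:
                logger.warning("imported signal annotation for unknown id %r dropped", rec_id)
                continue
            out[rec_id] = ann
    return out
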