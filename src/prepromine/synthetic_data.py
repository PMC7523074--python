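"""Synthetic precursor/decoy datasets with known ground truth.

Real genome and transcriptome assemblies cannot ship with the package,
so recovery is measured on generated data that emulates the precursor
architecture of hexacorallian preprohormones: a signal peptide, then
repeated immature peptide copies, each followed by an amidation-donor G
and a basic cleavage site (KR, RR or R), separated by acidic-residue-
rich spacers; or a single post-signal copy for the single-copy families.
Planted records are embedded among composition-matched decoy proteins
that are rejection-sampled to never satisfy the multi-copy calling
criteria, so precision is measurable.

Within one record the spacer and the signal hydrophobic core are drawn
once and reused, mirroring the near-identical repeats of real
precursors; substitution noise (never touching the signal peptide or
the G+basic cleavage signals, and never creating new basic residues) is
what degrades copy similarity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .maturation import DEFAULT_RULES, mature_peptide
from .precursor_scan import CandidatePeptide, ProcessingSite, ScanParams, call_multicopy
from .seqio import PROTEIN, SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# average composition of globular proteins, used for decoys and tails
_BACKGROUND = {
    "A": 0.083, "C": 0.014, "D": 0.054, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.041, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.054, "V": 0.069, "W": 0.011, "Y": 0.029,
}

# spacers: acidic-rich (>= 40% D/E), fully composed of residues the
# aminopeptidase trim rules can remove
_SPACER_RESIDUES = "DESTAG"
_SPACER_WEIGHTS = np.array([0.30, 0.30, 0.10, 0.10, 0.10, 0.10])

# signal hydrophobic core alphabet; A and C excluded so the (-3,-1)
# small-residue rule fires only at the planted cleavage position
_SIGNAL_HYDROPHOBIC = "LIVFMW"

_BASIC_CHOICES = ("KR", "RR", "R")
# substitution targets exclude K/R so noise cannot create cleavage sites
_NOISE_TARGETS = "".join(a for a in AA20 if a not in "KR")


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PrecursorSpec:
    """Blueprint for one planted precursor."""

    family_id: int
    peptide: str                 # immature core, without the donor G
    copy_number: int
    with_signal: bool = True
    substitution_rate: float = 0.0
    spacer_len: tuple[int, int] = (4, 8)
    post_signal: bool = False    # peptide directly after the signal (single-copy families)

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise GenerationError("copy_number must be >= 1")
        if not 3 <= len(self.peptide) <= 30:
            raise GenerationError("peptide length must be 3..30")
        if not 0.0 <= self.substitution_rate <= 0.2:
            raise GenerationError("substitution_rate must be in [0, 0.2]")
        if self.post_signal and not self.with_signal:
            raise GenerationError("post_signal placement requires a signal peptide")


# Study conditions: one template per family, with the peptides and copy
# numbers reported for these precursors (19x GPRGamide, 11x Antho-RFamide,
# MMA-type GLWamides, RPamides, pQSITRFamides, long FHIRamides, and the
# four single-copy post-signal families).
DEFAULT_FAMILY_MIX: tuple[PrecursorSpec, ...] = (
    PrecursorSpec(1, "GPRG", 19),
    PrecursorSpec(2, "QGRF", 11),
    PrecursorSpec(3, "QQPPGLW", 11),
    PrecursorSpec(4, "LPPGPLPRP", 4),
    PrecursorSpec(5, "QSITRF", 19),
    PrecursorSpec(6, "QPPYLDLTPSYFHIR", 5),
    PrecursorSpec(7, "FLRN", 1, post_signal=True),
    PrecursorSpec(8, "FYRV", 1, post_signal=True),
    PrecursorSpec(9, "FFKA", 1, post_signal=True),
    PrecursorSpec(10, "QGLRW", 1, post_signal=True),
)


@dataclass
class ManifestRecord:
    id: str
    signal_pos: int | None
    copies: list[dict]  # {"start", "end", "mature"} — span of the immature
    # copy as the caller delimits it (spacer through donor G), with the
    # mature display the processing rules give for the emitted residues
    family_id: int
    copy_number: int

    @property
    def top_mature(self) -> str:
        """Most frequent per-copy mature display (ties: lexicographic)."""
        counts: dict[str, int] = {}
        for c in self.copies:
            counts[c["mature"]] = counts.get(c["mature"], 0) + 1
        return min(counts, key=lambda d: (-counts[d], d))


@dataclass
class SyntheticManifest:
    records: list[ManifestRecord] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "records": [
                    {
                        "id": r.id,
                        "signal_pos": r.signal_pos,
                        "copies": r.copies,
                        "family_id": r.family_id,
                        "copy_number": r.copy_number,
                    }
                    for r in self.records
                ],
                "decoys": self.decoys,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticManifest":
        data = json.loads(text)
        return cls(
            records=[ManifestRecord(**r) for r in data["records"]],
            decoys=list(data["decoys"]),
        )


def _draw(rng: np.random.Generator, alphabet: str, weights=None, n: int = 1) -> str:
    probs = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        probs = w / w.sum()
    return "".join(rng.choice(list(alphabet), size=n, p=probs))


def _make_signal(rng: np.random.Generator) -> str:
    """A signal peptide the hydrophobicity heuristic resolves exactly:
    M + hydrophobic core + A·X·A placing the (-3,-1) rule at the end."""
    core_len = int(rng.integers(10, 15))  # mature_start = core_len + 4, in 14..18
    core = _draw(rng, _SIGNAL_HYDROPHOBIC, n=core_len)
    x = _draw(rng, "LIVF")
    return "M" + core + "A" + x + "A"


def generate_precursor(
    spec: PrecursorSpec, rng: np.random.Generator, record_id: str = "precursor"
) -> tuple[SequenceRecord, ManifestRecord]:
    """Emit one planted precursor and its manifest entry.

    Copy spans run from the end of the previous cleavage site (so they
    include the spacer) through the amide-donor G, exactly as the caller
    delimits candidate peptides; the manifest's per-copy mature display
    is derived from the residues actually emitted, noise included, so at
    any noise level the manifest states what faithful processing of this
    record yields.
    """
    parts: list[str] = []
    protected: list[bool] = []  # residues noise must not touch

    def emit(segment: str, protect: bool) -> None:
        parts.append(segment)
        protected.extend([protect] * len(segment))

    signal_pos: int | None = None
    if spec.with_signal:
        signal = _make_signal(rng)
        emit(signal, True)
        signal_pos = len(signal)

    spacer = ""
    if not spec.post_signal:
        s_lo, s_hi = spec.spacer_len
        spacer = _draw(rng, _SPACER_RESIDUES, _SPACER_WEIGHTS, int(rng.integers(s_lo, s_hi + 1)))

    spans: list[tuple[int, int]] = []
    for _ in range(spec.copy_number):
        start = sum(len(p) for p in parts)  # previous site end / signal end
        if spacer:
            emit(spacer, False)
        emit(spec.peptide, False)
        emit("G", True)  # amidation donor
        end = sum(len(p) for p in parts)
        emit(str(rng.choice(_BASIC_CHOICES)), True)
        spans.append((start, end))

    tail = _draw(rng, _NOISE_TARGETS, n=int(rng.integers(5, 13)))
    emit(tail, False)

    residues = list("".join(parts))
    if spec.substitution_rate > 0:
        for i, keep in enumerate(protected):
            if keep:
                continue
            if rng.random() < spec.substitution_rate:
                choices = _NOISE_TARGETS.replace(residues[i], "")
                residues[i] = _draw(rng, choices)
    sequence = "".join(residues)

    copies: list[dict] = []
    for start, end in spans:
        candidate = CandidatePeptide(
            record_id=record_id,
            start=start,
            end=end,
            residues=sequence[start:end],
            follows_signal=spec.post_signal,
            site_ref=ProcessingSite(end, end + 1, "R", True),
        )
        copies.append(
            {"start": start, "end": end,
             "mature": mature_peptide(candidate, DEFAULT_RULES).display}
        )

    record = SequenceRecord(
        id=record_id,
        residues=sequence,
        alphabet=PROTEIN,
        description=f"synthetic family {spec.family_id}",
        source="synthetic",
    )
    manifest = ManifestRecord(
        id=record_id,
        signal_pos=signal_pos,
        copies=copies,
        family_id=spec.family_id,
        copy_number=spec.copy_number,
    )
    return record, manifest


# one arbitrary codon per amino acid (no degeneracy needed: the forward
# translation is what matters for feeding the nucleotide input path)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def reverse_translate(record: SequenceRecord, stop: bool = True) -> SequenceRecord:
    """Encode a protein record as a transcript-like nucleotide record
    (fixed codon per residue, optional stop codon)."""
    dna = "".join(_CODON[a] for a in record.residues) + ("TAA" if stop else "")
    return SequenceRecord(
        id=record.id, residues=dna, alphabet="nucleotide",
        description=record.description, source="reverse-translated",
    )


def generate_decoys(
    n: int,
    rng: np.random.Generator,
    length_mean: float = 300.0,
    length_sd: float = 80.0,
    min_length: int = 60,
    params: ScanParams = ScanParams(),
    max_attempts: int = 1000,
) -> list[SequenceRecord]:
    """Composition-matched random proteins, rejection-sampled so that
    none satisfies the multi-copy calling criteria."""
    alphabet = list(_BACKGROUND)
    probs = np.array(list(_BACKGROUND.values()))
    probs = probs / probs.sum()
    decoys: list[SequenceRecord] = []
    for k in range(n):
        for _ in range(max_attempts):
            length = max(min_length, int(round(rng.normal(length_mean, length_sd))))
            residues = "".join(rng.choice(alphabet, size=length, p=probs))
            record = SequenceRecord(
                id=f"decoy_{k:04d}", residues=residues, alphabet=PROTEIN, source="synthetic"
            )
            if call_multicopy(record, signal=None, params=params) is None:
                decoys.append(record)
                break
        else:
            raise GenerationError(f"decoy {k}: rejection sampling failed after {max_attempts} attempts")
    return decoys


def generate_dataset(
    n_precursors: int = 20,
    n_decoys: int = 200,
    family_mix: tuple[PrecursorSpec, ...] = DEFAULT_FAMILY_MIX,
    seed: int = 0,
    substitution_rate: float | None = None,
    params: ScanParams = ScanParams(),
) -> tuple[list[SequenceRecord], SyntheticManifest]:
    """A shuffled dataset of planted precursors and decoys, plus its
    manifest. ``substitution_rate``, when given, overrides the rate of
    every spec in the mix."""
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    manifest = SyntheticManifest()
    for i in range(n_precursors):
        spec = family_mix[i % len(family_mix)]
        if substitution_rate is not None:
            spec = PrecursorSpec(
                family_id=spec.family_id,
                peptide=spec.peptide,
                copy_number=spec.copy_number,
                with_signal=spec.with_signal,
                substitution_rate=substitution_rate,
                spacer_len=spec.spacer_len,
                post_signal=spec.post_signal,
            )
        record, entry = generate_precursor(spec, rng, record_id=f"planted_{i:04d}")
        records.append(record)
        manifest.records.append(entry)
    decoys = generate_decoys(n_decoys, rng, params=params)
    manifest.decoys = [d.id for d in decoys]
    records.extend(decoys)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, manifest
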