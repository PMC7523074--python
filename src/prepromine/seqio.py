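"""Sequence input/output and translation of transcript assemblies.

Reads protein or nucleotide FASTA (optionally gzip-compressed), writes
FASTA, and turns nucleotide transcripts into a protein search space by
six-frame translation and ORF extraction. Coordinates are 0-based
half-open everywhere in this package; reports convert to 1-based
inclusive at the edge.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

PROTEIN = "protein"
NUCLEOTIDE = "nucleotide"

# IUPAC sets, with X/N as the unknowns the spec of each alphabet allows.
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
_NUCLEOTIDE_ALPHABET = set("ACGTUNRYSWKMBDHV")

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


class FastaError(ValueError):
    """Malformed FASTA input (empty record, duplicate id, bad alphabet)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein or nucleotide sequence with provenance.

    ``residues`` are uppercase; unknown residues are X (protein) or N
    (nucleotide). ``source`` records where the sequence came from (file
    path, or a frame label for translation products).
    """

    id: str
    residues: str
    alphabet: str = PROTEIN
    description: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaError(f"record {self.id!r}: empty sequence")
        allowed = _PROTEIN_ALPHABET if self.alphabet == PROTEIN else _NUCLEOTIDE_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise FastaError(
                f"record {self.id!r}: residues {sorted(bad)} not in {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OrfFragment:
    """A maximal stop-free segment of one translation frame.

    ``start``/``end`` are protein coordinates on the translated frame,
    0-based half-open. ``has_start``/``has_stop`` record whether the
    fragment begins with M and is terminated by a stop codon; fragments
    truncated by the sequence boundary keep those flags False so that
    downstream precursor calls can be marked as fragments.
    """

    parent_id: str
    frame: str
    start: int
    end: int
    residues: str
    has_start: bool
    has_stop: bool

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.residues):
            raise ValueError("OrfFragment span inconsistent with residues")
        if "*" in self.residues:
            raise ValueError("OrfFragment contains a stop symbol")


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, alphabet: str = PROTEIN) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    The header token before the first whitespace becomes the id; the
    remainder the description. Residues are uppercased. Duplicate ids
    and empty sequences raise :class:`FastaError` naming the offending
    header.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            if entry.id in seen:
                raise FastaError(f"duplicate id in {path}: {entry.id!r}")
            seen.add(entry.id)
            residues = str(entry.seq).upper()
            if not residues:
                raise FastaError(f"empty sequence in {path}: {entry.description!r}")
            desc = entry.description
            if desc.startswith(entry.id):
                desc = desc[len(entry.id):].strip()
            records.append(
                SequenceRecord(
                    id=entry.id,
                    residues=residues,
                    alphabet=alphabet,
                    description=desc,
                    source=str(path),
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as FASTA with sequence lines wrapped at ``width``."""
    records = list(records)
    if not records:
        raise ValueError("write_fasta: no records to write")
    if width < 1:
        raise ValueError("write_fasta: width must be positive")
    path = Path(path)
    with open(path, "wt") as out:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            out.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def six_frame_translate(record: SequenceRecord) -> dict[str, str]:
    """Translate a nucleotide record in all six frames (table 1).

    Stops are rendered as '*'; codons containing N translate to 'X'.
    Reverse frames translate the reverse complement.
    """
    if record.alphabet != NUCLEOTIDE:
        raise ValueError(f"six_frame_translate: record {record.id!r} is not nucleotide")
    fwd = Seq(record.residues.replace("U", "T"))
    rev = fwd.reverse_complement()
    out: dict[str, str] = {}
    for k in (1, 2, 3):
        for label, strand in ((f"+{k}", fwd), (f"-{k}", rev)):
            sub = strand[k - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            out[label] = str(sub.translate(table=1)) if sub else ""
    return out


def extract_orfs(
    translated: str, frame: str, parent_id: str, min_len: int = 30
) -> list[OrfFragment]:
    """Maximal stop-free segments of a translated frame, length >= min_len.

    Segments at the string boundaries are retained (partial ORFs), with
    ``has_start``/``has_stop`` set from the leading M and terminating
    stop respectively.
    """
    if min_len < 1:
        raise ValueError("extract_orfs: min_len must be >= 1")
    fragments: list[OrfFragment] = []
    pos = 0
    n = len(translated)
    while pos <= n:
        stop = translated.find("*", pos)
        seg_end = stop if stop != -1 else n
        seg = translated[pos:seg_end]
        if len(seg) >= min_len:
            fragments.append(
                OrfFragment(
                    parent_id=parent_id,
                    frame=frame,
                    start=pos,
                    end=seg_end,
                    residues=seg,
                    has_start=seg.startswith("M"),
                    has_stop=stop != -1,
                )
            )
        if stop == -1:
            break
        pos = stop + 1
    return fragments


def protein_search_space(
    records: Iterable[SequenceRecord], min_orf_len: int = 30
) -> Iterator[tuple[SequenceRecord, bool, bool]]:
    """Yield (protein record, has_start, has_stop) from a mixed input.

    Protein records pass through (flags True: an explicit proteome entry
    is taken at face value). Nucleotide records are six-frame translated
    and each ORF becomes one protein record named ``{id}|{frame}|{start}``.
    """
    for rec in records:
        if rec.alphabet == PROTEIN:
            yield rec, True, True
            continue
        for frame, prot in six_frame_translate(rec).items():
            for orf in extract_orfs(prot, frame, rec.id, min_len=min_orf_len):
                yield (
                    SequenceRecord(
                        id=f"{rec.id}|{frame}|{orf.start}",
                        residues=orf.residues,
                        alphabet=PROTEIN,
                        description=f"ORF of {rec.id} frame {frame}",
                        source=f"{rec.source}|{frame}",
                    ),
                    orf.has_start,
                    orf.has_stop,
                )
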