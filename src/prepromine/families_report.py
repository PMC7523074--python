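"""Classification of mature peptides into the ten hexacorallian
neuropeptide families, and per-species reporting.

Families are defined by C-terminally anchored patterns over the
canonical display strings (pQGRFamide, GPRGamide, phelac-LRNamide, ...)
and evaluated in a fixed precedence order, so that e.g. pQGRFamide is
always the GRFamide family and never swallowed by the generic
X1PRX2amide or TRFamide patterns despite the shared RFamide ending.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import pandas as pd

from .maturation import MaturePeptide
from .precursor_scan import PreprohormoneCall

MULTI = "multi"
SINGLE = "single"
UNCLASSIFIED = 0


@dataclass(frozen=True)
class FamilyDefinition:
    family_id: int
    name: str
    mature_pattern: str  # regular expression over display strings
    copy_mode: str       # multi | single
    precedence: int
    min_length: int = 0  # minimum core length (FHIRamides are long)
    flag: str = ""       # annotation attached to assignments (e.g. GVWamide variant)

    @property
    def compiled(self) -> re.Pattern:
        return re.compile(self.mature_pattern)


# Precedence: GRFamide before TRFamide before X1PRX2amide, then the
# remaining families; first match wins.
DEFAULT_FAMILIES: tuple[FamilyDefinition, ...] = (
    FamilyDefinition(2, "GRFamide", r"^pQGRFamide$", MULTI, 1),
    FamilyDefinition(5, "TRFamide", r"TR[FIY]amide$", MULTI, 2),
    # tetrapeptides only: longer ...PRPamide peptides are RPamides
    FamilyDefinition(1, "X1PRX2amide", r"^(.PR[GSA]|GPRP)amide$", MULTI, 3),
    FamilyDefinition(3, "GLWamide", r"GLWamide$", MULTI, 4),
    FamilyDefinition(3, "GLWamide", r"GVWamide$", MULTI, 5, flag="GVWamide variant (non-hexacoral)"),
    FamilyDefinition(4, "RPamide", r"RPamide$", MULTI, 6),
    FamilyDefinition(6, "FHIRamide", r"F?.HIRamide$", MULTI, 7, min_length=10),
    FamilyDefinition(7, "phelac-RNamide", r"^phelac-.*RNamide$", SINGLE, 8),
    FamilyDefinition(8, "phelac-RIamide", r"^phelac-.*(R[IV]|KI)amide$", SINGLE, 9),
    FamilyDefinition(9, "phelac-KAamide", r"^phelac-.*KAamide$", SINGLE, 10),
    FamilyDefinition(10, "RWamide", r"RWamide$", SINGLE, 11),
)

FAMILY_NAMES = {
    1: "X1PRX2amide", 2: "GRFamide", 3: "GLWamide", 4: "RPamide",
    5: "TRFamide", 6: "FHIRamide", 7: "phelac-RNamide",
    8: "phelac-RIamide", 9: "phelac-KAamide", 10: "RWamide",
}


@dataclass(frozen=True)
class FamilyAssignment:
    peptide: MaturePeptide
    family_id: int  # 0 = unclassified
    matched_pattern: str = ""
    flag: str = ""


def classify_peptide(
    p: MaturePeptide, families=DEFAULT_FAMILIES
) -> FamilyAssignment:
    """Highest-precedence family whose pattern matches the display string."""
    display = p.display
    for fam in sorted(families, key=lambda f: f.precedence):
        if fam.min_length and len(p.core) < fam.min_length:
            continue
        if fam.compiled.search(display):
            return FamilyAssignment(
                peptide=p, family_id=fam.family_id,
                matched_pattern=fam.mature_pattern, flag=fam.flag,
            )
    return FamilyAssignment(peptide=p, family_id=UNCLASSIFIED)


def count_copies(call_or_peptides) -> dict[str, int]:
    """Counts of identical mature display strings.

    Accepts a matured PreprohormoneCall or an iterable of MaturePeptide.
    """
    if isinstance(call_or_peptides, PreprohormoneCall):
        peptides = call_or_peptides.matured
    else:
        peptides = call_or_peptides
    counts: dict[str, int] = {}
    for p in peptides:
        counts[p.display] = counts.get(p.display, 0) + 1
    return counts


@dataclass(frozen=True)
class FamilyRow:
    family_id: int
    family_name: str
    gene_count: int
    completeness: str
    top_peptide: str
    top_copy_number: int
    flags: str = ""


@dataclass(frozen=True)
class SpeciesReport:
    species: str
    rows: tuple[FamilyRow, ...]
    unclassified: tuple[str, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": self.species,
                    "family_id": r.family_id,
                    "family_name": r.family_name,
                    "gene_count": r.gene_count,
                    "completeness": r.completeness,
                    "top_peptide": r.top_peptide,
                    "top_copy_number": r.top_copy_number,
                    "flags": r.flags,
                }
                for r in self.rows
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "species": self.species,
                "rows": [vars(r) for r in self.rows],
                "unclassified": list(self.unclassified),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SpeciesReport":
        data = json.loads(text)
        return cls(
            species=data["species"],
            rows=tuple(FamilyRow(**r) for r in data["rows"]),
            unclassified=tuple(data.get("unclassified", ())),
        )


def load_canonical_fixture() -> list[tuple[str, int]]:
    """The shipped list of canonical mature peptides and their families,
    used to pin the classification precedence."""
    from importlib.resources import files

    pairs: list[tuple[str, int]] = []
    text = files("prepromine").joinpath("data/canonical_peptides.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        display, family_id = line.split("\t")
        pairs.append((display, int(family_id)))
    return pairs


def _top_display(call: PreprohormoneCall) -> tuple[str, int]:
    counts = count_copies(call)
    if not counts:
        return "", 0
    display = min(counts, key=lambda d: (-counts[d], d))
    return display, counts[display]


def build_report(
    calls, species_label: str, families=DEFAULT_FAMILIES
) -> SpeciesReport:
    """One row per family over a species' matured calls.

    Each call is assigned to the family of its most frequent mature
    peptide; several records in one family are separate genes. A family
    with no calls is reported as absent (gene_count 0). Calls whose top
    peptide classifies to no family are listed as unclassified
    candidates rather than forced into a row.
    """
    per_family: dict[int, list[tuple[PreprohormoneCall, str, int, str]]] = {}
    unclassified: list[str] = []
    for call in calls:
        display, n = _top_display(call)
        if not display:
            continue
        assignment = classify_peptide(
            next(p for p in call.matured if p.display == display), families
        )
        if assignment.family_id == UNCLASSIFIED:
            unclassified.append(f"{call.record_id}:{display}")
            continue
        per_family.setdefault(assignment.family_id, []).append(
            (call, display, n, assignment.flag)
        )
    rows: list[FamilyRow] = []
    for fid in sorted(FAMILY_NAMES):
        entries = per_family.get(fid, [])
        if not entries:
            rows.append(FamilyRow(fid, FAMILY_NAMES[fid], 0, "absent", "-", 0))
            continue
        entries.sort(key=lambda e: (-e[2], e[0].record_id))
        top_call, display, n, flag = entries[0]
        flags = "; ".join(sorted({f for *_, f in entries if f}))
        rows.append(
            FamilyRow(
                family_id=fid,
                family_name=FAMILY_NAMES[fid],
                gene_count=len(entries),
                completeness=top_call.completeness,
                top_peptide=display,
                top_copy_number=n,
                flags=flags,
            )
        )
    return SpeciesReport(
        species=species_label, rows=tuple(rows), unclassified=tuple(sorted(unclassified))
    )
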