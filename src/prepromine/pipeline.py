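"""End-to-end orchestration: records -> signals -> calls -> mature
peptides -> family report, plus recovery evaluation against a synthetic
manifest."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import seqio
from .families_report import (
    DEFAULT_FAMILIES,
    SpeciesReport,
    build_report,
    classify_peptide,
    count_copies,
)
from .maturation import DEFAULT_RULES, ProcessingRules, _acid_split, mature_peptide
from .motif_search import DEFAULT_MOTIFS, find_single_copy, read_motif_library
from .precursor_scan import PreprohormoneCall, ScanParams, call_multicopy
from .signal_peptide import annotate_signals, import_signal_annotations
from .synthetic_data import SyntheticManifest

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_DATA = 3


class ConfigurationError(ValueError):
    pass


class EvaluationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    input: str | None = None
    alphabet: str = seqio.PROTEIN
    species: str = "unknown"
    min_sites: int = 3
    min_copies: int = 3
    identity_threshold: float = 0.6
    max_peptide_len: int = 30
    min_orf_len: int = 30
    motif_library: str | None = None
    signal_annotations: str | None = None
    output_dir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "wt") as out:
            yaml.safe_dump(vars(self), out, sort_keys=True)

    @property
    def scan_params(self) -> ScanParams:
        return ScanParams(
            min_sites=self.min_sites,
            min_copies=self.min_copies,
            identity_threshold=self.identity_threshold,
            max_peptide_len=self.max_peptide_len,
        )


@dataclass
class PipelineResult:
    calls: list[PreprohormoneCall]
    report: SpeciesReport
    signals: dict


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    per_family: dict[int, dict[str, int]] = field(default_factory=dict)


def mature_call(
    call: PreprohormoneCall, residues: str, rules: ProcessingRules = DEFAULT_RULES
) -> PreprohormoneCall:
    """Attach mature peptides to a call (dimeric spans resolved at
    acid-flanked monobasic sites before maturation)."""
    if call.matured:
        return call
    matured = []
    for cand in call.peptides:
        for piece in _acid_split(cand, residues):
            matured.append(mature_peptide(piece, rules))
    return replace(call, matured=tuple(matured))


def scan_records(
    records,
    params: ScanParams = ScanParams(),
    motifs=DEFAULT_MOTIFS,
    rules: ProcessingRules = DEFAULT_RULES,
    imported_signals=None,
    completeness_flags: dict[str, tuple[bool, bool]] | None = None,
) -> PipelineResult:
    """The full caller over protein records.

    Multi-copy calls are matured in place; single-copy calls come back
    matured from the motif stage. One call at most per record: a record
    with a multi-copy call is excluded from the single-copy search.
    """
    records = list(records)
    flags = completeness_flags or {}
    signals = annotate_signals(records, imported_signals)
    calls: list[PreprohormoneCall] = []
    multi_ids = set()
    for rec in records:
        has_start, has_stop = flags.get(rec.id, (True, True))
        call = call_multicopy(
            rec, signals.get(rec.id), params, has_start=has_start, has_stop=has_stop
        )
        if call is not None:
            calls.append(mature_call(call, rec.residues, rules))
            multi_ids.add(rec.id)
        else:
            logger.debug("record %s: no multi-copy call", rec.id)
    singles = find_single_copy(
        [r for r in records if r.id not in multi_ids], motifs, signals, rules, params
    )
    calls.extend(singles)
    return PipelineResult(calls=calls, report=None, signals=signals)  # report set by run


def run_pipeline(config: PipelineConfig):
    """Run the configured pipeline and write calls TSV, mature-peptide
    FASTA, and the species report (TSV + JSON) into the output
    directory. Deterministic for a fixed config."""
    if config.input is None or not Path(config.input).exists():
        raise ConfigurationError(f"input file not found: {config.input}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = seqio.read_fasta(config.input, config.alphabet)
    proteins = []
    flags = {}
    for rec, has_start, has_stop in seqio.protein_search_space(raw, config.min_orf_len):
        proteins.append(rec)
        flags[rec.id] = (has_start, has_stop)
    motifs = (
        tuple(read_motif_library(config.motif_library))
        if config.motif_library
        else DEFAULT_MOTIFS
    )
    imported = (
        import_signal_annotations(config.signal_annotations)
        if config.signal_annotations
        else None
    )
    if not proteins:
        logger.warning("empty input: no protein records to scan")
        result = PipelineResult(calls=[], report=build_report([], config.species), signals={})
        _write_outputs(result, out_dir)
        return result
    result = scan_records(
        proteins,
        config.scan_params,
        motifs,
        imported_signals=imported,
        completeness_flags=flags,
    )
    result.report = build_report(result.calls, config.species)
    _write_outputs(result, out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    calls_path = out_dir / "calls.tsv"
    with open(calls_path, "wt") as out:
        out.write(
            "record_id\tcompleteness\tn_amidated_sites\ttop_copy_number\trepresentative\ttop_mature\n"
        )
        for call in sorted(result.calls, key=lambda c: c.record_id):
            counts = count_copies(call)
            top = min(counts, key=lambda d: (-counts[d], d)) if counts else "-"
            rep = call.clusters[0].representative if call.clusters else "-"
            out.write(
                f"{call.record_id}\t{call.completeness}\t{call.n_amidated_sites}\t"
                f"{call.top_copy_number}\t{rep}\t{top}\n"
            )
    fasta_path = out_dir / "mature_peptides.fasta"
    with open(fasta_path, "wt") as out:
        for call in sorted(result.calls, key=lambda c: c.record_id):
            for i, pep in enumerate(call.matured):
                nmod = {"pyroglutamate": "pQ", "phenyllactyl": "phelac", "none": "none"}[
                    pep.n_mod
                ]
                out.write(
                    f">{call.record_id}|{i} display={pep.display} nmod={nmod} "
                    f"camid={int(pep.c_amidated)}\n{pep.core}\n"
                )
    if result.report is not None:
        result.report.to_frame().to_csv(out_dir / "report.tsv", sep="\t", index=False)
        (out_dir / "report.json").write_text(result.report.to_json())


def evaluate_recovery(
    calls, manifest: SyntheticManifest, records=None
) -> RecoveryMetrics:
    """Precision/recall of calls against a synthetic manifest.

    A planted record counts as recovered iff a call on it reproduces the
    manifest's top mature display and its copy count (the size of the
    call's top cluster). Calls on decoys are false positives; a call on
    a planted record that misses the exact display/count costs recall
    but is not a false discovery.
    """
    planted = {r.id: r for r in manifest.records}
    known = set(planted) | set(manifest.decoys)
    per_family: dict[int, dict[str, int]] = {
        r.family_id: {"planted": 0, "recovered": 0, "false_calls": 0}
        for r in manifest.records
    }
    for r in manifest.records:
        per_family[r.family_id]["planted"] += 1
    tp = fp = 0
    recovered_ids = set()
    for call in calls:
        if call.record_id not in known:
            raise EvaluationError(f"call on unknown record {call.record_id!r}")
        entry = planted.get(call.record_id)
        counts = count_copies(call)
        top = min(counts, key=lambda d: (-counts[d], d)) if counts else ""
        if entry is not None:
            if (
                call.record_id not in recovered_ids
                and top == entry.top_mature
                and call.top_copy_number == entry.copy_number
            ):
                tp += 1
                recovered_ids.add(call.record_id)
                per_family[entry.family_id]["recovered"] += 1
        else:
            fp += 1
            fam = 0
            if counts:
                pep = next(p for p in _call_peptides(call) if p.display == top)
                fam = classify_peptide(pep, DEFAULT_FAMILIES).family_id
            per_family.setdefault(fam, {"planted": 0, "recovered": 0, "false_calls": 0})
            per_family[fam]["false_calls"] += 1
    n_planted = len(manifest.records)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / n_planted if n_planted else 1.0
    return RecoveryMetrics(precision=precision, recall=recall, per_family=per_family)


def _call_peptides(call: PreprohormoneCall):
    return call.matured


def configure_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * verbosity
    logging.basicConfig(
        stream=sys.stderr,
        level=max(level, logging.DEBUG),
        format="%(levelname)s %(name)s: %(message)s",
    )
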