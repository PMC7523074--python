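# Methods

## The biological model

Cnidarian neuropeptides are made as preprohormones: a signal peptide
followed by a prohormone that carries one or many immature peptide
copies. Processing follows a small set of enzymatic rules:

* **Endoproteolysis.** Prohormone convertases cleave C-terminal to
  basic sites — the dibasic pairs KR and RR and monobasic R. An
  isolated K is not used. In these animals an additional
  endoproteinase activity cleaves around acidic residues, which is why
  a monobasic R immediately followed by D or E is treated as an
  obligatory cleavage point (this is what resolves "dimeric" processing
  intermediates such as pQGRFG·RED·QGRFamide into two monomers).
* **C-terminal amidation.** A glycine immediately preceding the basic
  site donates the C-terminal amide (GKR/GRR/GR). Peptides cleaved at a
  site without the donor G are predicted non-amidated (e.g. pQGRF
  instead of pQGRFamide).
* **N-terminal trimming.** Unspecific aminopeptidases remove residues
  until a protecting motif is reached: an N-terminal glutamine (which
  cyclizes to pyroglutamate, pQ) or a proline at position 2 (X-P, which
  also covers X-P-P). The freely trimmable residues are the acidic
  D/E, the hydrophilic S/T, and A/G. In addition, any residue whose
  removal immediately exposes a protected motif is considered
  trimmable. This generalization (rather than a fixed trim alphabet
  alone) is what makes the second monomer of GPRGG·RATEF·GPRGamide come
  out as the protected GPRGamide: A, T and E are trimmed by the set,
  and the leftover F directly precedes the X-P-protected GPRG.
* **Phenyllactyl formation.** A phenylalanine located directly after
  the signal-peptide cleavage site (within 2 residues, to absorb
  cleavage-site uncertainty) is converted to an N-terminal
  L-3-phenyllactyl group in the rough ER. An F anywhere else is left
  unmodified. Only the sequence consequence is modelled; the enzyme is
  unknown.
* **Not modelled.** Proline hydroxylation (Hyp) is not predicted — P is
  reported as P — because no sequence rule determines it. Whether S/T
  trimming ever stops early in real precursors cannot be decided from
  sequence; repeats without amidation donors (such as the N-terminal
  QFWKGRFS repeats of GRFamide precursors) are never reported as mature
  peptides.

## Multi-copy calling

A record is called a multi-copy preprohormone when it has at least
`min_sites` (default 3) amidation-capable cleavage sites and at least
`min_copies` (default 3) similar peptide copies.

**Site grammar.** Every KR/RR occurrence and every isolated monobasic R
is a candidate site; within a run of basic residues dibasic pairs are
taken greedily left-to-right and a leftover single basic residue is not
double-reported (KRR is one KR site).

**Repeat-consistent segmentation.** Dibasic sites always cleave.
Monobasic R sites are ambiguous: an R inside a repeated peptide (the R
of QGRF, with its own preceding G) must not be selected even though it
looks like a GR site. Instead of residue-context rules, a subset of
monobasic sites is chosen to maximize, lexicographically:

1. the size of the largest similarity cluster of the delimited
   peptides,
2. the total number of delimited peptides,
3. the number of peptides ending at an amidation-donor site,
4. the total residues covered by the peptides,
5. (fewest) selected sites,
6. the mean pairwise identity within the largest cluster.

Terms 3 and 4 are decided by the precursor architecture itself:
cleaving inside a repeat unit wastes its C-terminal part and loses the
amide donor, so the biologically correct segmentation dominates on
them whenever cluster structure ties. The subset search is exhaustive
(over monobasic sites) up to 12 such sites, 2^12 evaluations being the
practical bound for interactive use on one core, and greedy
deselection from the all-selected state beyond that; the two agree on
generated precursors within the exhaustive range, which is pinned by a
test.

Peptide spans run from the end of the previous selected site (or the
signal cleavage, or the sequence start) to the first basic residue of
their own site, so they include the donor G. Spans longer than
`max_peptide_len` (default 30, comfortably above the 14–19-residue
FHIRamides) are truncated right after the first acidic residue that
fits, else hard-cut; spans shorter than 4 residues (the maturation
floor of 3 plus the donor G) are discarded.

**Similarity and clustering.** Pairwise similarity is the number of
matches in an optimal global alignment scored match 1 / mismatch 0 /
gap 0 — equivalently the longest-common-subsequence length — divided by
the longer peptide length. "Highly similar" is fixed at ≥ 0.6
(configurable); clusters are single-linkage components at that
threshold. With single linkage a chained cluster's mean identity can
fall below the threshold; the mean is reported per cluster rather than
enforced.

## Single-copy calling

Single-copy precursors (the RWamides and the three phenyllactyl
families) carry one peptide directly after the signal peptide and are
invisible to the multi-copy criteria. They are found by motif patterns
in precursor form — the mature C-terminal consensus plus the
amidation/cleavage signal `G(KR|RR|R)` — anchored to start within 2
residues of the predicted signal cleavage. A hit is called only when it
ends at a G+basic site and no other similar peptide copy exists in the
record, so the single-copy and multi-copy call sets are disjoint per
record. A local-alignment homology search (BLOSUM62; affine gaps with
the BLAST protein convention, a length-k gap costing 11 + k) is
provided for query-driven discovery; it is checked against an
independent quadratic dynamic-programming reference in the tests.

Motif scanning reports every match of every length, including
overlapping ones — operationally identical to testing each substring
(up to a 40-residue span bound) against the pattern, which is exactly
how the test oracle recomputes it.

## Signal peptides

The heuristic is deliberately transparent rather than probabilistic: a
hydrophobic core (an 8-residue window in the first 45 residues with at
least 6 of A/C/F/I/L/M/V/W) followed, within 12 residues, by the first
position satisfying the classic (−3,−1) small-residue rule (A/G/S/C/T
at both offsets), bounded to mature starts in 11–45. The score is the
mean Kyte–Doolittle hydropathy of the core. External predictions can be
imported from a two-column table and take precedence. Agreement with
any particular published predictor is not claimed; the heuristic exists
so that post-signal rules are testable end-to-end.

## Family classification

Mature peptides are classified by C-terminally anchored patterns over
their display strings, in fixed precedence: GRFamide (`^pQGRFamide$`),
TRF/TRI/TRYamide, X1PRX2amide (anchored tetrapeptides
`^(.PR[GSA]|GPRP)amide$` — longer ...PRPamide peptides such as
LPPGPLPRPamide are RPamides), GLWamide (with the GVWamide variant
accepted but flagged), RPamide, FHIRamide (minimum core length 10,
these peptides being unusually long), then the phenyllactyl families
RNamide / RI–RV–KIamide / KAamide, and RWamide. First match wins;
anything else is reported as an unclassified candidate. A shipped
fixture of canonical peptides pins every one of these decisions.

## The synthetic benchmark

Real assemblies cannot ship with the package, so recovery is measured
on generated data with a ground-truth manifest. A planted precursor is
`[signal] + N × (spacer + peptide + G + basic) + tail`, with:

* a signal peptide constructed to satisfy the hydrophobicity heuristic
  exactly (core alphabet L/I/V/F/M/W, so the (−3,−1) rule fires only at
  the planted cleavage);
* acidic-rich spacers (≥ 40% D/E, remainder S/T/A/G — fully trimmable,
  so they exercise the trim rules) drawn once per record and reused
  across copies, mirroring the near-identical repeats of real
  precursors;
* one template per family as the default mix, with the peptides and
  copy numbers reported for these precursor types (19× GPRG, 11× QGRF,
  11× QQPPGLW, 4× LPPGPLPRP, 19× QSITRF, 5× the long FHIRamide, and
  the four single-copy post-signal families);
* substitution noise (a per-residue rate up to 0.2) applied to copies,
  spacers and tails but never to the signal peptide, the donor G or the
  basic residues, and never substituting *to* K or R. Noise models
  divergence of the repeats; destroying cleavage signals would make
  copy-number truth undefined, which is a separate failure mode from
  the segmentation correctness these data are meant to measure.

The manifest records, per planted copy, the span exactly as the caller
delimits it and the mature display that faithful processing of the
*emitted* residues yields, so it remains ground truth at any noise
level. Decoys are composition-matched random proteins
(globular-average residue frequencies, normal length distribution with
mean 300) rejection-sampled against the actual caller so that none
satisfies the multi-copy criteria; precision is therefore measurable.
A planted record counts as recovered when a call on it reproduces the
manifest's most frequent mature display and its copy number (the size
of the call's top cluster); false positives are calls on decoys.

What passing these tests does *not* show: robustness to fragmented or
mis-assembled transcripts, to signal peptides the heuristic cannot
represent, to insertion/deletion divergence between copies, or to
compositional biases of real proteomes. Single-copy recovery degrades
under substitution noise by construction, since one substitution in a
short motif defeats an exact pattern; the homology-search route exists
for that regime.

## Numerical and implementation choices

* Coordinates are 0-based half-open internally; human-readable reports
  are 1-based.
* Translation uses the standard genetic code only; N-containing codons
  yield X; partial ORFs are retained and propagate "fragment"
  completeness to calls.
* LCS-based identity and local alignment are computed with
  Bio.Align.PairwiseAligner (identity: match 1 / mismatch 0 / gap 0 in
  global mode; alignment: BLOSUM62 with open −12 / extend −1, which
  reproduces the 11 + k BLAST gap convention); identities are memoized.
* Clustering ties (representative choice) resolve by frequency then
  lexicographic order; segmentation ties resolve deterministically by
  the lexicographic objective and a fixed enumeration order. The whole
  pipeline is deterministic given its inputs; the only random source is
  the generator's explicitly passed seeded NumPy generator.
* Problem sizes used by the shipped benchmark: 20 planted precursors +
  200 decoys at zero noise, 10 seeds × 20 precursors at 10%
  substitution, 200 precursors for signal localization — sizes at which
  every stage, including the exhaustive segmentation oracle, runs
  comfortably on a single core.

## Known limitations

* The segmentation objective assumes repeats exist; for precursors with
  several *dissimilar* peptides (common in the RPamide family) it
  degenerates to cleaving at every admissible site, which matches how
  such precursors are annotated but is not independently validated
  here.
* The signal heuristic is a stand-in, not a calibrated predictor.
* Family patterns were reconstructed from reported consensus sequences;
  the original study's exact regular expressions and similarity metric
  are unpublished, so equivalence with that tool is not asserted —
  only the behaviour pinned by this package's own rules and tests.
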