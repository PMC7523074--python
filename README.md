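# prepromine

Mining and maturation analysis of cnidarian neuropeptide
preprohormones.

Hexacorals (sea anemones, stony corals and their relatives) signal
through short amidated neuropeptides that are excised from larger
precursor proteins. A preprohormone is a signal peptide followed by a
prohormone carrying either many identical/similar peptide copies or a
single copy placed directly after the signal sequence. Each immature
copy ends in a glycine followed by a prohormone-convertase site
(GKR, GRR or GR): the convertase cleaves C-terminal to the basic
residues, peptidylglycine monooxygenase turns the exposed G into a
C-terminal amide, and unspecific aminopeptidases trim the N-terminus
until a protecting motif — glutamine (→ pyroglutamate, pQ) or a
proline at position 2 (X-P / X-P-P) — stops them. Peptides whose F
sits directly after the signal sequence instead acquire an N-terminal
L-3-phenyllactyl (phelac) group.

`prepromine` turns those rules into a tested pipeline for proteomes
and transcriptome assemblies:

* **precursor_scan** — the multi-copy caller: cleavage-site grammar,
  repeat-consistent selection of ambiguous monobasic sites, similarity
  clustering (≥ 3 amidated sites and ≥ 3 similar copies to call).
* **motif_search** — the single-copy caller: post-signal-anchored
  motif patterns in precursor form plus BLOSUM62 local-alignment
  homology search.
* **maturation** — immature span → predicted mature peptide
  (amidation, pQ, phelac, aminopeptidase trimming, resolution of
  dimeric processing intermediates at acid-flanked monobasic sites).
* **families_report** — classification into the ten hexacorallian
  neuropeptide families (X1PRX2amide, GRFamide, GLWamide, RPamide,
  TRFamide, FHIRamide, phelac-RNamide, phelac-RIamide, phelac-KAamide,
  RWamide) and per-species report tables.
* **signal_peptide**, **seqio** — a transparent hydrophobicity +
  (−3,−1) signal heuristic (external annotations importable), FASTA
  I/O, six-frame translation and ORF extraction.
* **synthetic_data**, **pipeline** — a ground-truth generator for
  planted precursors among certified decoys, end-to-end orchestration
  and precision/recall evaluation.

See `docs/methods.md` for the processing model, the segmentation
objective, and what the synthetic benchmark does and does not show.

## Worked example

Two toy precursors — one with three Antho-RFamide copies, one with a
single post-signal RWamide:

```text
>rfamide_precursor
MLLLLLLLLLLLLLAGADEDAQGRFGREDAQGRFGREDAQGRFGRSTVA
>rwamide_precursor
MLLLLLLLLLLLLLAGAQGLRWGKRNTVDAW
```

```sh
$ prepromine mature demo.fasta
record_id	mature_peptide	copies
rfamide_precursor	pQGRFamide	3
rwamide_precursor	pQGLRWamide	1
```

Each `QGRFGR` repeat loses its basic R to the convertase, its G to
amidation, and its acidic `EDA` spacer to trimming, leaving three
copies of pQGRFamide; `QGLRWGKR` directly after the signal yields one
pQGLRWamide. The family table from the same input:

```sh
$ prepromine report demo.fasta --species demo
species	family_id	family_name	gene_count	completeness	top_peptide	top_copy_number	flags
demo	2	GRFamide	1	complete	pQGRFamide	3	
demo	10	RWamide	1	complete	pQGLRWamide	1	
...                 # the eight other families reported absent
```

The same stages are available as a library:

```python
from prepromine import digest_prohormone

[p.display for p in digest_prohormone("QGRFGREDQGRFGR")]
# ['pQGRFamide', 'pQGRFamide']  — a dimeric processing intermediate
#                                 resolved into its two monomers
```

Other CLI subcommands: `scan` (FASTA → calls + report + mature-peptide
FASTA), `simulate` (synthetic dataset + manifest), `evaluate`
(calls vs manifest → precision/recall). Every flag overrides its key
in a YAML config (`--config`).

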