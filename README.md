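# selenoscan

Selenoprotein gene discovery and comparative selenoproteome analysis for
genomic and transcript sequences.

## The problem

Selenoproteins carry selenocysteine (Sec, one-letter `U`), the 21st amino
acid, encoded by an in-frame TGA codon that every standard gene finder reads
as a stop.  Recoding of that TGA requires a SECIS element — a conserved
stem-loop in the 3'-UTR of the mRNA — and is betrayed at the protein level by
conservation of the residues flanking the Sec site.  Annotating a
selenoproteome therefore needs a dedicated pipeline: enumerate open reading
frames that *read through* candidate TGA codons, align them to a
Sec-annotated reference family database under a scoring model that knows
about `U`, classify the residue found at each reference Sec column
(Sec / Cys / other), confirm SECIS elements downstream of the stop, and
separate live genes from frameshifted pseudogenes.  On top of the per-genome
calls sit the comparative questions: tandem gene clusters, segmental
duplications of gene+flank regions, and the species × family presence matrix
whose double clustering summarizes selenoproteome evolution across a cohort.

`selenoscan` implements that whole chain as a tested library and CLI, with a
synthetic-cohort generator that plants every structure the pipeline must
detect — Sec genes (1–3 in-frame TGAs), Cys- and other-residue homologs,
frameshifted pseudogenes, SECIS elements, tandem clusters, ≥98 %-identity
gene+flank duplications, and ESTs — together with a machine-readable truth
table, so recovery can be scored exactly.

## Method core

- **Read-through ORFs** — in every frame of both strands, TAA/TAG-bounded
  segments are expanded so each internal TGA is tried both as Sec and as a
  stop (up to `max_readthrough_tga`, default 3: enough for families with
  three Sec residues).  Which TGAs are real Sec codons is decided by
  homology, not by the ORF stage.
- **Sec-aware local alignment** — exact affine-gap Smith–Waterman over
  BLOSUM62 extended with a `U` row copied from `C` and
  `score(U,U) = score(C,C) + 2`, so U–U > U–C > U–anything-else.  A shared
  peptide 5-mer pre-filter (U≡C) keeps genome scans fast without touching
  the exactness of the scores that are computed.
- **Sec-site classes** — at each reference Sec column the aligned query
  residue gives Sec (`U`), Cys (`C`) or Other; a conservation check over the
  ±5 flanking columns demotes spurious pairings to Unaligned.  The family
  motif (e.g. `GUGUU`, `UxxC`, `TGGUT`, `CxU`) is read off the aligned
  columns.
- **SECIS detection** — an explicit stem-loop grammar (AUGA…GA core quartet,
  helix-2 of 9–15 pairs with ≤2 mismatches, G·U wobble allowed, apical loop
  3–18 nt containing `AA`, ≥4 lower-helix pairs) scanned over ≤3 kb
  downstream of each stop.  SECIS presence raises confidence; it is not
  required for a Sec call.
- **Pseudogenes** — a frameshift-aware protein-to-DNA alignment (1–2 nt slip
  states, −12 per slip) localizes indels; an indel with no EST aligning
  across it (≥95 % identity, gap-free at the event) marks the locus as a
  pseudogene.
- **Comparative layer** — clusters are maximal same-contig chains with
  inter-gene gaps ≤10 kb; duplications require a protein positive rate
  > 50 %, then ≥80 %-identity blocks covering ≥20 % of the gene ± 10 kb
  segment; the presence matrix cell is the set-union of classes per
  (family, species), double-clustered with average linkage on Jaccard
  distances over (Sec, Cys, Other) indicator triples.

## Worked example

Generate a one-species cohort, predict, evaluate against the planted truth,
and run the comparative layer:

```bash
cat > cohort.json <<'EOF'
{"n_species": 1, "contigs_per_species": 2, "contig_length_nt": 200000,
 "n_sec_genes": 10, "n_cys_homologs": 6, "n_other_homologs": 2,
 "n_pseudogenes": 2, "n_clusters": 1, "n_duplications": 1,
 "duplication_flank_nt": 5000, "seed": 4}
EOF
selenoscan simulate --spec cohort.json --out cohort
selenoscan predict --genome cohort/sp01.genome.fasta \
    --ests cohort/sp01.ests.fasta --ref cohort/reference_db.fasta --out pred
selenoscan evaluate --calls pred/sp01.calls.tsv --truth cohort/truth.tsv --out eval
selenoscan compare --calls pred/sp01.calls.tsv \
    --genome cohort/sp01.genome.fasta --out comp
```

which prints

```
wrote cohort: 1 species, 20 planted features -> cohort
20 calls -> pred
Sec sensitivity (with family): 1.000; Sec<->Cys swaps: 0
compared 20 calls -> comp
```

`eval/metrics.tsv` then shows per-class sensitivity/precision (all 1.0 for
this cohort: every planted Sec gene recovered with the right family, both
pseudogenes flagged), `comp/matrix.tsv` holds the presence classes
(e.g. `AhpC_a  Sec&Cys` — the species has both a selenoprotein and a
Cys-homolog of that family), and `comp/duplications.tsv` the detected
gene+flank duplication with its positive rate, block identity, and coverage.

## Layout

```
src/selenoscan/
  refdb.py        reference families, U-extended scoring matrix, parameters
  simgen.py       synthetic cohorts with planted truth
  orffind.py      read-through ORF enumeration
  secis.py        SECIS grammar: detection + synthesis
  homology.py     Sec-aware aligner, site classes, frameshifts, fusion
  comparative.py  clusters, duplications, presence matrix, motif census
  pipeline.py     stage orchestration and truth evaluation
  io.py, cli.py   FASTA/GFF3/TSV I/O and the CLI
docs/methods.md   model, parameters, and design notes
```

The reference database dialect is FASTA with `family=NAME` (and optionally
`motif=PATTERN`) in the description line; `U` is permitted in sequences and
Sec positions are derived from it.  The bundled 10-family database is
synthetic: family names and canonical motifs follow the selenoprotein
literature, the sequences do not correspond to real proteins.
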