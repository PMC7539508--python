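# Methods

## Scope and model

`selenoscan` treats selenoprotein discovery as a homology problem with one
twist: the query alphabet contains a residue (`U`, selenocysteine) whose
codon (TGA) doubles as a stop.  The pipeline therefore decouples three
decisions that ordinary annotation merges: (i) where open reading frames
are, given that any internal TGA may be Sec; (ii) which reference family a
candidate resembles and what residue it carries at each reference Sec
column; (iii) whether supporting evidence (SECIS element downstream,
absence of unexplained frameshifts) is consistent with a functional
selenoprotein gene.  Genes are modelled as intronless: the codon-, alignment-
and SECIS-level logic under test does not depend on exon structure, and the
synthetic data generator plants intronless genes accordingly.  Spliced
alignment of ESTs to multi-exon genes is out of scope; EST evidence enters
only through a simplified infix-alignment support check.

## Read-through ORF enumeration

For each strand and frame, segments bounded by TAA/TAG (or sequence ends)
are translated; codons containing `N` become `X` and never terminate a
segment.  Within a segment with internal TGAs at codon positions
`t1 < t2 < …`, ORFs are emitted from every start boundary — the segment
start and the position after each TGA — and, per start, one ORF per
read-through budget `k = 0 … K`: terminate at the (k+1)-th TGA, or run to
the segment end when no more than `K` TGAs remain (`K` =
`max_readthrough_tga`, default 3, sized to the largest known per-gene Sec
count among the bundled families).  TGA is thereby tried both as Sec and as
stop on *both* sides of an ORF.  The start-side expansion matters in
practice: background DNA puts spurious in-frame TGAs upstream of a real
gene inside the same segment, and without new starts after each TGA those
spurious codons exhaust the budget `K` before the gene's last genuine Sec
codon.  The candidate set grows monotonically in `K`, and downstream scoring
— not the ORF stage — decides each TGA's meaning.  ORFs need not begin with
ATG (transcript fragments and partial genes); a `require_atg` flag restricts
to ATG-initiated ORFs.  Coordinates are 0-based half-open on the forward
strand throughout; GFF3 writers convert to 1-based closed.

## Scoring model and alignment

The substitution model is BLOSUM62 with a `U` row inherited from `C` and
`score(U,U) = score(C,C) + 2` (11 vs 9).  Sec→Cys is the canonical
substitution in this gene class, so `U` behaving as a slightly-better-
than-Cys cysteine is the least-surprising extension; the +2 bonus makes
Sec–Sec pairings strictly preferred without distorting the rest of the
matrix.  Gap penalties are the BLOSUM62 defaults (−11 open, −1 extend).

Alignment is an exact Smith–Waterman/Gotoh local aligner with affine gaps
and a fixed tie-break (diagonal, then vertical, then horizontal; lowest end
cell), making tracebacks reproducible.  A search-engine heuristic (BLAST)
is deliberately replaced by this exact aligner: at the scale of a candidate
set that has passed the pre-filter, exactness is affordable and testable.
The pre-filter requires ≥2 shared peptide 5-mers (with `U` folded onto `C`)
between query and reference member before any alignment is computed; on
uniform background DNA this removes essentially all of the ~10⁵ spurious
ORF candidates per 2 Mb genome while true homologs share dozens of seeds.
Hits below `min_hit_score` (default 60) are discarded; the default sits well
above typical top scores for random 30–50-residue peptides (~30–40) and far
below the scores of genuine family members (hundreds).  A raw-score
threshold has no length correction or significance model (E-value
statistics are out of scope), so over the ~10⁷ candidate ORFs of a
multi-megabase scan a rare short random alignment can still clear it and
surface as a spurious low-scoring homolog call; Sec calls are additionally
protected by the flank-conservation window, but the presence matrix can
occasionally acquire an extra Other entry from such a hit.

## Sec-site classification and motifs

One call is made per reference Sec column: Sec iff the aligned query residue
is `U`, Cys iff `C`, Other for any other residue, Unaligned for a gap — or
when the ±`sec_window` (default 5) reference columns around the site have a
positively-scoring aligned fraction below `min_window_positive_frac`
(default 0.4), which suppresses classifications read off unconserved local
context.  The reported motif is the query subsequence aligned to the
reference columns carrying the family's canonical motif (`GUGUU`, `UxxC`,
`TGGUT`, `CxU`, `CxxU` in the bundled set); families without a declared
motif fall back to the ±2-residue window around the first Sec column.  The
motif-column rule is needed because no single fixed window reproduces all
published family motifs (they differ in length and in the Sec position
within them).

## SECIS grammar

Elements are matched, on DNA, as: ≥4 perfectly paired lower-helix
positions, the `ATGA` core-quartet half, a helix-2 of 9–15 pairs with ≤2
mismatches (G·T wobble counts as a pair), an apical loop of 3–18 nt
containing `AA`, the complementary helix-2 arm, the `GA` quartet half, and
the complementary lower-helix arm.  These numerics follow the canonical
eukaryotic SECIS consensus used by pattern-based SECIS search tools; the
search window is 3000 nt downstream of the stop (configurable).  Scores are
pair counts minus 2 per mismatch plus an apical-AA bonus; overlapping
matches reduce to local maxima.  When the same total span admits several
helix/loop splits, the split with the most pairs wins the tie — the core
quartet coordinates are identical across splits, so reported element
boundaries are unaffected.  The generator emits elements from this same
grammar (fully paired arms, zero mismatches), which is what makes the
round-trip sensitivity check exact by construction; the measured
false-positive rate on dinucleotide-shuffled 1-kb windows (Altschul–Erikson
shuffle, exact dinucleotide counts preserved) is ~0–5 per 100 windows.
Thermodynamic folding is not modelled; Type-II (non-AA apical) elements are
not matched by the default grammar.  SECIS presence upgrades a Sec call's
confidence to `high` but is not required for the call — the discovery order
is homology first, SECIS second.

## Frameshifts and the pseudogene rule

A reference protein is aligned directly against locus DNA with moves for a
codon (3 nt, scored via the matrix on the translated codon, in-frame TGA
scoring as `U`), 1–2 nt deletions and insertions (`frameshift_penalty`
−12), and codon-level gaps (−8), with free leading/trailing DNA.  −12 was
chosen so a single slip is always preferred over absorbing a frameshifted
tail as mismatches once ≥ ~4 informative codons follow the slip; slips
closer than that to a fragment end are genuinely ambiguous and are excluded
by the generator (indels planted ≥10 codons from CDS ends).  Within
homopolymer runs or short repeats the slip position itself is
underdetermined — any placement inside the repeat yields the same sequence
— so localization is assessed to ±1 codon and can occasionally exceed that
on repeat-containing sequences.  As an efficiency measure the frameshift
alignment runs only when a locus is fragmented (multiple ORF frames merged,
or best-hit reference coverage < 0.98): a slip breaks the reading frame, so
a single-frame hit covering the reference essentially end-to-end cannot
contain one.

A locus is a pseudogene iff it has at least one frameshift event with no
EST support.  An EST supports an event when it aligns (edlib infix
alignment) across the event position with ≥ `est_min_identity_frac`
(default 0.95) identity and a gap-free alignment path within ±10 nt of the
event: such an EST shows the indel is present in the expressed transcript.
An EST from an intact paralog instead aligns with a compensating 1–2 nt gap
at the event and therefore does not support it — without the gap-free
requirement, cross-paralog ESTs at ~98 % identity would spuriously rescue
nearly every pseudogene.

## Locus assembly, fusion, calls

Overlapping ORF variants (prefixes, read-through alternatives, frameshift
fragments) whose aligned genomic spans overlap or fall within 90 nt and
share a family are collapsed into one locus; the highest-scoring variant
(ties: longer ORF) represents it, and the locus span is the union of
aligned spans — aligned spans, not raw ORF bounds, so upstream junk carried
by segment-start ORFs does not inflate coordinates.  An ORF with two
non-overlapping above-threshold hits from different families yields a
fusion call (ordered by query position).  The overall class is Sec if any
site is Sec and the locus is not a pseudogene; else Cys if any site is Cys;
else Other.

## Comparative layer

*Clusters*: maximal chains of calls on one contig with inter-gene gaps ≤
`cluster_max_gap_nt` (default 10 kb), two or more members, any class mix.
*Duplications*: same-species same-family call pairs only; stage 1 keeps
pairs whose optimal local protein alignment has > 50 % positively-scoring
columns (denominator: all aligned columns including gaps — the published
rule names no denominator, this is the stricter choice); stage 2 compares
gene ± 10 kb segments via exact 16-mer anchors grouped by diagonal and
extended to blocks, counts blocks with ≥ 80 % identity, and calls an event
when their summed length covers ≥ 20 % of the compared segment.  The 20 %
fraction is applied to the *actual* segment length (the published "20 % of
200,000 bp" cannot be reconciled with 10 kb flanks, which give ~20 kb
segments); both flank length and fraction are parameters.  Pairs whose
segments overlap on the contig (tandem copies) are skipped — a tandem
cluster is not a segmental duplication.  *Matrix*: cell = set-union of
overall classes of non-pseudogene calls per (family, species), one of 8
presence classes; pseudogenes are dead copies and do not assert presence.
*Clustering*: average linkage on Jaccard distances over per-family
(Sec, Cys, Other) indicator triples, rows and columns lexicographically
sorted before clustering so leaf orders are invariant to call input order.

## Synthetic cohorts

The generator emulates the structures the pipeline must detect, not real
algal genomes: background DNA is i.i.d. uniform; genes are back-translated
from reference members with a fixed most-frequent-codon table (Sec → TGA;
Cys class → TGC/TGT; Other class → TGG/AGA/GGA); point mutations are i.i.d.
substitutions at `mutation_rate` (default 0.01/site) outside the Sec-flank
window, with draws that would create or destroy an in-frame stop/TGA codon
resampled so the planted truth class stays unambiguous; indels occur only
where planted.  Sec genes receive a grammar-emitted SECIS 80–400 nt after
the stop with probability `secis_attach_prob` (default 1 — canonical
selenoprotein mRNAs carry one).  Clusters are pairs of different-family
genes 0.5–2 kb apart; duplications copy a gene plus 10 kb flanks to a
distant locus with ~1 % flank substitutions (gene and SECIS spared), i.e.
≥98 % identity, with the source's full segment reserved so copied flanks
are feature-free.  ESTs are 150–400 nt substrings of non-pseudogene
transcripts with 0.5 % error.  Defaults (5 species, 5 × 400 kb contigs
each, 30/20/5/5 Sec/Cys/Other/pseudogene plants, 2 clusters, 2
duplications, 120 ESTs per species) define the benchmark cohort; everything
is reproducible byte-for-byte from (spec, seed).

What passing on this cohort does *not* show: robustness to real base
composition and codon bias, introns and alternative splicing, assembly
errors, fragmented reference homology, or divergence levels beyond ~1 %
within families and the fixed divergence between bundled family sequences.
The bundled 10-family reference database is itself synthetic (names and
canonical motifs from the selenoprotein literature; sequences random), so
absolute scores carry no biological meaning — only the relative logic is
exercised.

## Numerical and degenerate-input choices

Empty downstream windows, regions shorter than the minimal SECIS span, and
empty call sets return empty results, not errors.  A reference database
without any `U` yields only homolog-class calls and a warning.  All
deterministic orderings tie-break lexicographically (family, then id; leaf
labels by name).  All randomness flows from explicit seeds; reruns are
byte-identical.
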