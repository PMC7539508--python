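"""Sec-aware homology search, Sec-site classification, pseudogene and fusion
calling.

The search replaces a BLAST step with an exact affine-gap Smith-Waterman
local aligner over the U-extended substitution matrix, fronted by a shared
peptide k-mer pre-filter (U treated as C for seeding) so that genome-scale
candidate sets stay tractable.  At every reference Sec column the aligned
query residue is classified Sec (``U``), Cys (``C``), Other, or Unaligned;
a conservation check over the Sec-flanking window demotes spurious pairings.
Frameshift detection aligns the reference protein directly against locus DNA
with 1–2 nt slip states; an in-frame indel without EST support marks the
locus as a pseudogene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .orffind import CandidateORF, translate_cds
from .refdb import Parameters, ReferenceFamily, ReferenceSequence, ScoringMatrix, find_motif

logger = logging.getLogger(__name__)

GAP = -1  # gap marker inside aligned_columns


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment of a query ORF peptide to one reference member.

    ``aligned_columns`` pairs query/reference residue indices; ``GAP`` (-1)
    marks a gap on that side.  ``query_span``/``ref_span`` are 0-based
    half-open residue intervals covered by the alignment.
    """

    query_id: str
    ref_id: str
    family: str
    score: int
    query_span: tuple[int, int]
    ref_span: tuple[int, int]
    aligned_columns: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class SecSiteCall:
    ref_sec_index: int
    query_residue: str  # one letter, or '-' for gap/outside span
    site_class: str  # Sec | Cys | Other | Unaligned
    window_positive_frac: float


@dataclass(frozen=True)
class FrameshiftEvent:
    offset_nt: int  # CDS-relative
    kind: str  # insertion | deletion
    length: int  # 1 or 2
    est_supported: bool = False


@dataclass(frozen=True)
class FusionCall:
    query_id: str
    family_a: str
    family_b: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    gap_between: int


@dataclass
class SelenoproteinCall:
    """Final verdict for one locus."""

    species: str
    contig: str
    strand: str
    start: int
    end: int
    family: str
    ref_id: str
    score: int
    site_classes: list[SecSiteCall]
    overall_class: str  # Sec | Cys | Other
    pseudogene: bool
    secis: list = field(default_factory=list)
    confidence: str = "medium"
    motif: str = ""
    frameshifts: list[FrameshiftEvent] = field(default_factory=list)
    peptide: str = ""

    @property
    def called_class(self) -> str:
        """Class used for truth matching and the presence matrix."""
        return "Pseudogene" if self.pseudogene else self.overall_class


# ---------------------------------------------------------------------------
# Exact local alignment (Gotoh affine gaps), deterministic traceback
# ---------------------------------------------------------------------------

def align_sec_aware(
    query: str, ref: ReferenceSequence | str, matrix: ScoringMatrix,
    query_id: str = "q", ref_id: str = "r", family: str = "",
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Tie-breaks are fixed: at equal score prefer the diagonal move, then the
    vertical (gap in query), then the horizontal; among equal maxima the
    lowest (i, j) end cell wins.  This makes tracebacks reproducible.
    """
    if isinstance(ref, ReferenceSequence):
        rseq, ref_id, family = ref.residues, ref.id, ref.family
    else:
        rseq = ref
    if not query or not rseq:
        raise ValueError("empty sequence in alignment")
    for s, name in ((query, "query"), (rseq, "reference")):
        bad = set(s) - set(matrix.alphabet)
        if bad:
            raise ValueError(f"{name} contains non-alphabet residues {sorted(bad)}")

    n, m = len(query), len(rseq)
    go, ge = matrix.gap_open, matrix.gap_extend
    sc = matrix.scores
    NEG = -(10 ** 9)
    H_prev = [0] * (m + 1)
    E_prev = [NEG] * (m + 1)
    # pointers: 0 stop, 1 diag, 2 up(H)/up-extend(E), 3 left(H)/left-extend(F)
    ptr_H = [bytearray(m + 1) for _ in range(n + 1)]
    ptr_E = [bytearray(m + 1) for _ in range(n + 1)]
    ptr_F = [bytearray(m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        H_cur = [0] * (m + 1)
        E_cur = [NEG] * (m + 1)
        F = NEG
        pH, pE, pF = ptr_H[i], ptr_E[i], ptr_F[i]
        for j in range(1, m + 1):
            # E: gap in query (consume ref? no — vertical consumes query).
            # Convention: E = ending with gap in reference (consume query),
            # F = ending with gap in query (consume ref).
            e_open = H_prev[j] + go
            e_ext = E_prev[j] + ge
            if e_ext > e_open:
                E = e_ext
                pE[j] = 2
            else:
                E = e_open
                pE[j] = 1
            f_open = H_cur[j - 1] + go
            f_ext = F + ge
            if f_ext > f_open:
                F = f_ext
                pF[j] = 2
            else:
                F = f_open
                pF[j] = 1
            diag = H_prev[j - 1] + sc[qi, rseq[j - 1]]
            h, p = 0, 0
            if diag >= h:
                h, p = diag, 1
            if E > h:
                h, p = E, 2
            if F > h:
                h, p = F, 3
            H_cur[j] = h
            E_cur[j] = E
            pH[j] = p
            if h > best:
                best, bi, bj = h, i, j
        H_prev, E_prev = H_cur, E_cur

    # traceback
    cols: list[tuple[int, int]] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            p = ptr_H[i][j]
            if p == 0:
                break
            if p == 1:
                cols.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append((i - 1, GAP))
            p = ptr_E[i][j]
            i -= 1
            state = "E" if p == 2 else "H"
        else:
            cols.append((GAP, j - 1))
            p = ptr_F[i][j]
            j -= 1
            state = "F" if p == 2 else "H"
    cols.reverse()
    q_idx = [q for q, _ in cols if q != GAP]
    r_idx = [r for _, r in cols if r != GAP]
    q_span = (q_idx[0], q_idx[-1] + 1) if q_idx else (0, 0)
    r_span = (r_idx[0], r_idx[-1] + 1) if r_idx else (0, 0)
    return AlignmentHit(
        query_id, ref_id, family, int(best), q_span, r_span, tuple(cols),
    )


def recompute_score(hit: AlignmentHit, query: str, ref: str,
                    matrix: ScoringMatrix) -> int:
    """Re-derive the alignment score from its columns (consistency check)."""
    total = 0
    in_gap = False
    for q, r in hit.aligned_columns:
        if q == GAP or r == GAP:
            total += matrix.gap_extend if in_gap else matrix.gap_open
            in_gap = True
        else:
            total += matrix.scores[query[q], ref[r]]
            in_gap = False
    return total


# ---------------------------------------------------------------------------
# k-mer pre-filter + family search
# ---------------------------------------------------------------------------

def _norm_kmers(pep: str, k: int) -> set[str]:
    p = pep.replace("U", "C")
    return {p[i : i + k] for i in range(len(p) - k + 1)}


class ReferenceIndex:
    """Peptide k-mer index over all reference members (U folded onto C)."""

    def __init__(self, db: list[ReferenceFamily], params: Parameters):
        self.params = params
        self.members: list[ReferenceSequence] = [
            m for fam in sorted(db, key=lambda f: f.name) for m in fam.members
        ]
        self.family_of = {m.id: m.family for m in self.members}
        self.motif_of = {
            fam.name: fam.canonical_motif for fam in db
        }
        k = params.prefilter_kmer_k
        self._kmer_to_members: dict[str, list[int]] = {}
        for idx, m in enumerate(self.members):
            for km in _norm_kmers(m.residues, k):
                self._kmer_to_members.setdefault(km, []).append(idx)

    def candidate_members(self, peptide: str) -> list[ReferenceSequence]:
        counts: dict[int, int] = {}
        for km in _norm_kmers(peptide, self.params.prefilter_kmer_k):
            for idx in self._kmer_to_members.get(km, ()):
                counts[idx] = counts.get(idx, 0) + 1
        min_seeds = self.params.prefilter_min_seeds
        return [self.members[i] for i, c in sorted(counts.items()) if c >= min_seeds]


def best_family_hit(
    orf: CandidateORF, index: ReferenceIndex, matrix: ScoringMatrix,
    params: Parameters,
) -> tuple[AlignmentHit, str] | None:
    """Best-scoring reference hit for an ORF, or None below ``min_hit_score``.

    Ties broken by (family name, reference id) so results are deterministic.
    """
    qid = f"{orf.contig}:{orf.start}-{orf.end}({orf.strand})"
    best: AlignmentHit | None = None
    for member in index.candidate_members(orf.peptide):
        hit = align_sec_aware(orf.peptide, member, matrix, query_id=qid)
        if hit.score < params.min_hit_score:
            continue
        if (
            best is None
            or hit.score > best.score
            or (hit.score == best.score and (hit.family, hit.ref_id) < (best.family, best.ref_id))
        ):
            best = hit
    return (best, best.family) if best else None


def all_family_hits(
    orf: CandidateORF, index: ReferenceIndex, matrix: ScoringMatrix,
    params: Parameters,
) -> dict[str, AlignmentHit]:
    """Best hit per family at/above ``min_hit_score`` (fusion screening)."""
    qid = f"{orf.contig}:{orf.start}-{orf.end}({orf.strand})"
    best: dict[str, AlignmentHit] = {}
    for member in index.candidate_members(orf.peptide):
        hit = align_sec_aware(orf.peptide, member, matrix, query_id=qid)
        if hit.score < params.min_hit_score:
            continue
        cur = best.get(hit.family)
        if cur is None or hit.score > cur.score or (
            hit.score == cur.score and hit.ref_id < cur.ref_id
        ):
            best[hit.family] = hit
    return best


# ---------------------------------------------------------------------------
# Sec-site classification
# ---------------------------------------------------------------------------

def classify_sec_sites(
    hit: AlignmentHit, query: str, ref: ReferenceSequence, matrix: ScoringMatrix,
    params: Parameters,
) -> list[SecSiteCall]:
    """Classify the query residue aligned to each reference Sec column.

    ``window_positive_frac`` is the fraction of the ±``sec_window`` reference
    columns around the Sec site whose aligned pair scores positively under
    the matrix (gaps and uncovered columns count against it); calls in
    windows below ``min_window_positive_frac`` are demoted to Unaligned.
    """
    ref_to_query = {r: q for q, r in hit.aligned_columns if r != GAP}
    calls: list[SecSiteCall] = []
    for sec_idx in ref.sec_positions:
        lo = max(0, sec_idx - params.sec_window)
        hi = min(len(ref.residues), sec_idx + params.sec_window + 1)
        window_cols = [r for r in range(lo, hi) if r != sec_idx]
        positive = 0
        for r in window_cols:
            q = ref_to_query.get(r, GAP)
            if q != GAP and matrix.scores[query[q], ref.residues[r]] > 0:
                positive += 1
        frac = positive / len(window_cols) if window_cols else 0.0
        q = ref_to_query.get(sec_idx, GAP)
        if q == GAP or frac < params.min_window_positive_frac:
            calls.append(SecSiteCall(sec_idx, "-", "Unaligned", frac))
            continue
        residue = query[q]
        if residue == "U":
            cls = "Sec"
        elif residue == "C":
            cls = "Cys"
        else:
            cls = "Other"
        calls.append(SecSiteCall(sec_idx, residue, cls, frac))
    return calls


def extract_motif(hit: AlignmentHit, query: str, ref: ReferenceSequence,
                  canonical_motif: str | None, flank: int = 2) -> str:
    """Query residues over the family's motif columns of the reference.

    When the family declares a canonical motif (e.g. GUGUU, UxxC, CxU) the
    reference columns carrying it are used; otherwise the ±``flank`` window
    around the first Sec column.  Gaps render as ``-``.
    """
    if canonical_motif:
        span = find_motif(ref.residues, canonical_motif)
    else:
        span = None
    if span is None:
        if not ref.sec_positions:
            return ""
        s = ref.sec_positions[0]
        span = (max(0, s - flank), min(len(ref.residues), s + flank + 1))
    ref_to_query = {r: q for q, r in hit.aligned_columns if r != GAP}
    out = []
    for r in range(*span):
        q = ref_to_query.get(r, GAP)
        out.append(query[q] if q != GAP else "-")
    return "".join(out)


# ---------------------------------------------------------------------------
# Frameshift-aware protein-to-DNA alignment
# ---------------------------------------------------------------------------

def detect_frameshifts(
    ref: ReferenceSequence, locus_dna: str, matrix: ScoringMatrix,
    params: Parameters,
) -> list[FrameshiftEvent]:
    """Align a reference protein against raw locus DNA allowing 1–2 nt slips.

    Dynamic program over (protein index i, DNA offset j).  One reference
    residue normally consumes 3 nt (scored via the matrix on the translated
    codon, in-frame TGA scored as ``U``); frameshift moves consume 1/2/4/5 nt
    at ``frameshift_penalty``; codon-level gaps on either side cost
    ``codon_gap_penalty``.  DNA end gaps are free (semi-global), so the CDS
    need not be precisely delimited.  Each slip becomes a FrameshiftEvent at
    its DNA offset.
    """
    m, n = len(ref.residues), len(locus_dna)
    fs = params.frameshift_penalty
    gp = params.codon_gap_penalty
    NEG = float("-inf")
    sc = matrix.scores

    # translated amino acid at every DNA offset (in-frame TGA scores as U)
    trans = [
        "X" if (a := translate_cds(locus_dna[j : j + 3])) in ("*", "") else a
        for j in range(max(0, n - 2))
    ]

    # H[i][j]: best score of ref[:i] against dna ending at j
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    BT: list[list[tuple[int, int, str] | None]] = [
        [None] * (n + 1) for _ in range(m + 1)
    ]
    for j in range(n + 1):
        H[0][j] = 0.0  # free leading DNA
    for i in range(1, m + 1):
        Hi, Hi1 = H[i], H[i - 1]
        BTi = BT[i]
        ri = ref.residues[i - 1]
        row = [-1.0 if aa == "X" else sc[ri, aa] for aa in trans]
        for j in range(n + 1):
            best_v, best_bt = NEG, None
            if j >= 3:
                v = Hi1[j - 3] + row[j - 3]
                if v > best_v:
                    best_v, best_bt = v, (i - 1, j - 3, "codon")
            # 1-2 nt deletions (codon shrunk)
            for d in (1, 2):
                if j >= 3 - d:
                    v = Hi1[j - (3 - d)] + fs
                    if v > best_v:
                        best_v, best_bt = v, (i - 1, j - (3 - d), f"del{d}")
            # 1-2 nt insertions (codon stretched)
            for d in (1, 2):
                if j >= 3 + d:
                    v = Hi1[j - (3 + d)] + row[j - 3] + fs
                    if v > best_v:
                        best_v, best_bt = v, (i - 1, j - (3 + d), f"ins{d}")
            v = Hi1[j] + gp  # ref residue vs nothing
            if v > best_v:
                best_v, best_bt = v, (i - 1, j, "refgap")
            if j >= 3:
                v = Hi[j - 3] + gp  # extra DNA codon
                if v > best_v:
                    best_v, best_bt = v, (i, j - 3, "dnagap")
            Hi[j] = best_v
            BTi[j] = best_bt

    j_end = max(range(n + 1), key=lambda j: H[m][j])
    events: list[FrameshiftEvent] = []
    i, j = m, j_end
    while i > 0 and BT[i][j] is not None:
        pi, pj, move = BT[i][j]
        if move.startswith("del"):
            events.append(FrameshiftEvent(pj, "deletion", int(move[3:])))
        elif move.startswith("ins"):
            events.append(FrameshiftEvent(pj + 3, "insertion", int(move[3:])))
        i, j = pi, pj
    events.reverse()
    return events


# ---------------------------------------------------------------------------
# Pseudogene rule and EST support
# ---------------------------------------------------------------------------

def est_supports_event(
    event_offset_in_locus: int, locus_dna: str, ests: list[tuple[str, str]],
    params: Parameters, margin: int = 10,
) -> bool:
    """True when some EST aligns across the indel at high identity.

    An EST transcribed from the locus matches the genomic sequence across the
    event — the indel is present in the expressed transcript, so the locus is
    not a dead genomic copy.  An EST from a functional paralog instead aligns
    with a compensating gap at the event and does NOT support it.  Alignment
    is infix edit-distance (edlib); support requires identity
    (1 - dist/len(EST)) at or above ``est_min_identity_frac``, target
    coverage of the event with ``margin`` nt on each side, and a gap-free
    alignment path within that window.
    """
    import re as _re

    for _eid, est in ests:
        if len(est) < 2 * margin + 1:
            continue
        res = edlib.align(est, locus_dna, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        identity = 1.0 - res["editDistance"] / len(est)
        if identity < params.est_min_identity_frac:
            continue
        t_start, t_end = res["locations"][0]
        if not (t_start + margin <= event_offset_in_locus <= t_end + 1 - margin):
            continue
        # walk the cigar along the target; any indel op near the event means
        # the EST contradicts the genomic frame change rather than confirming
        pos = t_start
        gap_free = True
        for n, op in _re.findall(r"(\d+)([=XIDM])", res["cigar"]):
            n = int(n)
            if op in "=XM":
                pos += n
            elif op == "D":  # deletion from EST = gap consuming target
                if pos < event_offset_in_locus + margin and \
                        pos + n > event_offset_in_locus - margin:
                    gap_free = False
                    break
                pos += n
            else:  # insertion in EST relative to target
                if (event_offset_in_locus - margin
                        <= pos <= event_offset_in_locus + margin):
                    gap_free = False
                    break
        if gap_free:
            return True
    return False


def call_pseudogene(events: list[FrameshiftEvent]) -> bool:
    """A locus is a pseudogene iff it has any EST-unsupported frameshift."""
    return any(not e.est_supported for e in events)


# ---------------------------------------------------------------------------
# Fusion calling
# ---------------------------------------------------------------------------

def detect_fusion(per_family_hits: dict[str, AlignmentHit],
                  params: Parameters) -> list[FusionCall]:
    """Two strong non-overlapping hits from different families on one ORF."""
    strong = sorted(
        (h for h in per_family_hits.values() if h.score >= params.min_hit_score),
        key=lambda h: (h.query_span[0], h.family),
    )
    calls: list[FusionCall] = []
    for i in range(len(strong)):
        for j in range(i + 1, len(strong)):
            a, b = strong[i], strong[j]
            if a.family == b.family:
                continue
            if a.query_span[1] <= b.query_span[0]:
                calls.append(FusionCall(
                    a.query_id, a.family, b.family,
                    a.query_span, b.query_span,
                    b.query_span[0] - a.query_span[1],
                ))
    return calls


# ---------------------------------------------------------------------------
# Call assembly (locus collapsing + class rules)
# ---------------------------------------------------------------------------

def _overall_class(site_classes: list[SecSiteCall], pseudogene: bool) -> str:
    classes = {c.site_class for c in site_classes}
    if "Sec" in classes and not pseudogene:
        return "Sec"
    if "Cys" in classes:
        return "Cys"
    return "Other"


def assemble_calls(
    scored_orfs: list[tuple[CandidateORF, AlignmentHit]],
    index: ReferenceIndex,
    matrix: ScoringMatrix,
    params: Parameters,
    contig_seq: dict[str, str],
    ests: list[tuple[str, str]] | None = None,
    species: str = "",
    merge_gap_nt: int = 90,
) -> list[SelenoproteinCall]:
    """Collapse overlapping ORF variants into loci and emit final calls.

    Same-strand hits whose genomic spans overlap or lie within
    ``merge_gap_nt`` and share a family are one locus (a frameshifted gene
    splits into two reading frames, so nearby fragments must merge); the
    highest-scoring variant (ties: longest ORF) represents the locus.
    Frameshift detection then runs on the merged genomic span against the
    representative reference, and the pseudogene rule is applied with EST
    support evidence.
    """
    ests = ests or []
    members_by_id = {m.id: m for m in index.members}

    def genomic_span(orf: CandidateORF, hit: AlignmentHit) -> tuple[int, int]:
        q0, q1 = hit.query_span
        if orf.strand == "+":
            return orf.start + 3 * q0, orf.start + 3 * q1
        return orf.end - 3 * q1, orf.end - 3 * q0

    loci: list[dict] = []
    for orf, hit in sorted(
        scored_orfs,
        key=lambda oh: (oh[0].contig, oh[0].strand, oh[0].start, oh[0].end),
    ):
        g0, g1 = genomic_span(orf, hit)
        placed = False
        for locus in loci:
            if (locus["contig"] == orf.contig and locus["strand"] == orf.strand
                    and locus["family"] == hit.family
                    and g0 <= locus["end"] + merge_gap_nt
                    and locus["start"] <= g1 + merge_gap_nt):
                locus["start"] = min(locus["start"], g0)
                locus["end"] = max(locus["end"], g1)
                locus["variants"].append((orf, hit))
                placed = True
                break
        if not placed:
            loci.append({
                "contig": orf.contig, "strand": orf.strand,
                "family": hit.family, "start": g0, "end": g1,
                "variants": [(orf, hit)],
            })

    # a later variant can bridge two loci created separately; merge to fixpoint
    changed = True
    while changed:
        changed = False
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                a, b = loci[i], loci[j]
                if (a["contig"] == b["contig"] and a["strand"] == b["strand"]
                        and a["family"] == b["family"]
                        and a["start"] <= b["end"] + merge_gap_nt
                        and b["start"] <= a["end"] + merge_gap_nt):
                    a["start"] = min(a["start"], b["start"])
                    a["end"] = max(a["end"], b["end"])
                    a["variants"].extend(b["variants"])
                    del loci[j]
                    changed = True
                    break
            if changed:
                break

    calls: list[SelenoproteinCall] = []
    for locus in loci:
        orf, hit = max(
            locus["variants"],
            key=lambda oh: (oh[1].score, oh[0].n_codons, -oh[0].start),
        )
        ref = members_by_id[hit.ref_id]
        site_calls = classify_sec_sites(hit, orf.peptide, ref, matrix, params)

        # Frameshift DP is only informative when the locus is fragmented:
        # a slip breaks the reading frame, so a single-frame hit covering the
        # reference (nearly) end to end cannot harbour one.
        frames = {o.frame for o, _ in locus["variants"]}
        coverage = (hit.ref_span[1] - hit.ref_span[0]) / len(ref.residues)
        supported_events: list[FrameshiftEvent] = []
        if len(frames) > 1 or coverage < 0.98:
            seq = contig_seq[locus["contig"]]
            pad = 30
            lo = max(0, locus["start"] - pad)
            hi = min(len(seq), locus["end"] + pad)
            locus_dna = seq[lo:hi]
            if locus["strand"] == "-":
                from .orffind import reverse_complement
                locus_dna = reverse_complement(locus_dna)
            events = detect_frameshifts(ref, locus_dna, matrix, params)
            for ev in events:
                sup = est_supports_event(ev.offset_nt, locus_dna, ests, params)
                supported_events.append(FrameshiftEvent(
                    ev.offset_nt, ev.kind, ev.length, est_supported=sup,
                ))
        pseudo = call_pseudogene(supported_events)
        overall = _overall_class(site_calls, pseudo)
        motif = extract_motif(
            hit, orf.peptide, ref, index.motif_of.get(hit.family),
        )
        calls.append(SelenoproteinCall(
            species=species, contig=locus["contig"], strand=locus["strand"],
            start=locus["start"], end=locus["end"], family=locus["family"],
            ref_id=hit.ref_id, score=hit.score, site_classes=site_calls,
            overall_class=overall, pseudogene=pseudo,
            motif=motif, frameshifts=supported_events, peptide=orf.peptide,
        ))
    calls.sort(key=lambda c: (c.contig, c.start, c.end, c.strand))
    return calls
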