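"""Cross-genome analytics over assembled selenoprotein calls.

Covers the comparative layer of a selenoproteome survey: tandem gene
clusters (same-contig call chains within a gap threshold), segmental
duplications of gene+flank segments (protein positive rate > 50%, then
summed >=80%-identity nucleotide blocks covering >=20% of the compared
segment, 10 kb flanks), the species x family presence-class matrix, its
double hierarchical clustering, and the Sec-flank motif census.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .homology import GAP, SelenoproteinCall, align_sec_aware
from .refdb import Parameters, ScoringMatrix

PRESENCE_CLASSES = (
    "absent", "Sec", "Cys", "Other", "Sec&Cys", "Sec&Other", "Cys&Other",
    "Sec&Cys&Other",
)


@dataclass(frozen=True)
class GeneCluster:
    species: str
    contig: str
    member_ids: tuple[str, ...]  # "family:class" labels in coordinate order
    start: int
    end: int

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class DuplicationEvent:
    species: str
    family: str
    call_a: str
    call_b: str
    protein_positive_frac: float
    flank_identity_frac: float
    flank_coverage_frac: float
    segment_a: tuple[str, int, int]
    segment_b: tuple[str, int, int]


def _call_id(c: SelenoproteinCall) -> str:
    return f"{c.contig}:{c.start}-{c.end}({c.strand})"


# ---------------------------------------------------------------------------
# Gene clusters
# ---------------------------------------------------------------------------

def detect_clusters(calls: list[SelenoproteinCall],
                    params: Parameters) -> list[GeneCluster]:
    """Maximal same-contig chains of calls with gaps <= cluster_max_gap_nt.

    Any call class participates (a cluster may mix Sec and Cys forms, as in
    published SELENOF–PDI_a pairs).  Chains of one are not clusters.
    """
    out: list[GeneCluster] = []
    by_contig: dict[tuple[str, str], list[SelenoproteinCall]] = {}
    for c in calls:
        by_contig.setdefault((c.species, c.contig), []).append(c)
    for (species, contig), group in sorted(by_contig.items()):
        group.sort(key=lambda c: (c.start, c.end))
        chain: list[SelenoproteinCall] = []
        for c in group + [None]:
            if chain and (
                c is None or c.start - chain[-1].end > params.cluster_max_gap_nt
            ):
                if len(chain) >= 2:
                    out.append(GeneCluster(
                        species, contig,
                        tuple(f"{x.family}:{x.called_class}" for x in chain),
                        chain[0].start, chain[-1].end,
                    ))
                chain = []
            if c is not None:
                chain.append(c)
    return out


# ---------------------------------------------------------------------------
# Segmental duplications
# ---------------------------------------------------------------------------

def positive_fraction(pep_a: str, pep_b: str, matrix: ScoringMatrix) -> float:
    """Positively-scoring aligned columns over all columns (incl. gaps) of
    the optimal local alignment of two call peptides."""
    hit = align_sec_aware(pep_a, pep_b, matrix)
    if not hit.aligned_columns:
        return 0.0
    pos = sum(
        1 for q, r in hit.aligned_columns
        if q != GAP and r != GAP and matrix.scores[pep_a[q], pep_b[r]] > 0
    )
    return pos / len(hit.aligned_columns)


def _identity_blocks(seg_a: str, seg_b: str, min_identity: float,
                     k: int = 16, min_block: int = 100) -> list[tuple[int, int, float]]:
    """Find high-identity co-linear blocks between two DNA segments.

    Exact k-mer anchors are grouped by diagonal (offset b-a); for each
    populated diagonal the spanned interval is compared base-by-base at that
    fixed offset and reported when identity >= ``min_identity``.  A
    deterministic stand-in for a pairwise nucleotide BLAST.
    """
    index: dict[str, list[int]] = {}
    for i in range(0, len(seg_a) - k + 1):
        index.setdefault(seg_a[i : i + k], []).append(i)
    diagonals: dict[int, list[int]] = {}
    for j in range(0, len(seg_b) - k + 1):
        for i in index.get(seg_b[j : j + k], ()):
            diagonals.setdefault(j - i, []).append(i)
    blocks: list[tuple[int, int, float]] = []
    for diag in sorted(diagonals):
        anchors = diagonals[diag]
        lo, hi = min(anchors), max(anchors) + k
        lo = max(lo, -diag if diag < 0 else 0)
        hi = min(hi, len(seg_a), len(seg_b) - diag)
        if hi - lo < min_block:
            continue
        a = np.frombuffer(seg_a[lo:hi].encode(), dtype=np.uint8)
        b = np.frombuffer(seg_b[lo + diag : hi + diag].encode(), dtype=np.uint8)
        ident = float((a == b).mean())
        if ident >= min_identity:
            blocks.append((lo, hi, ident))
    # merge overlapping intervals on seg_a so coverage is not double-counted
    blocks.sort()
    merged: list[list] = []
    for lo, hi, ident in blocks:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] = max(merged[-1][2], ident)
        else:
            merged.append([lo, hi, ident])
    return [tuple(b) for b in merged]


def detect_duplications(
    calls: list[SelenoproteinCall], genome: dict[str, str],
    matrix: ScoringMatrix, params: Parameters,
) -> list[DuplicationEvent]:
    """Two-stage duplication screen over same-species, same-family call pairs.

    Stage 1 keeps pairs whose protein positive rate exceeds
    ``duplication_positive_frac``.  Stage 2 extracts each gene plus
    ``duplication_flank_nt`` on both sides, finds >= ``duplication_identity_frac``
    identity blocks, and reports an event when their summed length reaches
    ``duplication_coverage_frac`` of the compared segment.  Pairs whose
    segments overlap on the same contig (tandem copies) are skipped.
    Events are symmetric in (a, b); each unordered pair is reported once.
    """
    out: list[DuplicationEvent] = []
    by_key: dict[tuple[str, str], list[SelenoproteinCall]] = {}
    for c in calls:
        by_key.setdefault((c.species, c.family), []).append(c)
    flank = params.duplication_flank_nt
    for (species, family), group in sorted(by_key.items()):
        group.sort(key=lambda c: (c.contig, c.start))
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                seg_a = (a.contig, max(0, a.start - flank),
                         min(len(genome[a.contig]), a.end + flank))
                seg_b = (b.contig, max(0, b.start - flank),
                         min(len(genome[b.contig]), b.end + flank))
                if a.contig == b.contig and (
                    seg_a[1] < seg_b[2] and seg_b[1] < seg_a[2]
                ):
                    continue
                pos_frac = positive_fraction(a.peptide, b.peptide, matrix)
                if pos_frac <= params.duplication_positive_frac:
                    continue
                sa = genome[a.contig][seg_a[1] : seg_a[2]]
                sb = genome[b.contig][seg_b[1] : seg_b[2]]
                blocks = _identity_blocks(
                    sa, sb, params.duplication_identity_frac,
                )
                covered = sum(hi - lo for lo, hi, _ in blocks)
                seg_len = min(len(sa), len(sb))
                coverage = covered / seg_len if seg_len else 0.0
                if coverage < params.duplication_coverage_frac:
                    continue
                identity = max((ident for *_x, ident in blocks), default=0.0)
                out.append(DuplicationEvent(
                    species, family, _call_id(a), _call_id(b),
                    pos_frac, identity, coverage, seg_a, seg_b,
                ))
    return out


# ---------------------------------------------------------------------------
# Presence matrix and clustering
# ---------------------------------------------------------------------------

def build_matrix(calls: list[SelenoproteinCall],
                 families: list[str] | None = None,
                 species: list[str] | None = None) -> pd.DataFrame:
    """Species x family presence-class matrix.

    Each cell is the set-union of the overall classes of that species'
    (non-pseudogene) calls in the family, rendered as one of
    ``PRESENCE_CLASSES``.  Rows are families, columns species, both sorted.
    """
    fams = sorted(set(families or []) | {c.family for c in calls})
    sps = sorted(set(species or []) | {c.species for c in calls})
    cell_sets: dict[tuple[str, str], set[str]] = {}
    for c in calls:
        if c.pseudogene:
            continue
        cell_sets.setdefault((c.family, c.species), set()).add(c.overall_class)
    data = {}
    for sp in sps:
        col = []
        for fam in fams:
            classes = cell_sets.get((fam, sp), set())
            ordered = [x for x in ("Sec", "Cys", "Other") if x in classes]
            col.append("&".join(ordered) if ordered else "absent")
        data[sp] = col
    return pd.DataFrame(data, index=pd.Index(fams, name="family"))


def matrix_totals(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-species counts of families containing each elementary class."""
    rows = {}
    for cls in ("Sec", "Cys", "Other"):
        rows[cls] = [
            sum(cls in cell.split("&") for cell in matrix[sp]) for sp in matrix
        ]
    return pd.DataFrame(rows, index=matrix.columns).T


def _indicator(matrix: pd.DataFrame) -> np.ndarray:
    """(3F x S) binary encoding: per family the (Sec, Cys, Other) triple."""
    blocks = []
    for cls in ("Sec", "Cys", "Other"):
        blocks.append(matrix.map(lambda cell: cls in cell.split("&")).to_numpy())
    return np.concatenate(blocks, axis=0).astype(bool)


def cluster_matrix(matrix: pd.DataFrame):
    """Average-linkage double clustering of the presence matrix.

    Distances are Jaccard over the (Sec, Cys, Other) indicator triples.
    Input rows/columns are put in lexicographic order first, so the leaf
    order is invariant to call input order.  Returns
    (row_order, col_order, row_linkage, col_linkage).
    """
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    ind = _indicator(matrix)  # 3F x S

    def order(X, labels):
        if len(labels) < 2:
            return list(labels), None
        d = pdist(X, metric="jaccard")
        d = np.nan_to_num(d, nan=0.0)  # two all-absent vectors: distance 0
        Z = linkage(d, method="average")
        return [labels[i] for i in leaves_list(Z)], Z

    col_labels = list(matrix.columns)
    row_labels = list(matrix.index)
    col_order, col_Z = order(ind.T, col_labels)
    F = len(row_labels)
    row_X = np.stack(
        [np.concatenate([ind[i], ind[F + i], ind[2 * F + i]])
         for i in range(F)]
    )
    row_order, row_Z = order(row_X, row_labels)
    return row_order, col_order, row_Z, col_Z


# ---------------------------------------------------------------------------
# Motif census
# ---------------------------------------------------------------------------

def motif_census(calls: list[SelenoproteinCall]) -> pd.DataFrame:
    """Frequency table of observed Sec-flank motifs per (family, class)."""
    rows: dict[tuple[str, str, str], int] = {}
    for c in calls:
        if not c.motif:
            continue
        key = (c.family, c.called_class, c.motif)
        rows[key] = rows.get(key, 0) + 1
    if not rows:
        return pd.DataFrame(columns=["family", "class", "motif", "count"])
    df = pd.DataFrame(
        [(f, k, m, n) for (f, k, m), n in sorted(rows.items())],
        columns=["family", "class", "motif", "count"],
    )
    return df
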