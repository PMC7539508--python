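"""Read-through open reading frame enumeration.

A selenoprotein CDS contains in-frame TGA codons that the ribosome decodes as
selenocysteine, so a conventional ORF finder truncates it.  Here every
TAA/TAG-bounded segment in all six frames is expanded into candidate ORFs in
which internal TGA codons are tried both as Sec (translated ``U``) and as
stop: from each start boundary (the segment start or the position after any
internal TGA), the run reading through up to ``max_readthrough_tga`` TGAs is
emitted together with each of its terminate-at-TGA prefixes.  Which TGAs are
genuine Sec codons is decided downstream by homology, not here.

Coordinates are 0-based half-open on the forward strand for both strands;
``N``-containing codons translate to ``X`` and never act as stops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

VALID_NT = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base-5 codon index -> amino acid; '*' = TAA/TAG, '$' = TGA (read-through
# candidate), any N component -> 'X'
_NT_CODE = np.full(256, -1, dtype=np.int8)
for i, c in enumerate("ACGTN"):
    _NT_CODE[ord(c)] = i

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "$", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_AA_LUT = np.full(125, ord("X"), dtype=np.uint8)
for codon, aa in _CODON_TABLE.items():
    idx = 0
    for c in codon:
        idx = idx * 5 + int(_NT_CODE[ord(c)])
    _AA_LUT[idx] = ord(aa)


class SequenceError(ValueError):
    """Raised for characters outside the A/C/G/T/N DNA alphabet."""


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str
    species: str = ""

    def __post_init__(self):
        if not self.seq:
            raise SequenceError(f"contig {self.id!r}: empty sequence")
        seq = self.seq.upper()
        if seq is not self.seq:
            object.__setattr__(self, "seq", seq)
        bad = set(seq) - VALID_NT
        if bad:
            offset = next(i for i, c in enumerate(seq) if c in bad)
            raise SequenceError(
                f"contig {self.id!r}: invalid character {seq[offset]!r} "
                f"at offset {offset}"
            )


@dataclass(frozen=True)
class CandidateORF:
    """One read-through ORF candidate.

    ``start``/``end`` bound the coding codons (terminal stop excluded) on the
    forward strand; ``tga_offsets`` are codon indices translated as ``U``.
    """

    contig: str
    strand: str
    start: int
    end: int
    frame: int
    peptide: str
    tga_offsets: tuple[int, ...]
    terminal_stop: str | None

    @property
    def n_codons(self) -> int:
        return len(self.peptide)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a CDS, rendering in-frame TGA as ``U`` (no stop check)."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = _CODON_TABLE.get(cds[i : i + 3], "X")
        out.append("U" if aa == "$" else aa)
    return "".join(out)


def _frame_translation(seq: str, frame: int) -> str:
    """Translate one frame of ``seq``; '*'=TAA/TAG, '$'=TGA, 'X'=ambiguous."""
    codes = _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        bad = int(np.argmax(codes < 0))
        raise SequenceError(f"invalid character {seq[bad]!r} at offset {bad}")
    n = (len(seq) - frame) // 3
    if n <= 0:
        return ""
    c = codes[frame : frame + 3 * n].reshape(n, 3).astype(np.int32)
    idx = c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]
    return _AA_LUT[idx].tobytes().decode()


def _emit_segment(pep: str, seg_start: int, seg_end: int, has_term: bool,
                  max_k: int, min_aa: int, require_atg: bool):
    """Yield (start_codon, end_codon, tga_offsets, terminated_by_tga)."""
    tgas = [i for i in range(seg_start, seg_end) if pep[i] == "$"]
    starts = [seg_start] + [t + 1 for t in tgas]
    seen = set()
    for s in starts:
        if require_atg:
            m = pep.find("M", s, seg_end)
            if m == -1:
                continue
            s = m
        after = [t for t in tgas if t >= s]
        for k in range(0, min(max_k, len(after)) + 1):
            if k < len(after):
                end, by_tga = after[k], True
            elif len(after) <= max_k:
                end, by_tga = seg_end, False
            else:
                continue
            if end - s < min_aa or (s, end) in seen:
                continue
            seen.add((s, end))
            yield s, end, tuple(t - s for t in after[:k]), by_tga


def _orfs_one_strand(contig: Contig, seq: str, strand: str, params) -> list:
    L = len(seq)
    out: list[CandidateORF] = []
    for frame in range(3):
        pep = _frame_translation(seq, frame)
        n = len(pep)
        bounds = [-1] + [i for i, a in enumerate(pep) if a == "*"] + [n]
        for bi in range(len(bounds) - 1):
            seg_start, seg_end = bounds[bi] + 1, bounds[bi + 1]
            if seg_end - seg_start < params.min_orf_aa:
                continue
            has_term = bounds[bi + 1] < n
            for s, e, tgas, by_tga in _emit_segment(
                pep, seg_start, seg_end, has_term,
                params.max_readthrough_tga, params.min_orf_aa,
                params.require_atg,
            ):
                nt_start = frame + 3 * s
                nt_end = frame + 3 * e
                if by_tga:
                    term = "TGA"
                elif has_term and e == seg_end:
                    term = seq[nt_end : nt_end + 3]
                else:
                    term = None
                peptide = pep[s:e].replace("$", "U")
                if strand == "+":
                    f_start, f_end = nt_start, nt_end
                else:
                    f_start, f_end = L - nt_end, L - nt_start
                out.append(CandidateORF(
                    contig.id, strand, f_start, f_end, frame,
                    peptide, tgas, term,
                ))
    return out


def enumerate_orfs(contig: Contig, params) -> list[CandidateORF]:
    """Enumerate read-through ORF candidates on both strands of a contig."""
    orfs = _orfs_one_strand(contig, contig.seq, "+", params)
    orfs += _orfs_one_strand(contig, reverse_complement(contig.seq), "-", params)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame, len(o.tga_offsets)))
    return orfs


def orfs_from_transcripts(
    records: Iterable[tuple[str, str]], params, both_strands: bool = False,
    species: str = "",
) -> list[CandidateORF]:
    """Enumerate ORFs on transcripts/ESTs; forward strand only by default."""
    out: list[CandidateORF] = []
    for tid, seq in records:
        contig = Contig(tid, seq, species)
        if both_strands:
            out.extend(enumerate_orfs(contig, params))
        else:
            out.extend(_orfs_one_strand(contig, contig.seq, "+", params))
    return out
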