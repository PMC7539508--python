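"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result by a different, simpler route than
the production code: plain-Python six-frame ORF enumeration, memoized
recursive affine-gap local alignment, exhaustive frameshift alignment for
tiny instances, and quadratic interval chaining for clusters.
"""

from __future__ import annotations

import functools
import sys

_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "@", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _rc(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_force_orfs(seq, max_k, min_aa, require_atg=False):
    """Six-frame read-through ORF enumeration, the slow way.

    Returns a set of (strand, start, end, peptide, tga_offsets) tuples with
    forward-strand half-open nt coordinates.
    """
    out = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", _rc(seq))):
        for frame in range(3):
            codons = [
                s[i : i + 3] for i in range(frame, L - 2, 3)
            ]
            aas = [
                "X" if "N" in c else _CODONS[c] for c in codons
            ]
            # segments between TAA/TAG (exclusive) over codon indices
            seg = []
            segments = []
            for idx, a in enumerate(aas):
                if a == "*":
                    segments.append(seg)
                    seg = []
                else:
                    seg.append(idx)
            segments.append(seg)
            for segment in segments:
                if not segment:
                    continue
                tgas = [i for i in segment if aas[i] == "@"]
                starts = [segment[0]] + [t + 1 for t in tgas if t + 1 <= segment[-1]]
                for st in starts:
                    if require_atg:
                        while st <= segment[-1] and aas[st] != "M":
                            st += 1
                        if st > segment[-1]:
                            continue
                    after = [t for t in tgas if t >= st]
                    ends = [t for t in after[: max_k + 1]]
                    if len(after) <= max_k:
                        ends.append(segment[-1] + 1)
                    for en in ends:
                        if en - st < min_aa:
                            continue
                        pep = "".join(
                            "U" if aas[i] == "@" else aas[i]
                            for i in range(st, en)
                        )
                        offs = tuple(t - st for t in after if t < en)
                        nt_s, nt_e = frame + 3 * st, frame + 3 * en
                        if strand == "+":
                            f_s, f_e = nt_s, nt_e
                        else:
                            f_s, f_e = L - nt_e, L - nt_s
                        out.add((strand, f_s, f_e, pep, offs))
    return out


def local_align_score(query, ref, scores, gap_open, gap_extend):
    """Memoized recursive affine-gap Smith-Waterman score (oracle)."""
    sys.setrecursionlimit(100_000)

    @functools.lru_cache(maxsize=None)
    def best_ending(i, j, state):
        # best score of a local alignment ending exactly at (i, j) in state
        # state: 0 = match column, 1 = gap-in-ref column, 2 = gap-in-query
        if state == 0:
            if i == 0 or j == 0:
                return float("-inf")
            prev = max(
                0,
                best_ending(i - 1, j - 1, 0),
                best_ending(i - 1, j - 1, 1),
                best_ending(i - 1, j - 1, 2),
            )
            return prev + scores[query[i - 1], ref[j - 1]]
        if state == 1:
            if i == 0:
                return float("-inf")
            return max(
                best_ending(i - 1, j, 0) + gap_open,
                best_ending(i - 1, j, 1) + gap_extend,
            )
        if j == 0:
            return float("-inf")
        return max(
            best_ending(i, j - 1, 0) + gap_open,
            best_ending(i, j - 1, 2) + gap_extend,
        )

    best = 0
    for i in range(len(query) + 1):
        for j in range(len(ref) + 1):
            for st in range(3):
                v = best_ending(i, j, st)
                if v > best:
                    best = v
    return int(best)


def exhaustive_frameshift_events(ref_protein, dna, scores, fs_penalty,
                                 gap_penalty):
    """Best frameshift-aware alignment of a tiny instance, by suffix recursion.

    Tries every move (codon / 1-2 nt deletion / 1-2 nt insertion / residue
    gap / extra DNA codon) with free leading and trailing DNA.  Returns the
    (score, events) of the best alignment; ties prefer fewer events, then
    the lexicographically smallest event list.
    """

    def aa(j):
        c = dna[j : j + 3]
        if len(c) < 3 or "N" in c:
            return "X"
        a = _CODONS[c]
        return "U" if a == "@" else ("X" if a == "*" else a)

    n, m = len(dna), len(ref_protein)

    @functools.lru_cache(maxsize=None)
    def suffix(i, j):
        # best (score, -n_events, neg_events, events) aligning ref[i:] from dna[j:]
        if i == m:
            return (0.0, 0, ())
        r = ref_protein[i]
        options = []
        if j + 3 <= n:
            a = aa(j)
            s, ne, ev = suffix(i + 1, j + 3)
            options.append((s + (-1.0 if a == "X" else scores[r, a]), ne, ev))
            s, ne, ev = suffix(i, j + 3)  # extra DNA codon
            options.append((s + gap_penalty, ne, ev))
        for d in (1, 2):
            if j + (3 - d) <= n:
                s, ne, ev = suffix(i + 1, j + (3 - d))
                options.append((s + fs_penalty, ne - 1,
                                ((j, "deletion", d),) + ev))
            if j + (3 + d) <= n:
                a = aa(j)
                s, ne, ev = suffix(i + 1, j + (3 + d))
                options.append((
                    s + fs_penalty + (-1.0 if a == "X" else scores[r, a]),
                    ne - 1, ((j + 3, "insertion", d),) + ev,
                ))
        s, ne, ev = suffix(i + 1, j)  # ref residue vs nothing
        options.append((s + gap_penalty, ne, ev))
        return max(options, key=lambda o: (o[0], o[1]))

    best = max(
        (suffix(0, start) for start in range(n + 1)),
        key=lambda o: (o[0], o[1]),
    )
    return list(best[2])


def chain_clusters(intervals, max_gap):
    """Quadratic interval-chaining oracle: maximal chains with gap <= max_gap.

    ``intervals``: list of (start, end).  Returns a list of tuples of member
    indices (input order), one per chain of size >= 2.
    """
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    chains = []
    cur = []
    for idx in order:
        if cur and intervals[idx][0] - intervals[cur[-1]][1] > max_gap:
            if len(cur) >= 2:
                chains.append(tuple(cur))
            cur = []
        cur.append(idx)
    if len(cur) >= 2:
        chains.append(tuple(cur))
    return chains
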