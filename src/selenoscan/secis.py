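"""SECIS element detection by explicit stem-loop grammar.

Eukaryotic selenoprotein mRNAs carry a SECIS element in the 3'-UTR: a stem
loop with a quartet of conserved non-Watson-Crick core pairs (5' AUGA ... GA
3'), a lower helix, an upper helix of 9–15 pairs, and an apical loop with two
unpaired adenosines.  SECIS search tools encode this consensus as a pattern
grammar; the same approach is used here, on DNA coordinates (AUGA -> ATGA).

Layout of a match on the strand-resolved (5'->3') sequence::

    [helix1 5' arm]=ATGA=[helix2 5' arm][apical loop][helix2 3' arm]=GA=[helix1 3' arm]

G·T (G·U) wobble pairs count as valid helix pairs.  The generator in
:mod:`selenoscan.simgen` emits elements from this grammar, so detection of
planted elements is exact by construction; scores rank matches in real scans.
"""

from __future__ import annotations

from dataclasses import dataclass

from .orffind import CandidateORF, Contig, reverse_complement

_PAIRS = {
    ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"),
    ("G", "T"), ("T", "G"),  # wobble
}


def is_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class SECISGrammar:
    core5: str = "ATGA"
    core3: str = "GA"
    helix2_pairs_min: int = 9
    helix2_pairs_max: int = 15
    helix2_max_mismatch: int = 2
    apical_min: int = 3
    apical_max: int = 18
    apical_required: str = "AA"
    helix1_pairs_min: int = 4
    max_distance_from_stop: int = 3000
    apical_aa_bonus: int = 2
    mismatch_penalty: int = 2

    def __post_init__(self):
        if self.helix2_pairs_min > self.helix2_pairs_max:
            raise ValueError("helix2 pair range inverted")
        if self.apical_min > self.apical_max:
            raise ValueError("apical loop range inverted")

    @property
    def min_span(self) -> int:
        return (
            self.helix1_pairs_min + len(self.core5) + 2 * self.helix2_pairs_min
            + self.apical_min + len(self.core3) + self.helix1_pairs_min
        )


@dataclass(frozen=True)
class SECISElement:
    """A stem-loop match; coordinates are forward-strand, 0-based half-open.

    ``core5_start`` is the first base of the ATGA quartet half;
    ``core3_end`` is one past the GA half.  On the minus strand the
    coordinate order is reversed relative to reading direction but the
    interval convention is unchanged.
    """

    contig: str
    strand: str
    core5_start: int
    apical_start: int
    apical_end: int
    core3_end: int
    helix2_pairs: int
    mismatches: int
    score: float
    distance_from_stop: int


def _scan(region: str, g: SECISGrammar):
    """Yield raw grammar matches as dicts of region-local coordinates."""
    n = len(region)
    pos = region.find(g.core5)
    while pos != -1:
        c = pos
        if c >= g.helix1_pairs_min:
            for h2 in range(g.helix2_pairs_min, g.helix2_pairs_max + 1):
                arm5_start = c + len(g.core5)
                for loop in range(g.apical_min, g.apical_max + 1):
                    arm3_start = arm5_start + h2 + loop
                    core3_start = arm3_start + h2
                    end = core3_start + len(g.core3) + g.helix1_pairs_min
                    if end > n:
                        continue
                    if region[core3_start : core3_start + len(g.core3)] != g.core3:
                        continue
                    apical = region[arm5_start + h2 : arm3_start]
                    if g.apical_required not in apical:
                        continue
                    mism = 0
                    for k in range(h2):
                        if not is_pair(region[arm5_start + k],
                                       region[arm3_start + h2 - 1 - k]):
                            mism += 1
                            if mism > g.helix2_max_mismatch:
                                break
                    if mism > g.helix2_max_mismatch:
                        continue
                    ok1 = all(
                        is_pair(region[c - 1 - k],
                                region[core3_start + len(g.core3) + k])
                        for k in range(g.helix1_pairs_min)
                    )
                    if not ok1:
                        continue
                    score = (
                        (h2 - mism) - g.mismatch_penalty * mism
                        + (g.apical_aa_bonus if g.apical_required in apical else 0)
                    )
                    yield {
                        "core5_start": c,
                        "apical_start": arm5_start + h2,
                        "apical_end": arm3_start,
                        "core3_end": core3_start + len(g.core3),
                        "helix2_pairs": h2 - mism,
                        "mismatches": mism,
                        "score": float(score),
                    }
        pos = region.find(g.core5, pos + 1)


def detect_secis(region: str, grammar: SECISGrammar | None = None,
                 contig: str = "", strand: str = "+") -> list[SECISElement]:
    """Scan a strand-resolved downstream region for SECIS matches.

    Overlapping raw matches are reduced to local score maxima (ties: leftmost,
    then most helix pairs).  Coordinates in the result are region-local;
    :func:`attach_secis` maps them onto the genome.
    """
    g = grammar or SECISGrammar()
    region = region.upper()
    if len(region) < g.min_span:
        return []
    raw = sorted(
        _scan(region, g),
        key=lambda d: (d["core5_start"], -d["score"], -d["helix2_pairs"]),
    )
    kept: list[dict] = []
    for cand in raw:
        overlapping = [
            k for k in kept
            if k["core5_start"] < cand["core3_end"]
            and cand["core5_start"] < k["core3_end"]
        ]
        if not overlapping:
            kept.append(cand)
        elif all(cand["score"] > k["score"] for k in overlapping):
            for k in overlapping:
                kept.remove(k)
            kept.append(cand)
    kept.sort(key=lambda d: (d["core5_start"], -d["score"]))
    return [
        SECISElement(
            contig=contig, strand=strand,
            core5_start=d["core5_start"], apical_start=d["apical_start"],
            apical_end=d["apical_end"], core3_end=d["core3_end"],
            helix2_pairs=d["helix2_pairs"], mismatches=d["mismatches"],
            score=d["score"], distance_from_stop=d["core5_start"],
        )
        for d in kept
    ]


def attach_secis(orf: CandidateORF, contig: Contig,
                 grammar: SECISGrammar | None = None) -> list[SECISElement]:
    """Search the strand-correct window downstream of an ORF's stop codon.

    Distances are measured from the base following the terminal stop (or the
    coding end when the ORF runs off the contig).  Returns elements with
    forward-strand genomic coordinates.
    """
    g = grammar or SECISGrammar()
    w = g.max_distance_from_stop
    stop_len = 3 if orf.terminal_stop else 0
    if orf.strand == "+":
        lo = orf.end + stop_len
        region = contig.seq[lo : lo + w]
        found = detect_secis(region, g, contig.id, "+")
        return [
            SECISElement(
                contig.id, "+",
                lo + e.core5_start, lo + e.apical_start,
                lo + e.apical_end, lo + e.core3_end,
                e.helix2_pairs, e.mismatches, e.score, e.distance_from_stop,
            )
            for e in found
        ]
    hi = orf.start - stop_len
    lo = max(0, hi - w)
    region = reverse_complement(contig.seq[lo:hi])
    found = detect_secis(region, g, contig.id, "-")
    return [
        SECISElement(
            contig.id, "-",
            hi - e.core3_end, hi - e.apical_end,
            hi - e.apical_start, hi - e.core5_start,
            e.helix2_pairs, e.mismatches, e.score, e.distance_from_stop,
        )
        for e in found
    ]


def synthesize_secis(rng, grammar: SECISGrammar | None = None) -> str:
    """Emit a canonical element satisfying the grammar by construction.

    Helix arms are fully paired (Watson-Crick only, zero mismatches), the
    apical loop contains the required ``AA``, and the flanking lower helix has
    exactly ``helix1_pairs_min`` perfect pairs.  Used by the synthetic-data
    generator so that detection round-trips exactly.
    """
    g = grammar or SECISGrammar()
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def rand_nt(k):
        return "".join(rng.choice("ACGT") for _ in range(k))

    h1 = rand_nt(g.helix1_pairs_min)
    h2_len = rng.randrange(g.helix2_pairs_min, g.helix2_pairs_max + 1)
    arm5 = rand_nt(h2_len)
    loop_len = rng.randrange(max(g.apical_min, 2), g.apical_max + 1)
    pad = loop_len - 2
    pre = rng.randrange(pad + 1)
    apical = rand_nt(pre) + g.apical_required + rand_nt(pad - pre)
    arm3 = "".join(comp[c] for c in reversed(arm5))
    h1_3 = "".join(comp[c] for c in reversed(h1))
    return h1 + g.core5 + arm5 + apical + arm3 + g.core3 + h1_3
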