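"""Synthetic cohorts with planted selenoprotein structure and full truth.

The generator builds multi-contig genomes carrying intronless selenoprotein
genes back-translated from reference family members: Sec codons become TGA
(read-through), Cys homologs recode them as TGC/TGT, Other homologs as a
non-Cys codon such as TGG (Trp), and pseudogenes carry a single 1–2 nt
frameshifting indel.  Canonical SECIS elements are appended downstream of
selenoprotein stops, genes are optionally grouped into tandem clusters, and
gene+flank segments are copied at >=98% identity to emulate segmental
duplications.  ESTs are sampled from the planted (non-pseudogene)
transcripts.  Every planted feature is recorded in a machine-readable truth
table so recovery can be scored exactly.

The generator makes no attempt to mimic real algal base composition, codon
usage, or genome sizes; the background is i.i.d. uniform DNA.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np

from .orffind import Contig, reverse_complement, translate_cds
from .refdb import ReferenceFamily, ReferenceSequence, STANDARD_AA
from .secis import SECISGrammar, synthesize_secis

# most-frequent human codon per amino acid (fixed back-translation table)
PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCC", "Q": "CAG", "R": "CGG", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC", "U": "TGA", "X": "GCC",
}

OTHER_CODONS = ("TGG", "AGA", "GGA")  # Trp / Arg / Gly at ex-Sec sites
STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TruthRecord:
    """One planted feature; coordinates are forward-strand 0-based half-open
    over the coding codons (terminal stop excluded)."""

    gene_id: str
    species: str
    contig: str
    start: int
    end: int
    strand: str
    family: str
    member_id: str
    planted_class: str  # Sec | Cys | Other | Pseudogene
    sec_codon_offsets: tuple[int, ...] = ()
    secis_present: bool = False
    secis_core5_start: int = -1
    cluster_id: str = ""
    duplication_id: str = ""
    indel_codon: int = -1
    indel_kind: str = ""
    indel_length: int = 0


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort (defaults: the 5-species
    benchmark — ~2 Mb genomes, 30/20/5/5 Sec/Cys/Other/pseudogene plants per
    species from the bundled 10-family reference set)."""

    n_species: int = 5
    contigs_per_species: int = 5
    contig_length_nt: int = 400_000
    n_sec_genes: int = 30
    n_cys_homologs: int = 20
    n_other_homologs: int = 5
    n_pseudogenes: int = 5
    n_clusters: int = 2
    n_duplications: int = 2
    secis_attach_prob: float = 1.0
    mutation_rate: float = 0.01
    duplication_flank_nt: int = 10_000
    cluster_gap_nt: int = 2_000
    n_ests: int = 120
    est_error_rate: float = 0.005
    reverse_strand_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("secis_attach_prob", "mutation_rate", "est_error_rate",
                     "reverse_strand_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_species", "contigs_per_species", "contig_length_nt",
                     "n_sec_genes", "n_cys_homologs", "n_other_homologs",
                     "n_pseudogenes", "n_clusters", "n_duplications",
                     "n_ests"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Cohort:
    spec: SyntheticCohortSpec
    ref_db: list[ReferenceFamily]
    contigs: dict[str, list[Contig]]  # species -> contigs
    truth: list[TruthRecord]
    transcripts: dict[str, list[tuple[str, str]]]
    ests: dict[str, list[tuple[str, str]]]
    est_links: dict[str, str] = field(default_factory=dict)  # est id -> gene id


# ---------------------------------------------------------------------------
# Bundled synthetic reference families
# ---------------------------------------------------------------------------

_FAMILY_PLAN = [
    # (name, motif or None, length range)
    ("AhpC_a", "TGGUT", (90, 130)),
    ("AhpC_b", "UxxC", (90, 130)),
    ("GPX", None, (110, 150)),
    ("GRX", None, (80, 110)),
    ("GST", None, (100, 140)),
    ("MSRA", None, (110, 150)),
    ("PDI_a", None, (100, 140)),
    ("PDI_e", "GUGUU", (100, 140)),
    ("SELENOF", "CxU", (80, 110)),
    ("SELENOW", "CxxU", (70, 100)),
]


def _random_peptide(rng: random.Random, length: int) -> str:
    return "M" + "".join(rng.choice(STANDARD_AA) for _ in range(length - 1))


def _apply_motif(residues: str, motif: str, pos: int, rng: random.Random) -> str:
    chars = list(residues)
    for k, c in enumerate(motif):
        if c == "x":
            if chars[pos + k] == "U":
                chars[pos + k] = rng.choice(STANDARD_AA.replace("C", ""))
        else:
            chars[pos + k] = c
    return "".join(chars)


def make_reference_db(seed: int = 0, n_members: int = 2) -> list[ReferenceFamily]:
    """Build the bundled synthetic 10-family reference database.

    Family names and canonical Sec-flank motifs (GUGUU for PDI_e, UxxC for
    AhpC_b, TGGUT for AhpC_a, CxU for SELENOF, CxxU for SELENOW) follow the
    selenoprotein literature; the sequences themselves are synthetic.
    """
    rng = random.Random(seed * 2 + 1)
    families = []
    for name, motif, (lo, hi) in _FAMILY_PLAN:
        length = rng.randrange(lo, hi + 1)
        base = _random_peptide(rng, length)
        pos = rng.randrange(length // 3, 2 * length // 3)
        if motif:
            base = _apply_motif(base, motif, pos, rng)
            if "U" not in motif:  # motif without Sec letter never happens here
                pass
        else:
            base = base[:pos] + "U" + base[pos + 1 :]
        members = []
        for i in range(n_members):
            residues = base
            if i > 0:
                chars = list(base)
                protect = set(range(max(0, pos - 6), min(length, pos + 10)))
                protect.add(0)
                for p in range(length):
                    if p in protect or chars[p] == "U":
                        continue
                    if rng.random() < 0.10:
                        chars[p] = rng.choice(STANDARD_AA.replace("C", ""))
                residues = "".join(chars)
            members.append(ReferenceSequence(f"{name}_{i + 1}", name, residues))
        families.append(ReferenceFamily(name, tuple(members), motif))
    return families


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------

def back_translate(peptide: str, planted_class: str, rng: random.Random,
                   ) -> tuple[str, tuple[int, ...]]:
    """CDS for a peptide under a planted class; returns (cds, sec offsets).

    Sec residues become TGA for class Sec, TGC/TGT for Cys, and a random
    non-Cys codon (e.g. TGG) for Other.  A terminal TAA stop is appended.
    """
    codons, sec_offsets = [], []
    for i, aa in enumerate(peptide):
        if aa == "U":
            if planted_class in ("Sec", "Pseudogene"):
                codons.append("TGA")
                sec_offsets.append(i)
            elif planted_class == "Cys":
                codons.append(rng.choice(("TGC", "TGT")))
            else:
                codons.append(rng.choice(OTHER_CODONS))
        else:
            codons.append(PREFERRED_CODON[aa])
    return "".join(codons) + "TAA", tuple(sec_offsets)


def mutate_cds(cds: str, sec_offsets: tuple[int, ...], rate: float,
               rng: random.Random, sec_window: int = 5) -> str:
    """Apply i.i.d. substitutions outside the Sec-flank windows.

    A drawn substitution that would create or destroy an in-frame stop/TGA
    codon is resampled so the planted truth class stays unambiguous.  The
    ATG start and the terminal stop are protected.
    """
    n_codons = len(cds) // 3
    protected = {0, n_codons - 1}
    for s in sec_offsets:
        protected.update(range(s - sec_window, s + sec_window + 1))
    chars = list(cds)
    for ci in range(n_codons):
        if ci in protected:
            continue
        for k in range(3):
            p = 3 * ci + k
            if rng.random() >= rate:
                continue
            old_codon = cds[3 * ci : 3 * ci + 3]
            for _attempt in range(10):
                nt = rng.choice("ACGT")
                if nt == chars[p]:
                    continue
                trial = chars[3 * ci : 3 * ci + 3]
                trial[k] = nt
                if "".join(trial) in STOPS or old_codon in STOPS:
                    continue
                chars[p] = nt
                break
    return "".join(chars)


def apply_indel(cds: str, codon: int, kind: str, length: int,
                rng: random.Random) -> str:
    """Introduce one frameshifting indel at a codon of a CDS.

    The codon must be at least 5 codons from either end (a slip at the very
    edge of a gene is indistinguishable from alignment end noise).
    """
    n_codons = len(cds) // 3
    if not 5 <= codon <= n_codons - 6:
        raise ValueError(f"indel codon {codon} too close to CDS end")
    if length not in (1, 2):
        raise ValueError("indel length must be 1 or 2")
    p = 3 * codon
    if kind == "deletion":
        return cds[:p] + cds[p + length :]
    if kind == "insertion":
        ins = "".join(rng.choice("ACGT") for _ in range(length))
        return cds[:p] + ins + cds[p:]
    raise ValueError(f"unknown indel kind {kind!r}")


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

class _Packer:
    """Non-overlapping interval allocator over a species' contigs."""

    def __init__(self, n_contigs: int, length: int, rng: random.Random,
                 margin: int = 60, max_tries: int = 200):
        self.length = length
        self.rng = rng
        self.margin = margin
        self.max_tries = max_tries
        self.occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_contigs)]

    def place(self, size: int, contig: int | None = None) -> tuple[int, int]:
        for _ in range(self.max_tries):
            c = self.rng.randrange(len(self.occupied)) if contig is None else contig
            if size > self.length:
                break
            start = self.rng.randrange(self.length - size + 1)
            lo, hi = start - self.margin, start + size + self.margin
            if all(e <= lo or s >= hi for s, e in self.occupied[c]):
                self.occupied[c].append((start, start + size))
                return c, start
        raise RuntimeError(
            f"could not pack a feature of {size} nt; cohort too dense"
        )


def _gene_block(member: ReferenceSequence, planted_class: str,
                spec: SyntheticCohortSpec, rng: random.Random,
                grammar: SECISGrammar,
                indel: tuple[int, str, int] | None = None,
                attach_secis: bool | None = None):
    """Build one insertable gene block (CDS [+stop] [+spacer+SECIS]).

    Returns (block_seq, cds_start_in_block, cds_len, sec_offsets,
    secis_core5_in_block, transcript).
    """
    cds, sec_offsets = back_translate(member.residues, planted_class, rng)
    # protect every ex-Sec position (whatever codon the class put there), so
    # mutation noise can never flip the planted truth class
    u_positions = tuple(
        i for i, aa in enumerate(member.residues) if aa == "U"
    )
    cds = mutate_cds(cds, u_positions, spec.mutation_rate, rng)
    if indel is not None:
        codon, kind, length = indel
        cds = apply_indel(cds, codon, kind, length, rng)
    if attach_secis is None:
        attach_secis = (
            planted_class == "Sec" and rng.random() < spec.secis_attach_prob
        )
    block = cds
    secis_core5 = -1
    if attach_secis:
        spacer = rng.randrange(80, 400)
        element = synthesize_secis(rng, grammar)
        secis_core5 = len(cds) + spacer + grammar.helix1_pairs_min
        block = cds + _random_dna(rng, spacer) + element
    transcript = block + _random_dna(rng, 40)
    return block, len(cds) - 3, sec_offsets, secis_core5, transcript


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def generate_cohort(spec: SyntheticCohortSpec,
                    ref_db: list[ReferenceFamily] | None = None,
                    grammar: SECISGrammar | None = None) -> Cohort:
    """Generate genomes, transcripts, ESTs, and the truth table.

    Reproducible byte-for-byte from (spec, seed).  Planted features never
    overlap; duplication source genes reserve their full gene+flank segment
    so the copied flanks contain no other features.
    """
    rng = random.Random(spec.seed)
    nprng = np.random.default_rng(spec.seed)
    grammar = grammar or SECISGrammar()
    ref_db = ref_db or make_reference_db(seed=spec.seed % 10_007)
    members = [m for fam in ref_db for m in fam.members]
    sec_members = [m for m in members if m.n_sec > 0]

    contigs: dict[str, list[Contig]] = {}
    truth: list[TruthRecord] = []
    transcripts: dict[str, list[tuple[str, str]]] = {}
    ests: dict[str, list[tuple[str, str]]] = {}
    est_links: dict[str, str] = {}

    for si in range(spec.n_species):
        species = f"sp{si + 1:02d}"
        genome = [
            nprng.integers(0, 4, size=spec.contig_length_nt, dtype=np.int8)
            for _ in range(spec.contigs_per_species)
        ]
        packer = _Packer(spec.contigs_per_species, spec.contig_length_nt, rng)
        sp_truth: list[TruthRecord] = []
        sp_tx: list[tuple[str, str]] = []
        gene_no = 0

        def paste(contig_idx: int, start: int, seq: str):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            code = np.zeros(256, dtype=np.int8)
            for v, c in enumerate("ACGT"):
                code[ord(c)] = v
            genome[contig_idx][start : start + len(seq)] = code[arr]

        def plant_one(planted_class: str, member: ReferenceSequence,
                      cluster_id: str = "", contig: int | None = None,
                      at: int | None = None,
                      indel: tuple[int, str, int] | None = None,
                      reserve_flank: int = 0) -> TruthRecord:
            nonlocal gene_no
            block, cds_end_in_block, sec_offsets, secis_core5, tx = _gene_block(
                member, planted_class, spec, rng, grammar, indel=indel,
            )
            strand = "-" if rng.random() < spec.reverse_strand_frac else "+"
            insert = block if strand == "+" else reverse_complement(block)
            if at is None:
                # double flank reservation: nothing else may fall within one
                # flank length of the gene+flank segment, or an unrelated
                # neighbour's own flank window would contain duplicated
                # sequence and look like an unplanted duplication event
                size = len(block) + 4 * reserve_flank
                c, start0 = packer.place(size, contig)
                start = start0 + 2 * reserve_flank
            else:
                c, start = contig, at
            paste(c, start, insert)
            gene_no += 1
            gid = f"{species}_g{gene_no:03d}"
            if strand == "+":
                g_start, g_end = start, start + cds_end_in_block
                core5 = start + secis_core5 if secis_core5 >= 0 else -1
            else:
                g_start = start + len(block) - cds_end_in_block
                g_end = start + len(block)
                core5 = (
                    start + len(block) - secis_core5 - len(grammar.core5)
                    if secis_core5 >= 0 else -1
                )
            rec = TruthRecord(
                gene_id=gid, species=species, contig=f"{species}_c{c + 1}",
                start=g_start, end=g_end, strand=strand,
                family=member.family, member_id=member.id,
                planted_class=planted_class,
                sec_codon_offsets=sec_offsets,
                secis_present=secis_core5 >= 0,
                secis_core5_start=core5,
                cluster_id=cluster_id,
                indel_codon=indel[0] if indel else -1,
                indel_kind=indel[1] if indel else "",
                indel_length=indel[2] if indel else 0,
            )
            sp_truth.append(rec)
            if planted_class != "Pseudogene":
                sp_tx.append((gid, tx if strand == "+" else tx))
            return rec

        # --- tandem clusters (drawn from the Sec and Cys quotas) ---
        n_cluster_sec = min(spec.n_clusters, spec.n_sec_genes)
        n_cluster_cys = min(spec.n_clusters, spec.n_cys_homologs)
        for ci in range(spec.n_clusters):
            cl_id = f"{species}_cl{ci + 1}"
            m1 = rng.choice(sec_members)
            # different family: a same-family tandem pair is a cluster, not a
            # segmental duplication, and must not look like one
            m2 = rng.choice([m for m in sec_members if m.family != m1.family])
            gap = rng.randrange(500, spec.cluster_gap_nt + 1)
            blk1_len = 3 * len(m1.residues) + 3 + 400 + 60
            blk2_len = 3 * len(m2.residues) + 3 + 400 + 60
            c, start0 = packer.place(blk1_len + gap + blk2_len)
            r1 = plant_one("Sec" if ci < n_cluster_sec else "Cys", m1,
                           cluster_id=cl_id, contig=c, at=start0)
            r2 = plant_one("Cys" if ci < n_cluster_cys else "Sec", m2,
                           cluster_id=cl_id, contig=c, at=r1.end + gap)

        planted_sec = sum(1 for r in sp_truth if r.planted_class == "Sec")
        planted_cys = sum(1 for r in sp_truth if r.planted_class == "Cys")

        # --- duplications (Sec genes with reserved flanks, copied >=98%) ---
        dup_sources: list[TruthRecord] = []
        n_dup = min(spec.n_duplications,
                    max(0, spec.n_sec_genes - planted_sec) // 2)
        for di in range(n_dup):
            member = rng.choice(sec_members)
            rec = plant_one("Sec", member,
                            reserve_flank=spec.duplication_flank_nt)
            dup_sources.append(rec)

        # --- remaining singleton genes ---
        for _ in range(spec.n_sec_genes - planted_sec - n_dup * 2):
            plant_one("Sec", rng.choice(sec_members))
        for _ in range(spec.n_cys_homologs - planted_cys):
            plant_one("Cys", rng.choice(sec_members))
        for _ in range(spec.n_other_homologs):
            plant_one("Other", rng.choice(sec_members))
        for _ in range(spec.n_pseudogenes):
            member = rng.choice(sec_members)
            n_codons = len(member.residues) + 1
            codon = rng.randrange(10, n_codons - 10)
            kind = rng.choice(("deletion", "insertion"))
            length = rng.choice((1, 2))
            plant_one("Pseudogene", member, indel=(codon, kind, length))

        # --- materialize contigs, then copy duplication segments ---
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = [lut[g.astype(np.intp)].tobytes().decode() for g in genome]
        for di, src in enumerate(dup_sources):
            copy_rec = _copy_duplication(
                src, seqs, packer, spec, rng, f"{species}_dup{di + 1}",
                sp_truth, species, gene_no,
            )
            gene_no += 1
            sp_tx.append((copy_rec.gene_id,
                          _transcript_from_genome(copy_rec, seqs, grammar)))
        contigs[species] = [
            Contig(f"{species}_c{i + 1}", s, species)
            for i, s in enumerate(seqs)
        ]
        truth.extend(sp_truth)
        transcripts[species] = sp_tx

        sp_ests, links = sample_ests(
            sp_tx, spec.n_ests, spec.est_error_rate, rng, prefix=species,
        )
        ests[species] = sp_ests
        est_links.update(links)

    return Cohort(spec, ref_db, contigs, truth, transcripts, ests, est_links)


def _transcript_from_genome(rec: TruthRecord, seqs: list[str],
                            grammar: SECISGrammar) -> str:
    ci = int(rec.contig.rsplit("_c", 1)[1]) - 1
    lo, hi = rec.start, min(len(seqs[ci]), rec.end + 600)
    piece = seqs[ci][lo:hi]
    return piece if rec.strand == "+" else reverse_complement(piece)


def _copy_duplication(src: TruthRecord, seqs: list[str], packer: _Packer,
                      spec: SyntheticCohortSpec, rng: random.Random,
                      dup_id: str, sp_truth: list[TruthRecord],
                      species: str, gene_no: int) -> TruthRecord:
    """Copy a gene plus both flanks to a distant locus at >=98% identity."""
    flank = spec.duplication_flank_nt
    ci = int(src.contig.rsplit("_c", 1)[1]) - 1
    seg_lo = max(0, src.start - flank)
    seg_hi = min(len(seqs[ci]), src.end + 3 + flank)
    segment = seqs[ci][seg_lo:seg_hi]
    # substitutions at <=2%, sparing the gene's Sec/stop-determining codons
    chars = list(segment)
    gene_lo, gene_hi = src.start - seg_lo, src.end - seg_lo
    for p in range(len(chars)):
        if gene_lo <= p < gene_hi + 500:  # spare CDS, stop, and SECIS region
            continue
        if rng.random() < 0.01:
            chars[p] = rng.choice("ACGT".replace(chars[p], ""))
    mutated = "".join(chars)
    c, start0 = packer.place(len(mutated) + 2 * flank)
    start = start0 + flank  # keep neighbours a flank length away (see above)
    seqs[c] = seqs[c][:start] + mutated + seqs[c][start + len(mutated):]
    gid = f"{species}_g{gene_no + 1:03d}"
    rec = TruthRecord(
        gene_id=gid, species=species, contig=f"{species}_c{c + 1}",
        start=start + gene_lo, end=start + gene_hi, strand=src.strand,
        family=src.family, member_id=src.member_id,
        planted_class=src.planted_class,
        sec_codon_offsets=src.sec_codon_offsets,
        secis_present=src.secis_present,
        secis_core5_start=(
            start + (src.secis_core5_start - seg_lo)
            if src.secis_core5_start >= 0 else -1
        ),
        duplication_id=dup_id,
    )
    sp_truth.append(rec)
    # mark the source record with the duplication label too
    idx = sp_truth.index(src)
    sp_truth[idx] = replace(src, duplication_id=dup_id)
    return rec


def sample_ests(transcripts: list[tuple[str, str]], n: int, error_rate: float,
                rng: random.Random, prefix: str = "est",
                ) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Sample error-bearing substrings of planted transcripts.

    Returns (ests, links) where links maps EST id -> source gene id.
    """
    ests: list[tuple[str, str]] = []
    links: dict[str, str] = {}
    if not transcripts or n <= 0:
        return ests, links
    for i in range(n):
        gid, tx = transcripts[rng.randrange(len(transcripts))]
        length = min(len(tx), rng.randrange(150, 401))
        start = rng.randrange(len(tx) - length + 1)
        piece = list(tx[start : start + length])
        for p in range(len(piece)):
            if rng.random() < error_rate:
                piece[p] = rng.choice("ACGT".replace(piece[p], ""))
        eid = f"{prefix}_est{i + 1:04d}"
        ests.append((eid, "".join(piece)))
        links[eid] = gid
    return ests, links


def dinucleotide_shuffle(seq: str, rng: random.Random, max_tries: int = 200) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul–Erikson style: pick random last-exit edges forming a tree into
    the terminal vertex, shuffle the remaining edges, and walk the Eulerian
    path.  Used to build realistic null sequence for false-positive
    estimation of the SECIS scanner.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last_vertex = seq[-1]
    vertices = sorted(edges)
    for _ in range(max_tries):
        last_edge = {}
        for v in vertices:
            if v == last_vertex:
                continue
            last_edge[v] = rng.choice(edges[v])
        # tree check: every vertex must reach last_vertex via last edges
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last_vertex:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        walk_edges = {}
        for v in vertices:
            rest = list(edges[v])
            if v in last_edge:
                rest.remove(last_edge[v])
            rng.shuffle(rest)
            if v in last_edge:
                rest.append(last_edge[v])
            walk_edges[v] = rest
        out = [seq[0]]
        cur = seq[0]
        while walk_edges.get(cur):
            nxt = walk_edges[cur].pop(0)
            out.append(nxt)
            cur = nxt
        if len(out) == len(seq):
            return "".join(out)
    return "".join(rng.sample(seq, len(seq)))  # fallback: mononucleotide
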