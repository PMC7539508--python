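"""Reference selenoprotein-family database and Sec-aware scoring model.

Reference proteins are stored with selenocysteine written as ``U``.  A family
groups the reference members used as alignment targets, optionally with a
canonical Sec-flank motif (``x`` matches any residue) such as ``GUGUU`` for
PDI_e or ``UxxC`` for AhpC_b.  The scoring model extends a standard amino-acid
substitution table with a ``U`` row inherited from ``C`` plus a U–U bonus, so
Sec–Sec pairings are preferred over Sec–Cys, which in turn beat every other
Sec pairing.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Align import substitution_matrices

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = STANDARD_AA + "UX"

_HEADER_RE = re.compile(r"family=(\S+)")


class ReferenceDBError(ValueError):
    """Raised for malformed reference-database input."""


@dataclass(frozen=True)
class ReferenceSequence:
    """One reference protein; ``sec_positions`` are the 0-based ``U`` indices."""

    id: str
    family: str
    residues: str
    sec_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.residues:
            raise ReferenceDBError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ReferenceDBError(
                f"record {self.id!r}: residues outside alphabet: {sorted(bad)}"
            )
        derived = tuple(i for i, r in enumerate(self.residues) if r == "U")
        if tuple(self.sec_positions) != derived:
            object.__setattr__(self, "sec_positions", derived)

    @property
    def n_sec(self) -> int:
        return len(self.sec_positions)


@dataclass(frozen=True)
class ReferenceFamily:
    """A named selenoprotein family with its reference members."""

    name: str
    members: tuple[ReferenceSequence, ...]
    canonical_motif: str | None = None

    def __post_init__(self):
        if not self.members:
            raise ReferenceDBError(f"family {self.name!r} has zero members")
        for m in self.members:
            if m.family != self.name:
                raise ReferenceDBError(
                    f"member {m.id!r} carries family {m.family!r} != {self.name!r}"
                )
        if self.canonical_motif is not None:
            if not any(
                find_motif(m.residues, self.canonical_motif) is not None
                for m in self.members
            ):
                raise ReferenceDBError(
                    f"family {self.name!r}: no member contains motif "
                    f"{self.canonical_motif!r}"
                )


def find_motif(residues: str, motif: str) -> tuple[int, int] | None:
    """Locate ``motif`` (with ``x`` wildcards) in ``residues``.

    Returns the 0-based half-open span of the first occurrence, or None.
    """
    pattern = re.compile("".join("." if c == "x" else re.escape(c) for c in motif))
    m = pattern.search(residues)
    return (m.start(), m.end()) if m else None


@dataclass(frozen=True)
class ScoringMatrix:
    """Symmetric integer substitution scores over the 22-letter alphabet."""

    alphabet: str
    scores: dict
    gap_open: int
    gap_extend: int

    def __post_init__(self):
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        for a in self.alphabet:
            for b in self.alphabet:
                if self.scores[a, b] != self.scores[b, a]:
                    raise ValueError(f"asymmetric score for ({a},{b})")
        if not (self.scores["U", "U"] > self.scores["U", "C"]):
            raise ValueError("U-U must outscore U-C")
        worst_ok = max(
            self.scores["U", r] for r in STANDARD_AA if r != "C"
        )
        if not (self.scores["U", "C"] > worst_ok):
            raise ValueError("U-C must outscore every other U pairing")

    def score(self, a: str, b: str) -> int:
        return self.scores[a, b]


def build_scoring_matrix(
    base: str = "BLOSUM62", sec_bonus: int = 2,
    gap_open: int = -11, gap_extend: int = -1,
) -> ScoringMatrix:
    """Extend a named substitution table with Sec scoring.

    The ``U`` row copies the ``C`` row of the base table, except
    score(U,U) = score(C,C) + ``sec_bonus``.  ``X`` uses the base table's
    ambiguity row (``U``/``X`` pairs score as ``C``/``X``).
    """
    if sec_bonus <= 0:
        raise ValueError("sec_bonus must be positive")
    base_m = substitution_matrices.load(base)
    scores: dict[tuple[str, str], int] = {}
    letters = STANDARD_AA + "X"
    for a in letters:
        for b in letters:
            scores[a, b] = int(base_m[a, b])
    for b in letters:
        scores["U", b] = scores[b, "U"] = scores["C", b]
    scores["U", "U"] = scores["C", "C"] + sec_bonus
    return ScoringMatrix(ALPHABET, scores, gap_open, gap_extend)


@dataclass
class Parameters:
    """Tunable thresholds for the whole pipeline.

    Fractions are in [0, 1]; lengths in nucleotides unless suffixed ``_aa``.
    Duplication thresholds follow the published rules: protein positive rate
    above 0.50, flank identity at least 0.80 on counted blocks, summed block
    coverage at least 0.20 of the compared segment, 10 kb flanks.
    """

    max_readthrough_tga: int = 3
    min_orf_aa: int = 30
    require_atg: bool = False
    sec_window: int = 5
    min_window_positive_frac: float = 0.4
    min_hit_score: int = 60
    secis_search_window_nt: int = 3000
    duplication_positive_frac: float = 0.50
    duplication_identity_frac: float = 0.80
    duplication_coverage_frac: float = 0.20
    duplication_flank_nt: int = 10000
    cluster_max_gap_nt: int = 10000
    est_min_identity_frac: float = 0.95
    prefilter_kmer_k: int = 5
    prefilter_min_seeds: int = 2
    frameshift_penalty: int = -12
    codon_gap_penalty: int = -8
    seed: int = 0

    def __post_init__(self):
        for name in (
            "min_window_positive_frac", "duplication_positive_frac",
            "duplication_identity_frac", "duplication_coverage_frac",
            "est_min_identity_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "min_orf_aa", "sec_window", "secis_search_window_nt",
            "duplication_flank_nt", "cluster_max_gap_nt", "prefilter_kmer_k",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_readthrough_tga < 0:
            raise ValueError("max_readthrough_tga must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "Parameters":
        data = json.loads(Path(path).read_text())
        data.pop("schema_version", None)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        payload = {"schema_version": 1, **asdict(self)}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_reference_db(path: str | Path) -> list[ReferenceFamily]:
    """Load reference families from FASTA with ``family=NAME`` header metadata.

    Sec positions are derived directly from ``U`` residues.  Duplicate record
    ids and headers without a family key are rejected.  An optional
    ``motif=PATTERN`` key on any member sets the family's canonical motif.
    """
    by_family: dict[str, list[ReferenceSequence]] = {}
    motifs: dict[str, str] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _HEADER_RE.search(rec.description)
        if not m:
            raise ReferenceDBError(
                f"record {rec.id!r}: header lacks 'family=' metadata"
            )
        family = m.group(1)
        if rec.id in seen:
            raise ReferenceDBError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        mm = re.search(r"motif=(\S+)", rec.description)
        if mm:
            motifs[family] = mm.group(1)
        by_family.setdefault(family, []).append(
            ReferenceSequence(rec.id, family, str(rec.seq).upper())
        )
    return [
        ReferenceFamily(name, tuple(members), motifs.get(name))
        for name, members in sorted(by_family.items())
    ]


def write_reference_db(families: Iterable[ReferenceFamily], path: str | Path) -> None:
    """Write families back to the FASTA-with-metadata dialect (round-trips)."""
    with open(path, "w") as fh:
        for fam in families:
            for i, member in enumerate(fam.members):
                extra = (
                    f" motif={fam.canonical_motif}"
                    if fam.canonical_motif and i == 0 else ""
                )
                fh.write(f">{member.id} family={fam.name}{extra}\n")
                for j in range(0, len(member.residues), 70):
                    fh.write(member.residues[j : j + 70] + "\n")
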