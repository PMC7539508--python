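"""Stage orchestration: ORFs -> homology -> SECIS -> pseudogene rule, and
evaluation of calls against a planted truth table."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .homology import (
    ReferenceIndex, SelenoproteinCall, all_family_hits, assemble_calls,
    detect_fusion, FusionCall,
)
from .orffind import Contig, enumerate_orfs
from .refdb import Parameters, ReferenceFamily, ScoringMatrix, build_scoring_matrix
from .secis import SECISGrammar, attach_secis
from .orffind import CandidateORF

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class PredictResult:
    species: str
    calls: list[SelenoproteinCall]
    fusions: list[FusionCall]
    n_orfs: int = 0
    n_filtered: int = 0
    secis_elements: list = field(default_factory=list)


def predict_species(
    contigs: list[Contig], ref_db: list[ReferenceFamily], params: Parameters,
    matrix: ScoringMatrix | None = None, grammar: SECISGrammar | None = None,
    ests: list[tuple[str, str]] | None = None, species: str = "",
) -> PredictResult:
    """Run the full discovery pipeline on one species' contigs."""
    matrix = matrix or build_scoring_matrix()
    grammar = grammar or SECISGrammar(
        max_distance_from_stop=params.secis_search_window_nt,
    )
    index = ReferenceIndex(ref_db, params)
    contig_seq = {c.id: c.seq for c in contigs}

    scored: list[tuple[CandidateORF, object]] = []
    fusions: list[FusionCall] = []
    n_orfs = n_filtered = 0
    for contig in contigs:
        orfs = enumerate_orfs(contig, params)
        n_orfs += len(orfs)
        for orf in orfs:
            per_family = all_family_hits(orf, index, matrix, params)
            if not per_family:
                continue
            n_filtered += 1
            best = min(
                per_family.values(),
                key=lambda h: (-h.score, h.family, h.ref_id),
            )
            scored.append((orf, best))
            if len(per_family) > 1:
                fusions.extend(detect_fusion(per_family, params))
        logger.info("contig %s: %d ORFs, %d with hits",
                    contig.id, len(orfs), n_filtered)

    calls = assemble_calls(
        scored, index, matrix, params, contig_seq, ests=ests, species=species,
    )

    # SECIS search downstream of every identified gene
    all_elements = []
    for call in calls:
        stop_len = _stop_len(call, contig_seq[call.contig])
        pseudo_orf = CandidateORF(
            call.contig, call.strand, call.start, call.end, 0, "M", (),
            "TAA" if stop_len else None,
        )
        elements = attach_secis(pseudo_orf, Contig(call.contig, contig_seq[call.contig]), grammar)
        call.secis = elements
        call.confidence = (
            "high" if call.overall_class == "Sec" and elements else "medium"
        )
        all_elements.extend(elements)

    logger.info(
        "species %s: %d ORFs -> %d hits -> %d calls (%d Sec, %d pseudo)",
        species, n_orfs, n_filtered, len(calls),
        sum(c.overall_class == "Sec" for c in calls),
        sum(c.pseudogene for c in calls),
    )
    return PredictResult(species, calls, _dedupe_fusions(fusions),
                         n_orfs, n_filtered, all_elements)


def _stop_len(call: SelenoproteinCall, seq: str) -> int:
    if call.strand == "+":
        codon = seq[call.end : call.end + 3]
    else:
        from .orffind import reverse_complement
        codon = reverse_complement(seq[max(0, call.start - 3) : call.start])
    return 3 if codon in STOP_CODONS else 0


def _dedupe_fusions(fusions: list[FusionCall]) -> list[FusionCall]:
    seen = set()
    out = []
    for f in sorted(fusions, key=lambda f: (f.query_id, f.family_a, f.family_b)):
        key = (f.query_id, f.family_a, f.family_b)
        if key not in seen:
            seen.add(key)
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# Evaluation against planted truth
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a0: int, a1: int, b0: int, b1: int) -> float:
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def evaluate_against_truth(
    calls: list[SelenoproteinCall], truth, min_overlap: float = 0.5,
) -> dict:
    """Match calls to truth records by >=50% reciprocal coordinate overlap.

    Returns a dict with per-class sensitivity/precision, the family accuracy
    among matched calls, a truth-class x called-class confusion table
    (with a ``missed`` column), and the Sec<->Cys swap count.  Precision for
    a class with zero calls is reported as NaN.
    """
    classes = ["Sec", "Cys", "Other", "Pseudogene"]
    match_of_truth: dict[int, SelenoproteinCall] = {}
    used: set[int] = set()
    for ti, t in enumerate(truth):
        best, best_ov, best_ci = None, 0.0, -1
        for ci, c in enumerate(calls):
            if ci in used or c.species != t.species or c.contig != t.contig:
                continue
            if c.strand != t.strand:
                continue
            ov = _reciprocal_overlap(c.start, c.end, t.start, t.end)
            if ov >= min_overlap and ov > best_ov:
                best, best_ov, best_ci = c, ov, ci
        if best is not None:
            match_of_truth[ti] = best
            used.add(best_ci)

    confusion = pd.DataFrame(
        0, index=pd.Index(classes, name="truth"), columns=classes + ["missed"],
    )
    family_ok = family_total = 0
    for ti, t in enumerate(truth):
        call = match_of_truth.get(ti)
        if call is None:
            confusion.loc[t.planted_class, "missed"] += 1
        else:
            confusion.loc[t.planted_class, call.called_class] += 1
            family_total += 1
            family_ok += call.family == t.family

    sensitivity, precision = {}, {}
    for cls in classes:
        n_truth = sum(t.planted_class == cls for t in truth)
        n_correct = int(confusion.loc[cls, cls])
        sensitivity[cls] = n_correct / n_truth if n_truth else float("nan")
        n_called = sum(c.called_class == cls for c in calls)
        precision[cls] = n_correct / n_called if n_called else float("nan")

    # Sec genes correctly matched AND assigned the right family
    sec_truth = [ti for ti, t in enumerate(truth) if t.planted_class == "Sec"]
    sec_ok = sum(
        1 for ti in sec_truth
        if (c := match_of_truth.get(ti)) is not None
        and c.called_class == "Sec" and c.family == truth[ti].family
    )
    swaps = int(confusion.loc["Sec", "Cys"] + confusion.loc["Cys", "Sec"])
    return {
        "confusion": confusion,
        "sensitivity": sensitivity,
        "precision": precision,
        "family_accuracy": family_ok / family_total if family_total else float("nan"),
        "sec_sensitivity_with_family": (
            sec_ok / len(sec_truth) if sec_truth else float("nan")
        ),
        "sec_cys_swaps": swaps,
        "n_calls": len(calls),
        "n_truth": len(truth),
        "n_matched": len(match_of_truth),
    }
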