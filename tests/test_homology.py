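"""Sec-aware alignment, Sec-site classification, frameshifts, fusion."""

import random

import pytest

from selenoscan.homology import (
    GAP, FrameshiftEvent, ReferenceIndex, align_sec_aware, all_family_hits,
    best_family_hit, call_pseudogene, classify_sec_sites, detect_frameshifts,
    detect_fusion, est_supports_event, extract_motif, recompute_score,
)
from selenoscan.orffind import CandidateORF
from selenoscan.refdb import Parameters, ReferenceSequence
from selenoscan.simgen import back_translate, make_reference_db

from oracles import local_align_score

AA = "ACDEFGHIKLMNPQRSTVWYU"


def _rand_pep(rng, n, u_prob=0.1):
    return "".join(
        "U" if rng.random() < u_prob else rng.choice(AA[:-1]) for _ in range(n)
    )


class TestAligner:
    def test_self_alignment_scores_diagonal_sum(self, matrix):
        pep = "MKAUCWGGHILUV"
        hit = align_sec_aware(pep, pep, matrix)
        assert hit.score == sum(matrix.scores[a, a] for a in pep)
        assert hit.query_span == (0, len(pep))
        assert hit.ref_span == (0, len(pep))

    def test_matches_brute_force_oracle(self, matrix):
        """Exactness on 200 random pairs (length <= 40), U included."""
        rng = random.Random(2024)
        for _ in range(200):
            q = _rand_pep(rng, rng.randrange(5, 41))
            r = _rand_pep(rng, rng.randrange(5, 41))
            hit = align_sec_aware(q, r, matrix)
            expected = local_align_score(
                q, r, matrix.scores, matrix.gap_open, matrix.gap_extend,
            )
            assert hit.score == expected, (q, r)

    def test_score_recomputes_from_columns(self, matrix):
        rng = random.Random(8)
        for _ in range(50):
            q = _rand_pep(rng, rng.randrange(10, 60))
            r = _rand_pep(rng, rng.randrange(10, 60))
            hit = align_sec_aware(q, r, matrix)
            assert recompute_score(hit, q, r, matrix) == hit.score

    def test_uxxc_context_pairs_sec_with_cys(self, matrix):
        ref = ReferenceSequence("r", "fam", "MGKLWUAHCDERFG")  # UxxC context
        query = "MGKLWCAHCDERFG"
        hit = align_sec_aware(query, ref, matrix)
        pairs = dict((r, q) for q, r in hit.aligned_columns if r != GAP)
        sec_col = ref.sec_positions[0]
        assert query[pairs[sec_col]] == "C"

    def test_non_alphabet_residue_rejected(self, matrix):
        with pytest.raises(ValueError, match="query"):
            align_sec_aware("MA0G", "MAG", matrix)


class TestClassification:
    def _ref_and_hit(self, matrix, query_residue):
        residues = "MKWAGH" + "U" + "LIVEQR"
        ref = ReferenceSequence("r1", "fam", residues)
        query = residues.replace("U", query_residue)
        hit = align_sec_aware(query, ref, matrix)
        return hit, query, ref

    @pytest.mark.parametrize("residue,expected", [
        ("U", "Sec"), ("C", "Cys"), ("W", "Other"),
    ])
    def test_residue_classes(self, matrix, params, residue, expected):
        hit, query, ref = self._ref_and_hit(matrix, residue)
        (call,) = classify_sec_sites(hit, query, ref, matrix, params)
        assert call.site_class == expected
        assert call.query_residue == residue

    def test_weak_window_demotes_to_unaligned(self, matrix, params):
        ref = ReferenceSequence("r1", "fam", "MKWAGH" + "U" + "LIVEQR")
        # scrambled context around an opportunistic U pairing
        query = "PPPPPPUPPPPPP"
        hit = align_sec_aware(query, ref, matrix)
        calls = classify_sec_sites(hit, query, ref, matrix, params)
        assert all(c.site_class == "Unaligned" for c in calls)

    def test_motif_extraction_uses_family_motif_columns(self, matrix):
        db = make_reference_db(seed=0)
        pdi_e = next(f for f in db if f.name == "PDI_e")
        member = pdi_e.members[0]
        hit = align_sec_aware(member.residues, member, matrix)
        motif = extract_motif(hit, member.residues, member, "GUGUU")
        assert motif == "GUGUU"


class TestFamilySearch:
    def test_planted_member_finds_own_family(self, matrix, ref_db, params):
        index = ReferenceIndex(ref_db, params)
        member = ref_db[2].members[0]  # GPX
        orf = CandidateORF("c", "+", 0, 3 * member.n_sec, 0,
                           member.residues, member.sec_positions, None)
        result = best_family_hit(orf, index, matrix, params)
        assert result is not None
        assert result[1] == member.family

    def test_random_peptide_finds_nothing(self, matrix, ref_db, params):
        rng = random.Random(33)
        index = ReferenceIndex(ref_db, params)
        for _ in range(20):
            orf = CandidateORF("c", "+", 0, 120, 0,
                               _rand_pep(rng, 40, u_prob=0), (), None)
            assert best_family_hit(orf, index, matrix, params) is None

    def test_raising_threshold_never_adds_calls(self, matrix, ref_db):
        index_lo = ReferenceIndex(ref_db, Parameters(min_hit_score=40))
        member = ref_db[0].members[0]
        orf = CandidateORF("c", "+", 0, 0, 0, member.residues,
                          member.sec_positions, None)
        lo = all_family_hits(orf, index_lo, matrix, Parameters(min_hit_score=40))
        hi = all_family_hits(orf, index_lo, matrix, Parameters(min_hit_score=200))
        assert set(hi) <= set(lo)


class TestFrameshifts:
    def _cds(self, member):
        rng = random.Random(0)
        cds, _ = back_translate(member.residues, "Sec", rng)
        return cds

    def test_exact_cds_has_no_events(self, matrix, ref_db, params):
        member = ref_db[3].members[0]
        cds = self._cds(member)
        assert detect_frameshifts(member, cds, matrix, params) == []

    def test_single_deletion_localized(self, matrix, ref_db, params):
        member = ref_db[3].members[0]
        cds = self._cds(member)
        mutated = cds[:30] + cds[31:]  # 1-nt deletion at codon 10
        events = detect_frameshifts(member, mutated, matrix, params)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "deletion" and ev.length == 1
        assert abs(ev.offset_nt - 30) <= 3

    def test_tiny_instances_match_exhaustive_oracle(self, matrix, params):
        from oracles import exhaustive_frameshift_events

        rng = random.Random(14)
        for trial in range(15):
            n = rng.randrange(8, 13)
            pep = "M" + "".join(rng.choice(AA[:-1]) for _ in range(n - 1))
            ref = ReferenceSequence(f"t{trial}", "fam", pep)
            cds, _ = back_translate(pep, "Sec", rng)
            cds = cds[:-3]  # drop stop
            if rng.random() < 0.7:
                codon = rng.randrange(2, n - 2)
                kind = rng.choice(("deletion", "insertion"))
                length = rng.choice((1, 2))
                p = 3 * codon
                if kind == "deletion":
                    cds = cds[:p] + cds[p + length:]
                else:
                    ins = "".join(rng.choice("ACGT") for _ in range(length))
                    cds = cds[:p] + ins + cds[p:]
                expected = [(kind, length)]
            else:
                expected = []
            got = detect_frameshifts(ref, cds, matrix, params)
            oracle = exhaustive_frameshift_events(
                pep, cds, matrix.scores, params.frameshift_penalty,
                params.codon_gap_penalty,
            )
            # the DP must agree with the exhaustive oracle; whether the
            # planted indel is worth reporting at all on so short a peptide
            # is the oracle's call (a slip near the end can score worse than
            # absorbing the frameshifted tail as mismatches)
            del expected
            assert sorted((e.kind, e.length) for e in got) == \
                sorted((k, l) for _p, k, l in oracle)
            for e, (op, _k, _l) in zip(got, oracle):
                assert abs(e.offset_nt - op) <= 3


class TestPseudogeneRule:
    def test_unsupported_event_flags_pseudogene(self):
        assert call_pseudogene([FrameshiftEvent(30, "deletion", 1, False)])

    def test_supported_event_does_not_flag(self):
        assert not call_pseudogene([FrameshiftEvent(30, "deletion", 1, True)])

    def test_no_events_no_flag(self):
        assert not call_pseudogene([])

    def test_matching_est_supports_event(self, ref_db, params):
        rng = random.Random(5)
        member = ref_db[4].members[0]
        cds, _ = back_translate(member.residues, "Sec", rng)
        mutated = cds[:60] + cds[61:]  # genomic deletion at nt 60
        est = mutated[20:220]  # EST transcribed from the mutant locus
        assert est_supports_event(60, mutated, [("e1", est)], params)

    def test_est_from_functional_paralog_contradicts_event(self, ref_db, params):
        rng = random.Random(5)
        member = ref_db[4].members[0]
        cds, _ = back_translate(member.residues, "Sec", rng)
        mutated = cds[:60] + cds[61:]
        est = cds[20:220]  # EST from the intact paralog: gap at the indel
        assert not est_supports_event(60, mutated, [("e1", est)], params)


class TestFusion:
    def _fusion_orf(self, ref_db):
        gst = next(f for f in ref_db if f.name == "GST").members[0]
        msra = next(f for f in ref_db if f.name == "MSRA").members[0]
        pep = gst.residues + "GSGS" + msra.residues
        return CandidateORF("c", "+", 0, 3 * len(pep), 0, pep, (), None)

    def test_concatenated_families_yield_one_fusion(self, matrix, ref_db, params):
        index = ReferenceIndex(ref_db, params)
        orf = self._fusion_orf(ref_db)
        hits = all_family_hits(orf, index, matrix, params)
        calls = detect_fusion(hits, params)
        assert [(c.family_a, c.family_b) for c in calls] == [("GST", "MSRA")]
        assert calls[0].span_a[1] <= calls[0].span_b[0]

    def test_single_family_no_fusion(self, matrix, ref_db, params):
        index = ReferenceIndex(ref_db, params)
        member = ref_db[0].members[0]
        orf = CandidateORF("c", "+", 0, 0, 0, member.residues,
                          member.sec_positions, None)
        hits = all_family_hits(orf, index, matrix, params)
        assert detect_fusion(hits, params) == []

    def test_overlapping_hits_no_fusion(self, params):
        from selenoscan.homology import AlignmentHit

        a = AlignmentHit("q", "r1", "GST", 100, (0, 50), (0, 50), ())
        b = AlignmentHit("q", "r2", "MSRA", 100, (30, 80), (0, 50), ())
        assert detect_fusion({"GST": a, "MSRA": b}, params) == []
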