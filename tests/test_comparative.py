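"""Comparative layer: clusters, duplications, presence matrix, motifs."""

import random

import pandas as pd
import pytest

from selenoscan.comparative import (
    build_matrix, cluster_matrix, detect_clusters, detect_duplications,
    matrix_totals, motif_census,
)
from selenoscan.homology import SelenoproteinCall
from selenoscan.refdb import Parameters

from oracles import chain_clusters


def _call(species="sp01", contig="c1", start=0, end=300, family="GPX",
          overall="Sec", pseudo=False, motif="", peptide="M"):
    return SelenoproteinCall(
        species=species, contig=contig, strand="+", start=start, end=end,
        family=family, ref_id=f"{family}_1", score=100, site_classes=[],
        overall_class=overall, pseudogene=pseudo, motif=motif,
        peptide=peptide,
    )


class TestClusters:
    def test_two_nearby_genes_form_cluster(self, params):
        calls = [_call(start=0, end=300), _call(start=2300, end=2600, family="GRX")]
        (cluster,) = detect_clusters(calls, params)
        assert cluster.member_ids == ("GPX:Sec", "GRX:Sec")

    def test_single_gene_is_not_a_cluster(self, params):
        assert detect_clusters([_call()], params) == []

    def test_random_layouts_match_chaining_oracle(self, params):
        rng = random.Random(31)
        for _ in range(100):
            n = rng.randrange(0, 12)
            intervals = []
            pos = 0
            for _i in range(n):
                pos += rng.randrange(100, 30_000)
                length = rng.randrange(100, 500)
                intervals.append((pos, pos + length))
                pos += length
            calls = [
                _call(start=s, end=e, family=f"F{i}")
                for i, (s, e) in enumerate(intervals)
            ]
            got = detect_clusters(calls, params)
            expected = chain_clusters(intervals, params.cluster_max_gap_nt)
            got_spans = sorted((c.start, c.end, c.size) for c in got)
            exp_spans = sorted(
                (intervals[ch[0]][0], intervals[ch[-1]][1], len(ch))
                for ch in expected
            )
            assert got_spans == exp_spans


class TestDuplications:
    def test_planted_duplication_detected(self, small_cohort, small_predictions,
                                          matrix):
        result, params = small_predictions
        genome = {c.id: c.seq for c in small_cohort.contigs["sp01"]}
        events = detect_duplications(result.calls, genome, matrix, params)
        truth_dups = {t.duplication_id for t in small_cohort.truth
                      if t.duplication_id}
        assert truth_dups
        assert len(events) == len(truth_dups)
        for e in events:
            assert e.protein_positive_frac > params.duplication_positive_frac
            assert e.flank_identity_frac >= params.duplication_identity_frac
            assert e.flank_coverage_frac >= params.duplication_coverage_frac

    def test_symmetric_in_pair_order(self, small_cohort, small_predictions,
                                     matrix):
        result, params = small_predictions
        genome = {c.id: c.seq for c in small_cohort.contigs["sp01"]}
        fwd = detect_duplications(result.calls, genome, matrix, params)
        rev = detect_duplications(list(reversed(result.calls)), genome,
                                  matrix, params)
        key = lambda e: (e.species, e.family, tuple(sorted((e.call_a, e.call_b))))
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_gene_only_copy_fails_coverage(self, matrix):
        """A copied gene without copied flanks cannot reach 20% coverage of
        the gene+10kb segment."""
        rng = random.Random(2)
        gene = "".join(rng.choice("ACGT") for _ in range(600))
        bg = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        contig = bg(12_000) + gene + bg(24_000) + gene + bg(12_000)
        params = Parameters(duplication_flank_nt=10_000)
        calls = [
            _call(contig="c1", start=12_000, end=12_600, peptide="MKWAGHLIVEQR" * 5),
            _call(contig="c1", start=37_200, end=37_800, peptide="MKWAGHLIVEQR" * 5),
        ]
        events = detect_duplications(calls, {"c1": contig}, matrix, params)
        assert events == []

    def test_cross_family_pairs_never_compared(self, matrix, params):
        calls = [
            _call(family="GPX", peptide="MKWAGHLIVEQR" * 5),
            _call(family="GRX", start=50_000, end=50_300,
                  peptide="MKWAGHLIVEQR" * 5),
        ]
        contig = "A" * 60_000
        assert detect_duplications(calls, {"c1": contig}, matrix, params) == []


class TestMatrix:
    def test_empty_calls_give_all_absent(self):
        m = build_matrix([], families=["GPX"], species=["sp01"])
        assert m.loc["GPX", "sp01"] == "absent"

    def test_union_of_classes(self):
        calls = [
            _call(overall="Sec"),
            _call(start=5000, end=5300, overall="Cys"),
        ]
        m = build_matrix(calls)
        assert m.loc["GPX", "sp01"] == "Sec&Cys"

    def test_pseudogenes_do_not_contribute(self):
        calls = [_call(overall="Cys", pseudo=True)]
        m = build_matrix(calls)
        assert m.loc["GPX", "sp01"] == "absent"

    def test_totals_recount_calls(self):
        calls = [
            _call(overall="Sec"),
            _call(family="GRX", overall="Sec"),
            _call(family="GST", overall="Other"),
            _call(species="sp02", overall="Cys"),
        ]
        totals = matrix_totals(build_matrix(calls))
        assert totals.loc["Sec", "sp01"] == 2
        assert totals.loc["Other", "sp01"] == 1
        assert totals.loc["Cys", "sp02"] == 1

    def test_cell_invariant_to_input_order(self):
        calls = [
            _call(overall="Sec"),
            _call(start=5000, end=5300, overall="Other"),
            _call(family="GRX", overall="Cys"),
        ]
        a = build_matrix(calls)
        b = build_matrix(list(reversed(calls)))
        pd.testing.assert_frame_equal(a, b)


class TestMatrixClustering:
    def _matrix(self):
        calls = []
        for sp in ("spA", "spB", "spC"):
            calls.append(_call(species=sp, family="GPX", overall="Sec"))
        calls.append(_call(species="spA", family="GRX", overall="Cys"))
        calls.append(_call(species="spB", family="GRX", overall="Cys"))
        calls.append(_call(species="spC", family="GST", overall="Other"))
        return build_matrix(calls, species=["spA", "spB", "spC", "spEmpty"])

    def test_identical_columns_are_adjacent(self):
        m = self._matrix()
        _rows, cols, _rz, _cz = cluster_matrix(m)
        ia, ib = cols.index("spA"), cols.index("spB")
        assert abs(ia - ib) == 1

    def test_leaf_order_invariant_to_permutation(self):
        m = self._matrix()
        base = cluster_matrix(m)
        shuffled = m[["spC", "spA", "spEmpty", "spB"]].iloc[::-1]
        again = cluster_matrix(shuffled)
        assert base[0] == again[0]
        assert base[1] == again[1]


class TestMotifCensus:
    def test_empty_input(self):
        assert motif_census([]).empty

    def test_family_class_motif_counts(self):
        calls = [
            _call(motif="GUGUU", family="PDI_e"),
            _call(motif="GUGUU", family="PDI_e", start=9000, end=9300),
            _call(motif="CAKC", family="AhpC_b", overall="Cys"),
        ]
        df = motif_census(calls)
        row = df[(df.family == "PDI_e") & (df.motif == "GUGUU")]
        assert row["count"].tolist() == [2]
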