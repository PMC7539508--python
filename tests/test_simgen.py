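"""Synthetic cohort generator: planted truth is self-consistent and seeded."""

import random
from collections import Counter

import pytest

from selenoscan.orffind import reverse_complement, translate_cds
from selenoscan.simgen import (
    SyntheticCohortSpec, apply_indel, back_translate, dinucleotide_shuffle,
    generate_cohort, make_reference_db, mutate_cds, sample_ests,
)


def _contig_seq(cohort, record):
    for c in cohort.contigs[record.species]:
        if c.id == record.contig:
            return c.seq
    raise KeyError(record.contig)


class TestBackTranslation:
    def test_sec_class_plants_tga_at_sec_positions(self, rng):
        cds, offsets = back_translate("MAUGU", "Sec", rng)
        assert offsets == (2, 4)
        assert cds[6:9] == "TGA" and cds[12:15] == "TGA"
        assert cds.endswith("TAA")

    def test_cys_class_has_no_tga(self, rng):
        cds, offsets = back_translate("MAUGU", "Cys", rng)
        assert offsets == ()
        codons = {cds[i : i + 3] for i in (6, 12)}
        assert codons <= {"TGC", "TGT"}

    def test_other_class_recodes_to_non_cys(self, rng):
        cds, _ = back_translate("MAUGU", "Other", rng)
        assert cds[6:9] in ("TGG", "AGA", "GGA")

    def test_mutations_never_touch_stops_or_sec_flanks(self, rng):
        pep = "M" + "A" * 20 + "U" + "A" * 20
        cds, offsets = back_translate(pep, "Sec", rng)
        mutated = mutate_cds(cds, (21,), 0.5, rng, sec_window=2)
        n = len(mutated) // 3
        codons = [mutated[3 * i : 3 * i + 3] for i in range(n)]
        assert codons[0] == "ATG" and codons[-1] == "TAA"
        assert codons[21] == "TGA"
        assert not any(
            c in ("TAA", "TAG", "TGA")
            for i, c in enumerate(codons[1:-1], start=1) if i != 21
        )

    def test_indel_too_close_to_end_rejected(self, rng):
        cds, _ = back_translate("M" + "A" * 30, "Sec", rng)
        with pytest.raises(ValueError, match="too close"):
            apply_indel(cds, 3, "deletion", 1, rng)


class TestCohortTruth:
    def test_class_counts_match_spec(self, small_cohort):
        spec = small_cohort.spec
        counts = Counter(t.planted_class for t in small_cohort.truth)
        assert counts["Sec"] == spec.n_sec_genes
        assert counts["Cys"] == spec.n_cys_homologs
        assert counts["Other"] == spec.n_other_homologs
        assert counts["Pseudogene"] == spec.n_pseudogenes

    def test_planted_cds_retranslates_to_declared_class(self, small_cohort):
        """Slicing each truth interval back out of the emitted genome must
        reproduce the planted residue class (generator self-check)."""
        for t in small_cohort.truth:
            if t.planted_class == "Pseudogene":
                continue
            seq = _contig_seq(small_cohort, t)
            cds = seq[t.start : t.end]
            if t.strand == "-":
                cds = reverse_complement(cds)
            pep = translate_cds(cds)
            assert "*" not in pep
            u_at = tuple(i for i, a in enumerate(pep) if a == "U")
            if t.planted_class == "Sec":
                assert u_at == t.sec_codon_offsets and u_at
            else:
                assert u_at == ()

    def test_pseudogene_truth_records_indel(self, small_cohort):
        for t in small_cohort.truth:
            if t.planted_class == "Pseudogene":
                assert t.indel_codon >= 5
                assert t.indel_kind in ("deletion", "insertion")
                assert t.indel_length in (1, 2)

    def test_cluster_members_share_contig_within_gap(self, small_cohort):
        by_cluster = {}
        for t in small_cohort.truth:
            if t.cluster_id:
                by_cluster.setdefault(t.cluster_id, []).append(t)
        assert by_cluster
        for members in by_cluster.values():
            assert len(members) >= 2
            assert len({m.contig for m in members}) == 1
            members.sort(key=lambda m: m.start)
            for a, b in zip(members, members[1:]):
                assert 0 < b.start - a.end <= small_cohort.spec.cluster_gap_nt + 500

    def test_duplication_pairs_are_high_identity(self, small_cohort):
        by_dup = {}
        for t in small_cohort.truth:
            if t.duplication_id:
                by_dup.setdefault(t.duplication_id, []).append(t)
        assert by_dup
        for a, b in by_dup.values():
            sa = _contig_seq(small_cohort, a)[a.start : a.end]
            sb = _contig_seq(small_cohort, b)[b.start : b.end]
            assert len(sa) == len(sb)
            ident = sum(x == y for x, y in zip(sa, sb)) / len(sa)
            assert ident >= 0.98

    def test_reproducible_from_seed(self):
        spec = SyntheticCohortSpec(
            n_species=1, contigs_per_species=1, contig_length_nt=40_000,
            n_sec_genes=3, n_cys_homologs=2, n_other_homologs=1,
            n_pseudogenes=1, n_clusters=1, n_duplications=0, seed=99,
        )
        a, b = generate_cohort(spec), generate_cohort(spec)
        assert [c.seq for c in a.contigs["sp01"]] == \
            [c.seq for c in b.contigs["sp01"]]
        assert a.truth == b.truth
        assert a.ests == b.ests

    def test_reverse_strand_flag_plants_minus_genes(self):
        spec = SyntheticCohortSpec(
            n_species=1, contigs_per_species=1, contig_length_nt=60_000,
            n_sec_genes=6, n_cys_homologs=0, n_other_homologs=0,
            n_pseudogenes=0, n_clusters=0, n_duplications=0,
            reverse_strand_frac=1.0, seed=5,
        )
        cohort = generate_cohort(spec)
        assert all(t.strand == "-" for t in cohort.truth)


class TestESTs:
    def test_zero_error_est_is_exact_substring(self, rng):
        tx = [("g1", "".join(rng.choice("ACGT") for _ in range(800)))]
        ests, links = sample_ests(tx, 10, 0.0, rng)
        for eid, seq in ests:
            assert seq in tx[0][1]
            assert links[eid] == "g1"

    def test_seeded_reproducibility(self):
        tx = [("g1", "ACGT" * 200)]
        a = sample_ests(tx, 5, 0.01, random.Random(3))
        b = sample_ests(tx, 5, 0.01, random.Random(3))
        assert a == b

    def test_no_ests_from_pseudogenes(self, small_cohort):
        pseudo_ids = {t.gene_id for t in small_cohort.truth
                      if t.planted_class == "Pseudogene"}
        assert pseudo_ids
        assert not pseudo_ids & set(small_cohort.est_links.values())


class TestShuffle:
    def test_dinucleotide_counts_preserved(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(1000))
        shuffled = dinucleotide_shuffle(seq, rng)
        count = lambda s: Counter(zip(s, s[1:]))
        assert count(shuffled) == count(seq)
        assert shuffled != seq


class TestReferenceDB:
    def test_families_carry_expected_motifs(self, ref_db):
        motifs = {f.name: f.canonical_motif for f in ref_db}
        assert motifs["PDI_e"] == "GUGUU"
        assert motifs["AhpC_b"] == "UxxC"
        assert motifs["AhpC_a"] == "TGGUT"
        assert motifs["SELENOF"] == "CxU"
        pdi_e = next(f for f in ref_db if f.name == "PDI_e")
        assert all(m.n_sec == 3 for m in pdi_e.members)
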