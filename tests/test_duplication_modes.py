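"""Tandem-array chaining rules, retrocopy calls and chromosome summaries."""

import pytest

from famex.duplication_modes import (
    chromosome_distribution,
    detect_retrocopies,
    detect_tandem_arrays,
)
from famex.family_catalog import FamilyMember, select_family_members
from famex.io_formats import GeneModel, TranscriptModel

from .conftest import make_gene


def member(gene_id: str) -> FamilyMember:
    return FamilyMember(gene_id, f"{gene_id}.t1", ("BIR",), "G1", "domain_only")


def simple_gene(gene_id, start, end, strand="+", chrom="chr5"):
    tx = TranscriptModel(f"{gene_id}.t1", [(start, end)], [(start, end)])
    return GeneModel(gene_id, chrom, strand, [tx])


def six_gene_array_fixture():
    """Six same-strand family genes between 12,280 and 12,370 kb, flanked by
    non-family genes, with nothing interspersed."""
    genes = [simple_gene("up", 12_150_000, 12_155_000)]
    fam = []
    for i in range(6):
        start = 12_280_000 + i * 15_000
        gid = f"iap{i + 1}"
        genes.append(simple_gene(gid, start, start + 6_000))
        fam.append(member(gid))
    genes.append(simple_gene("down", 12_500_000, 12_505_000))
    return genes, fam


class TestTandemArrays:
    def test_worked_example_single_array_of_six(self):
        genes, fam = six_gene_array_fixture()
        arrays = detect_tandem_arrays(fam, genes)
        assert len(arrays) == 1
        assert arrays[0].size == 6
        assert arrays[0].same_strand
        assert arrays[0].members == [f"iap{i + 1}" for i in range(6)]
        assert arrays[0].n_intervening == 0

    def test_intervening_gene_splits_under_default(self):
        genes = [
            simple_gene("a", 100_000, 105_000),
            simple_gene("x", 110_000, 112_000),  # non-family between
            simple_gene("b", 120_000, 125_000),
        ]
        fam = [member("a"), member("b")]
        assert detect_tandem_arrays(fam, genes) == []
        arrays = detect_tandem_arrays(fam, genes, max_intervening=1)
        assert len(arrays) == 1 and arrays[0].n_intervening == 1

    def test_large_gap_splits_chain(self):
        # five members with one 150-kb gap: sizes must partition as 3 + 2
        starts = [0, 20_000, 40_000, 195_000, 215_000]
        genes = [simple_gene(f"m{i}", s, s + 5_000) for i, s in enumerate(starts)]
        fam = [member(f"m{i}") for i in range(5)]
        arrays = detect_tandem_arrays(fam, genes, max_gap_bp=100_000)
        assert sorted(a.size for a in arrays) == [2, 3]
        assert sum(a.size for a in arrays) == 5

    def test_strand_requirement_only_when_asked(self):
        genes = [
            simple_gene("a", 100_000, 105_000, "+"),
            simple_gene("b", 110_000, 115_000, "-"),
        ]
        fam = [member("a"), member("b")]
        (mixed,) = detect_tandem_arrays(fam, genes)
        assert not mixed.same_strand
        assert detect_tandem_arrays(fam, genes, require_same_strand=True) == []

    def test_arrays_are_disjoint_and_monotone_in_gap(self):
        starts = [i * 90_000 for i in range(8)]
        genes = [simple_gene(f"m{i}", s, s + 5_000) for i, s in enumerate(starts)]
        fam = [member(f"m{i}") for i in range(8)]
        seen: set[str] = set()
        previous_largest = 0
        for gap in (50_000, 90_000, 200_000):
            arrays = detect_tandem_arrays(fam, genes, max_gap_bp=gap)
            ids = [g for a in arrays for g in a.members]
            assert len(ids) == len(set(ids))  # disjoint
            largest = max((a.size for a in arrays), default=1)
            assert largest >= previous_largest
            previous_largest = largest

    def test_member_missing_from_annotation_raises(self):
        genes = [simple_gene("a", 0, 1_000)]
        with pytest.raises(ValueError, match="ghost"):
            detect_tandem_arrays([member("ghost")], genes)


class TestRetrocopies:
    def test_single_cds_exon_is_candidate(self):
        genes = [make_gene("r1", [300])]
        (call,) = detect_retrocopies([member("r1")], genes)
        assert call.is_retrocopy_candidate and call.intron_count == 0

    def test_multi_exon_gene_is_not(self):
        genes = [make_gene("g1", [150, 150])]
        (call,) = detect_retrocopies([member("g1")], genes)
        assert not call.is_retrocopy_candidate and call.intron_count == 1

    def test_utr_only_exons_do_not_add_introns(self):
        genes = [make_gene("g1", [300], utr_exons=2)]
        (call,) = detect_retrocopies([member("g1")], genes)
        assert call.is_retrocopy_candidate

    def test_representative_transcript_rule(self):
        # one-exon short CDS vs three-exon longer CDS: the longer wins,
        # so the gene is not called a retrocopy
        one_exon = TranscriptModel("g.t1", [(0, 300)], [(0, 300)])
        three_exon = TranscriptModel(
            "g.t2",
            [(1_000, 1_300), (1_800, 2_100), (2_600, 2_900)],
            [(1_000, 1_300), (1_800, 2_100), (2_600, 2_900)],
        )
        gene = GeneModel("g", "chr1", "+", [one_exon, three_exon])
        (call,) = detect_retrocopies(
            [FamilyMember("g", "g.t2", ("BIR",), "G1", "domain_only")], [gene]
        )
        assert not call.is_retrocopy_candidate

    def test_array_membership_cross_referenced(self):
        genes, fam = six_gene_array_fixture()
        arrays = detect_tandem_arrays(fam, genes)
        calls = detect_retrocopies(fam, genes, arrays)
        assert all(c.in_tandem_array for c in calls)


class TestChromosomeDistribution:
    def _members_on(self, layout: dict[str, int]):
        genes, fams = [], []
        i = 0
        for chrom, n in layout.items():
            for _ in range(n):
                i += 1
                genes.append(simple_gene(f"m{i}", i * 10_000, i * 10_000 + 1_000,
                                         chrom=chrom))
                fams.append(member(f"m{i}"))
        return fams, genes

    def test_59_of_159_reports_37_1_percent(self):
        fams, genes = self._members_on({"chr5": 59, "chr6": 22, "chr7": 12,
                                        "chr1": 66})
        dist = chromosome_distribution(fams, genes).set_index("chromosome")
        assert dist.loc["chr5", "percent"] == 37.1
        assert dist.loc["chr6", "percent"] == 13.8
        assert dist.loc["chr7", "percent"] == 7.5  # 12/159 to 0.1%
        assert dist["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_chromosome_is_100_percent(self):
        fams, genes = self._members_on({"chr1": 4})
        dist = chromosome_distribution(fams, genes)
        assert dist["percent"].tolist() == [100.0]

    def test_uniform_spread(self):
        fams, genes = self._members_on({f"chr{i}": 1 for i in range(1, 11)})
        dist = chromosome_distribution(fams, genes)
        assert dist["percent"].tolist() == [10.0] * 10


def test_planted_arrays_and_retrocopies_recovered(synthetic_genome):
    ann = synthetic_genome
    members = select_family_members(
        ann.genes, ann.domain_hits, annotation_table=ann.annotation_table
    )
    arrays = detect_tandem_arrays(members, ann.genes)
    assert sorted(tuple(a.members) for a in arrays) == sorted(
        tuple(a) for a in ann.truth.arrays
    )
    calls = detect_retrocopies(members, ann.genes, arrays)
    found = {c.gene_id for c in calls if c.is_retrocopy_candidate}
    assert found == set(ann.truth.retrocopy_ids)
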