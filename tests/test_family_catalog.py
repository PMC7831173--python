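"""Member selection, domain-string resolution and architecture typing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famex.family_catalog import (
    classify_architecture,
    domain_presence_matrix,
    resolve_domain_string,
    select_family_members,
)
from famex.io_formats import DomainHit, FormatWarning

from .conftest import make_gene


class TestSelection:
    def setup_method(self):
        self.genes = [make_gene(g, [300]) for g in ("g1", "g2", "g3", "g4")]
        self.hits = [
            DomainHit("g1", "BIR", 12, 77, 1e-20),
            DomainHit("g2", "BIR", 12, 77, 1e-20),
            DomainHit("g3", "RING", 5, 44, 1e-15),
            DomainHit("g4", "BIR", 12, 77, 1e-3),  # above the 1e-5 cutoff
        ]
        self.table = {
            "g1": "baculoviral IAP repeat-containing protein",
            "g2": "kinesin-like protein",
            "g3": "inhibitor of apoptosis protein",
            "g4": "baculoviral IAP repeat-containing protein",
        }

    def test_domain_and_annotation_both_required_when_table_given(self):
        members = select_family_members(
            self.genes, self.hits, annotation_table=self.table
        )
        assert [m.gene_id for m in members] == ["g1"]
        assert members[0].selected_by == "domain_plus_annotation"

    def test_keyword_mismatch_excludes_gene(self):
        ids = {
            m.gene_id
            for m in select_family_members(
                self.genes, self.hits, annotation_table=self.table
            )
        }
        assert "g2" not in ids  # has BIR but annotated as kinesin

    def test_required_domain_absent_excludes_gene(self):
        ids = {m.gene_id for m in select_family_members(self.genes, self.hits)}
        assert "g3" not in ids  # RING only

    def test_e_value_cutoff_applies(self):
        ids = {m.gene_id for m in select_family_members(self.genes, self.hits)}
        assert "g4" not in ids

    def test_gene_missing_from_table_falls_back_to_domain_only(self):
        table = {k: v for k, v in self.table.items() if k != "g1"}
        with pytest.warns(FormatWarning, match="missing from the annotation"):
            members = select_family_members(
                self.genes, self.hits, annotation_table=table
            )
        g1 = next(m for m in members if m.gene_id == "g1")
        assert g1.selected_by == "domain_only"

    def test_include_and_exclude_reproduce_manual_curation(self):
        members = select_family_members(
            self.genes, self.hits, annotation_table=self.table,
            include=["g3"], exclude=["g1"],
        )
        assert {m.gene_id for m in members} == {"g3"}


class TestDomainString:
    def test_orders_hits_n_to_c(self):
        hits = [
            DomainHit("g", "RING", 300, 340, 1e-8),
            DomainHit("g", "BIR", 10, 90, 1e-20),
        ]
        assert resolve_domain_string(hits) == ("BIR", "RING")

    def test_overlapping_hits_keep_best_e_value(self):
        hits = [
            DomainHit("g", "BIR", 10, 90, 1e-20),
            DomainHit("g", "BIR", 15, 85, 1e-4),
        ]
        assert resolve_domain_string(hits) == ("BIR",)

    def test_empty_hits_give_empty_string(self):
        assert resolve_domain_string([]) == ()

    def test_hits_from_multiple_genes_rejected(self):
        with pytest.raises(ValueError, match="multiple genes"):
            resolve_domain_string(
                [DomainHit("a", "BIR", 1, 50, 1e-9), DomainHit("b", "BIR", 1, 50, 1e-9)]
            )

    @given(st.permutations(list(range(4))))
    @settings(deadline=None)
    def test_input_order_never_changes_result(self, order):
        hits = [
            DomainHit("g", "BIR", 10, 75, 1e-30),
            DomainHit("g", "BIR", 100, 165, 1e-25),
            DomainHit("g", "UBA", 180, 220, 1e-8),
            DomainHit("g", "RING", 260, 299, 1e-12),
        ]
        shuffled = [hits[i] for i in order]
        assert resolve_domain_string(shuffled) == ("BIR", "BIR", "UBA", "RING")


class TestClassification:
    @pytest.mark.parametrize(
        ("domains", "label"),
        [
            (("BIR6",), "G2"),
            (("BIR", "BIR6", "RING"), "G2"),  # BIR6 marker dominates
            (("BIR", "PC4"), "G3"),
            (("BIR", "BIR", "BIR", "BIR"), "D"),
            (("BIR", "BIR", "BIR", "RING"), "A"),
            (("BIR", "BIR", "BIR"), "E"),
            (("BIR", "BIR", "RING"), "B"),
            (("BIR", "BIR"), "C"),
            (("BIR", "RING"), "F"),
            (("BIR",), "G1"),
            (("BIR", "UBA", "RING"), "F"),  # auxiliary domains ignored
            ((), "unclassified"),
            (("Pkinase",), "unclassified"),
        ],
    )
    def test_default_rule_table(self, domains, label):
        assert classify_architecture(domains) == label

    @given(
        st.lists(
            st.sampled_from(["BIR", "BIR6", "RING", "PC4", "UBA", "CARD"]),
            max_size=6,
        )
    )
    @settings(deadline=None)
    def test_classification_is_total_and_order_blind_in_counts(self, domains):
        label = classify_architecture(domains)
        assert isinstance(label, str) and label
        # default rules depend only on composition, not order
        assert classify_architecture(sorted(domains)) == label


class TestPresenceMatrix:
    def test_multi_copy_domain_counted_once(self):
        genes = [make_gene("g1", [600])]
        hits = [
            DomainHit("g1", "BIR", 10, 75, 1e-30),
            DomainHit("g1", "BIR", 80, 145, 1e-30),
            DomainHit("g1", "BIR", 150, 199, 1e-30),
        ]
        m = domain_presence_matrix({"sp": (genes, hits)}, ["BIR"])
        assert m.loc["sp", "BIR"] == 1

    def test_gene_contributes_to_each_domain_it_carries(self):
        genes = [make_gene("g1", [600])]
        hits = [
            DomainHit("g1", "BIR", 10, 75, 1e-30),
            DomainHit("g1", "RING", 150, 190, 1e-12),
        ]
        m = domain_presence_matrix({"sp": (genes, hits)}, ["BIR", "RING"])
        assert m.loc["sp", "BIR"] == 1 and m.loc["sp", "RING"] == 1

    def test_no_hits_gives_all_zero_matrix(self):
        genes = [make_gene("g1", [600])]
        m = domain_presence_matrix({"sp": (genes, [])}, ["BIR", "RING"])
        assert (m[["BIR", "RING"]] == 0).all().all()
        assert m.loc["sp", "total_genes"] == 1

    def test_species_with_zero_genes_raises(self):
        with pytest.raises(ValueError, match="zero genes"):
            domain_presence_matrix({"sp": ([], [])}, ["BIR"])


def test_planted_architectures_recovered_exactly(synthetic_genome):
    members = select_family_members(
        synthetic_genome.genes,
        synthetic_genome.domain_hits,
        annotation_table=synthetic_genome.annotation_table,
    )
    got = {m.gene_id: m.architecture_type for m in members}
    assert got == synthetic_genome.truth.architectures
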