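"""Family-member selection and domain-architecture classification.

A gene joins the family when it carries at least one hit of a required
diagnostic domain (BIR for IAPs) below an e-value cutoff, optionally
restricted to genes whose functional annotation matches family keywords.
Each member's ordered N->C domain string is resolved from its hits and
classified into a structural type by an ordered rule table keyed on BIR
copy number, RING presence and marker domains (BIR6, PC4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import DomainHit, FormatWarning, GeneModel

__all__ = [
    "ARCHITECTURE_TYPES",
    "TypeRule",
    "TypeRuleTable",
    "DEFAULT_RULES",
    "FamilyMember",
    "resolve_domain_string",
    "classify_architecture",
    "select_family_members",
    "domain_presence_matrix",
]

ARCHITECTURE_TYPES = ("A", "B", "C", "D", "E", "F", "G1", "G2", "G3", "unclassified")

DEFAULT_REQUIRED_DOMAINS = ("BIR", "BIR6")
DEFAULT_E_CUTOFF = 1e-5
DEFAULT_KEYWORDS = ("inhibitor of apoptosis", "IAP", "baculoviral IAP repeat")


@dataclass(frozen=True)
class TypeRule:
    """One classification rule: a predicate over the domain string."""

    label: str
    predicate: Callable[[Sequence[str]], bool]
    description: str = ""


def _counts(domains: Sequence[str]) -> tuple[int, bool]:
    n_bir = sum(1 for d in domains if d == "BIR")
    has_ring = "RING" in domains
    return n_bir, has_ring


@dataclass
class TypeRuleTable:
    """Ordered classification rules; first matching rule wins."""

    rules: list[TypeRule] = field(default_factory=list)
    default_label: str = "unclassified"

    def classify(self, domains: Sequence[str]) -> str:
        for rule in self.rules:
            if rule.predicate(domains):
                return rule.label
        return self.default_label


#: Default rule table for IAP structural types.  Marker domains take
#: priority: BIR6 marks the ancient Apollon-like type (G2) and PC4 the
#: BIR+PC4 innovation (G3).  The remaining types are keyed on BIR copy
#: number and RING presence: 4 BIR -> D; 3 BIR with/without RING -> A/E;
#: 2 BIR with/without RING -> B/C; 1 BIR with/without RING -> F/G1.
DEFAULT_RULES = TypeRuleTable(
    rules=[
        TypeRule("G2", lambda d: "BIR6" in d, "contains the BIR6 marker"),
        TypeRule(
            "G3",
            lambda d: "PC4" in d and _counts(d)[0] == 1,
            "one BIR plus co-opted PC4",
        ),
        TypeRule("D", lambda d: _counts(d)[0] == 4, "four BIR"),
        TypeRule("A", lambda d: _counts(d) == (3, True), "three BIR + RING"),
        TypeRule("E", lambda d: _counts(d) == (3, False), "three BIR, no RING"),
        TypeRule("B", lambda d: _counts(d) == (2, True), "two BIR + RING"),
        TypeRule("C", lambda d: _counts(d) == (2, False), "two BIR, no RING"),
        TypeRule("F", lambda d: _counts(d) == (1, True), "one BIR + RING"),
        TypeRule("G1", lambda d: _counts(d) == (1, False), "one BIR, no RING"),
    ]
)


@dataclass
class FamilyMember:
    gene_id: str
    transcript_id: str
    domain_string: tuple[str, ...]
    architecture_type: str
    selected_by: str  # domain_only | domain_plus_annotation


def resolve_domain_string(
    hits: Iterable[DomainHit], overlap_fraction: float = 0.5
) -> tuple[str, ...]:
    """Order a gene's hits N->C and collapse overlapping ones.

    Two hits conflict when their overlap exceeds ``overlap_fraction`` of the
    shorter hit; the better hit wins (lower e-value, then higher score, then
    longer span).  The result is independent of input order.
    """
    hits = sorted(
        hits, key=lambda h: (h.e_value, -h.score, -h.aa_length, h.aa_start, h.domain_name)
    )
    genes = {h.gene_id for h in hits}
    if len(genes) > 1:
        raise ValueError(f"hits span multiple genes: {sorted(genes)}")
    kept: list[DomainHit] = []
    for hit in hits:  # best-first greedy
        conflict = False
        for other in kept:
            ov = min(hit.aa_end, other.aa_end) - max(hit.aa_start, other.aa_start) + 1
            if ov > overlap_fraction * min(hit.aa_length, other.aa_length):
                conflict = True
                break
        if not conflict:
            kept.append(hit)
    kept.sort(key=lambda h: (h.aa_start, h.aa_end, h.domain_name))
    return tuple(h.domain_name for h in kept)


def classify_architecture(
    domain_string: Sequence[str], rules: TypeRuleTable | None = None
) -> str:
    """Assign the structural-type label for one ordered domain string."""
    table = rules if rules is not None else DEFAULT_RULES
    return table.classify(tuple(domain_string))


def select_family_members(
    annotation: Iterable[GeneModel],
    domain_hits: Iterable[DomainHit],
    required_domains: Sequence[str] = DEFAULT_REQUIRED_DOMAINS,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    annotation_table: Mapping[str, str] | None = None,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    rules: TypeRuleTable | None = None,
    include: Sequence[str] = (),
    exclude: Sequence[str] = (),
) -> list[FamilyMember]:
    """Select family members and classify their architectures.

    A gene qualifies when it has >=1 hit of a required domain at
    ``e_value <= e_cutoff`` and, if ``annotation_table`` (gene -> functional
    description) is given, its description matches at least one keyword
    (case-insensitive).  Genes missing from a supplied annotation table fall
    back to domain-only selection with a warning.  ``include``/``exclude``
    reproduce manual curation on top of the automatic rule.
    """
    genes = {g.gene_id: g for g in annotation}
    hits_by_gene: dict[str, list[DomainHit]] = {}
    for hit in domain_hits:
        hits_by_gene.setdefault(hit.gene_id, []).append(hit)

    missing_from_table = 0
    members: list[FamilyMember] = []
    lowered = [k.lower() for k in keywords]
    for gene_id, gene in genes.items():
        if gene_id in exclude:
            continue
        ghits = hits_by_gene.get(gene_id, [])
        has_required = any(
            h.domain_name in required_domains and h.e_value <= e_cutoff for h in ghits
        )
        forced = gene_id in include
        if not has_required and not forced:
            continue
        selected_by = "domain_only"
        if annotation_table is not None and not forced:
            desc = annotation_table.get(gene_id)
            if desc is None:
                missing_from_table += 1
            else:
                if not any(k in desc.lower() for k in lowered):
                    continue
                selected_by = "domain_plus_annotation"
        domain_string = resolve_domain_string(ghits) if ghits else ()
        members.append(
            FamilyMember(
                gene_id=gene_id,
                transcript_id=gene.representative_transcript().transcript_id,
                domain_string=domain_string,
                architecture_type=classify_architecture(domain_string, rules),
                selected_by=selected_by,
            )
        )
    if missing_from_table:
        warnings.warn(
            f"{missing_from_table} candidate gene(s) missing from the "
            "annotation table; selected by domain evidence only",
            FormatWarning,
            stacklevel=2,
        )
    return members


def domain_presence_matrix(
    species_data: Mapping[str, tuple[Iterable[GeneModel], Iterable[DomainHit]]],
    domain_list: Sequence[str],
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> pd.DataFrame:
    """Count, per species and domain, genes with >=1 qualifying hit.

    A domain occurring several times in one protein is counted once.  The
    returned frame has species as rows, domains as columns, plus a
    ``total_genes`` column for use as the chi-square background.
    """
    if not species_data:
        raise ValueError("at least one species is required")
    records = {}
    for species, (annotation, hits) in species_data.items():
        gene_ids = {g.gene_id for g in annotation}
        if not gene_ids:
            raise ValueError(f"species '{species}' has zero genes")
        with_domain: dict[str, set[str]] = {d: set() for d in domain_list}
        for hit in hits:
            if hit.domain_name in with_domain and hit.e_value <= e_cutoff:
                if hit.gene_id in gene_ids:
                    with_domain[hit.domain_name].add(hit.gene_id)
        row = {d: len(g) for d, g in with_domain.items()}
        row["total_genes"] = len(gene_ids)
        records[species] = row
    matrix = pd.DataFrame.from_dict(records, orient="index")
    return matrix[[*domain_list, "total_genes"]]


def members_table(members: Iterable[FamilyMember]) -> pd.DataFrame:
    """Tabular view of selected members (one row per gene)."""
    return pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "transcript_id": m.transcript_id,
                "architecture_type": m.architecture_type,
                "domain_string": "-".join(m.domain_string),
                "selected_by": m.selected_by,
            }
            for m in members
        ]
    )
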