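"""Phylostratigraphic age assignment.

Each gene is assigned the oldest phylostratum (lowest rank; PS1 = origin
of cellular life) containing a species with a qualifying homology hit
(e-value strictly below the cutoff).  Genes without any qualifying hit are
excluded by default rather than assumed lineage-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import HomologyHit

__all__ = [
    "PhylostratumMap",
    "PhylostratumAssignment",
    "assign_phylostratum",
    "assign_all",
    "age_distribution",
]

DEFAULT_E_CUTOFF = 1e-10


@dataclass
class PhylostratumMap:
    """Ranked lineage: species -> phylostratum rank (1 = oldest)."""

    species_rank: dict[str, int]

    def __post_init__(self) -> None:
        ranks = sorted(set(self.species_rank.values()))
        if not ranks:
            raise ValueError("empty phylostratum map")
        if ranks[0] != 1 or ranks != list(range(1, ranks[-1] + 1)):
            raise ValueError(f"ranks must be contiguous from 1, got {ranks}")

    @property
    def n_strata(self) -> int:
        return max(self.species_rank.values())

    def rank_of(self, species: str) -> int:
        try:
            return self.species_rank[species]
        except KeyError:
            raise ValueError(f"species '{species}' absent from phylostratum map")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhylostratumMap":
        mapping = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.split()
                if cols[0].lower() == "species":
                    continue
                mapping[cols[0]] = int(cols[1])
        return cls(mapping)


@dataclass
class PhylostratumAssignment:
    gene_id: str
    rank: int | None  # None = excluded (no qualifying hit)
    supporting_species: int

    @property
    def excluded(self) -> bool:
        return self.rank is None


def assign_phylostratum(
    gene_id: str,
    gene_hits: Iterable[HomologyHit],
    pmap: PhylostratumMap,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    self_rank: int | None = None,
) -> PhylostratumAssignment:
    """Oldest-rank assignment for one gene.

    Rank = minimum rank among species with a hit at ``e_value < e_cutoff``
    (strict).  With no qualifying hit the gene is excluded unless
    ``self_rank`` is given, in which case it is treated as specific to the
    focal lineage at that rank.
    """
    qualifying = [h for h in gene_hits if h.e_value < e_cutoff]
    species = {h.subject_species for h in qualifying}
    ranks = [pmap.rank_of(s) for s in species]
    if not ranks:
        return PhylostratumAssignment(gene_id, self_rank, 0)
    best = min(ranks)
    return PhylostratumAssignment(
        gene_id, best, sum(1 for r in ranks if r == best)
    )


def assign_all(
    hits: Iterable[HomologyHit],
    gene_ids: Iterable[str],
    pmap: PhylostratumMap,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    self_rank: int | None = None,
) -> list[PhylostratumAssignment]:
    by_gene: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_gene.setdefault(h.query_gene, []).append(h)
    return [
        assign_phylostratum(g, by_gene.get(g, []), pmap, e_cutoff, self_rank)
        for g in gene_ids
    ]


def age_distribution(
    assignments: Iterable[PhylostratumAssignment],
    gene_sets: Mapping[str, Iterable[str]],
    n_strata: int | None = None,
) -> pd.DataFrame:
    """Per-set fraction of assigned genes in each phylostratum.

    Excluded genes do not contribute; fractions sum to 1 within each set.
    A set with no assigned gene yields an all-NA row.
    """
    by_gene = {a.gene_id: a for a in assignments}
    max_rank = n_strata or max(
        (a.rank for a in by_gene.values() if a.rank is not None), default=1
    )
    rows = {}
    for name, ids in gene_sets.items():
        ranks = [
            by_gene[g].rank
            for g in ids
            if g in by_gene and by_gene[g].rank is not None
        ]
        if not ranks:
            rows[name] = {f"PS{r}": float("nan") for r in range(1, max_rank + 1)}
            continue
        total = len(ranks)
        rows[name] = {
            f"PS{r}": sum(1 for x in ranks if x == r) / total
            for r in range(1, max_rank + 1)
        }
    return pd.DataFrame.from_dict(rows, orient="index")
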