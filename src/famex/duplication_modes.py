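"""Duplication-mode calling: tandem arrays and retrocopies.

Tandem arrays are maximal runs of family genes along a chromosome's gene
order, chained while the intergenic gap and the number of intervening
non-family genes stay below thresholds.  Retrocopy candidates are members
whose representative transcript has a single CDS-bearing exon — the
signature of duplication through a reverse-transcribed mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .family_catalog import FamilyMember
from .io_formats import GeneModel

__all__ = [
    "TandemArray",
    "RetrocopyCall",
    "detect_tandem_arrays",
    "detect_retrocopies",
    "chromosome_distribution",
]

DEFAULT_MAX_GAP_BP = 100_000
DEFAULT_MAX_INTERVENING = 0


@dataclass
class TandemArray:
    array_id: str
    chromosome: str
    members: list[str]  # gene ids in genomic order
    span: tuple[int, int]
    same_strand: bool
    n_intervening: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class RetrocopyCall:
    gene_id: str
    intron_count: int
    is_retrocopy_candidate: bool
    in_tandem_array: bool


def detect_tandem_arrays(
    members: Iterable[FamilyMember | str],
    all_genes: Iterable[GeneModel],
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
    require_same_strand: bool = False,
) -> list[TandemArray]:
    """Chain family members along each chromosome into tandem arrays.

    Two consecutive members (in gene order) join the same array iff their
    intergenic gap is at most ``max_gap_bp``, at most ``max_intervening``
    non-family genes lie between them, and, when ``require_same_strand``,
    their strands agree.  Single genes do not form arrays.  ``same_strand``
    is reported for every array regardless of the flag.
    """
    member_ids = {m.gene_id if isinstance(m, FamilyMember) else m for m in members}
    genes = list(all_genes)
    by_id = {g.gene_id: g for g in genes}
    unknown = member_ids - set(by_id)
    if unknown:
        raise ValueError(
            f"member gene(s) missing from the annotation: {sorted(unknown)[:5]}"
        )

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    arrays: list[TandemArray] = []
    for chrom in sorted(by_chrom):
        order = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        chain: list[GeneModel] = []
        intervening_in_chain = 0

        def flush() -> None:
            nonlocal chain, intervening_in_chain
            if len(chain) >= 2:
                arrays.append(
                    TandemArray(
                        array_id=f"array_{len(arrays) + 1}",
                        chromosome=chrom,
                        members=[g.gene_id for g in chain],
                        span=(chain[0].start, max(g.end for g in chain)),
                        same_strand=len({g.strand for g in chain}) == 1,
                        n_intervening=intervening_in_chain,
                    )
                )
            chain = []
            intervening_in_chain = 0

        pending_intervening = 0
        for gene in order:
            if gene.gene_id not in member_ids:
                pending_intervening += 1
                continue
            if chain:
                prev = chain[-1]
                gap = max(0, gene.start - prev.end)
                ok = (
                    gap <= max_gap_bp
                    and pending_intervening <= max_intervening
                    and (not require_same_strand or gene.strand == prev.strand)
                )
                if ok:
                    intervening_in_chain += pending_intervening
                    chain.append(gene)
                else:
                    flush()
                    chain = [gene]
            else:
                chain = [gene]
            pending_intervening = 0
        flush()
    return arrays


def detect_retrocopies(
    members: Iterable[FamilyMember],
    annotation: Iterable[GeneModel],
    arrays: Sequence[TandemArray] | None = None,
) -> list[RetrocopyCall]:
    """Call intronless members as retrocopy candidates.

    The intron count is taken on the CDS-bearing exons of the
    representative transcript, so UTR-only exons do not mask a retrocopy.
    ``arrays`` (from :func:`detect_tandem_arrays`) annotates whether a
    candidate also sits inside a tandem array.
    """
    by_id = {g.gene_id: g for g in annotation}
    in_array = {gid for a in (arrays or []) for gid in a.members}
    calls = []
    for m in members:
        gene = by_id.get(m.gene_id)
        if gene is None:
            raise ValueError(f"member '{m.gene_id}' missing from the annotation")
        tx = gene.representative_transcript()
        intron_count = max(0, tx.n_coding_exons - 1)
        calls.append(
            RetrocopyCall(
                gene_id=m.gene_id,
                intron_count=intron_count,
                is_retrocopy_candidate=intron_count == 0,
                in_tandem_array=m.gene_id in in_array,
            )
        )
    return calls


def chromosome_distribution(
    members: Iterable[FamilyMember], annotation: Iterable[GeneModel]
) -> pd.DataFrame:
    """Member count and fraction of the family per chromosome.

    Fractions are reported both exactly and rounded to 0.1% (``percent``).
    """
    by_id = {g.gene_id: g for g in annotation}
    chroms = [by_id[m.gene_id].chromosome for m in members]
    if not chroms:
        raise ValueError("no family members")
    counts = pd.Series(chroms).value_counts().sort_index()
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "chromosome": counts.index,
            "n_members": counts.values,
            "fraction": counts.values / total,
        }
    )
    out["percent"] = (out["fraction"] * 100).round(1)
    return out.reset_index(drop=True)


def arrays_table(arrays: Iterable[TandemArray]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "array_id": a.array_id,
                "chromosome": a.chromosome,
                "start": a.span[0],
                "end": a.span[1],
                "size": a.size,
                "same_strand": a.same_strand,
                "n_intervening": a.n_intervening,
                "members": ",".join(a.members),
            }
            for a in arrays
        ]
    )


def retrocopies_table(calls: Iterable[RetrocopyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "intron_count": c.intron_count,
                "is_retrocopy_candidate": c.is_retrocopy_candidate,
                "in_tandem_array": c.in_tandem_array,
            }
            for c in calls
        ]
    )
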