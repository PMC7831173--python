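"""Intron phases and projection of protein domains onto exon structure.

Phases are computed in transcript (5'->3') orientation over CDS intervals
only: the phase of a coding intron is the number of coding nucleotides
upstream of it modulo 3.  A domain hit at protein positions
``aa_start..aa_end`` (1-based inclusive) occupies coding nucleotides
``[(aa_start-1)*3, aa_end*3)`` of the spliced CDS; walking that footprint
across the CDS intervals yields the bp the domain contributes to each exon
and the phases of its flanking introns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import DomainHit, FormatWarning, GeneModel, TranscriptModel

__all__ = [
    "IntronPhaseProfile",
    "DomainExonMap",
    "intron_phases",
    "map_domain_to_exons",
    "boundary_statistics",
]


@dataclass
class IntronPhaseProfile:
    gene_id: str
    phases: tuple[int, ...]  # one per coding intron, 5'->3'
    n_noncoding_introns: int = 0


@dataclass
class DomainExonMap:
    gene_id: str
    domain_name: str
    aa_start: int
    aa_end: int
    exon_bp: dict[int, int] = field(default_factory=dict)  # coding-exon index -> bp
    upstream_intron_phase: int | None = None
    downstream_intron_phase: int | None = None

    @property
    def n_exons_spanned(self) -> int:
        return len(self.exon_bp)


def _coding_exons_5to3(gene: GeneModel, tx: TranscriptModel) -> list[tuple[int, int]]:
    """CDS intervals ordered 5'->3' along the transcript."""
    cds = sorted(tx.cds)
    return cds[::-1] if gene.strand == "-" else cds


def intron_phases(gene: GeneModel, cds_only: bool = True) -> IntronPhaseProfile:
    """Phases of the coding introns of the representative transcript.

    With ``cds_only`` (the default) only introns between CDS-bearing
    segments are phased; introns entirely outside the CDS are counted in
    ``n_noncoding_introns``.  Setting it to False phases every exon/exon
    junction using cumulative exon length instead of coding length.
    """
    tx = gene.representative_transcript()
    if tx.coding_length == 0:
        raise ValueError(f"gene {gene.gene_id}: representative transcript is non-coding")
    if tx.coding_length % 3 != 0:
        warnings.warn(
            f"gene {gene.gene_id}: coding length {tx.coding_length} not a "
            "multiple of 3; phases computed anyway",
            FormatWarning,
            stacklevel=2,
        )
    segments = (
        _coding_exons_5to3(gene, tx)
        if cds_only
        else (sorted(tx.exons)[::-1] if gene.strand == "-" else sorted(tx.exons))
    )
    phases = []
    cumulative = 0
    for s, e in segments[:-1]:
        cumulative += e - s
        phases.append(cumulative % 3)
    n_noncoding = 0
    if cds_only:
        n_noncoding = max(0, len(tx.exons) - len(segments))
    return IntronPhaseProfile(gene.gene_id, tuple(phases), n_noncoding)


def map_domain_to_exons(gene: GeneModel, hit: DomainHit) -> DomainExonMap:
    """Project one domain hit onto the exon structure of its gene.

    Returns per-coding-exon bp of the domain footprint (exon indices are
    1-based in transcript orientation) and the phases of the introns
    immediately flanking the domain's first and last exon (absent at the
    transcript termini).
    """
    tx = gene.representative_transcript()
    protein_len = tx.coding_length // 3
    if hit.aa_end > protein_len:
        raise ValueError(
            f"gene {gene.gene_id}: domain {hit.domain_name} ends at aa "
            f"{hit.aa_end} beyond protein length {protein_len}"
        )
    nt_start = (hit.aa_start - 1) * 3
    nt_end = hit.aa_end * 3

    segments = _coding_exons_5to3(gene, tx)
    exon_bp: dict[int, int] = {}
    offset = 0
    for idx, (s, e) in enumerate(segments, start=1):
        seg_len = e - s
        lo = max(nt_start, offset)
        hi = min(nt_end, offset + seg_len)
        if hi > lo:
            exon_bp[idx] = hi - lo
        offset += seg_len
    profile = intron_phases(gene)
    first = min(exon_bp)
    last = max(exon_bp)
    return DomainExonMap(
        gene_id=gene.gene_id,
        domain_name=hit.domain_name,
        aa_start=hit.aa_start,
        aa_end=hit.aa_end,
        exon_bp=exon_bp,
        upstream_intron_phase=profile.phases[first - 2] if first > 1 else None,
        downstream_intron_phase=(
            profile.phases[last - 1] if last <= len(profile.phases) else None
        ),
    )


def boundary_statistics(
    maps: Iterable[DomainExonMap], domain_name: str
) -> dict[str, object]:
    """Summarise exon-boundary conventions of one domain across a family.

    Only each gene's first (most N-terminal) occurrence of ``domain_name``
    is used.  "First/second exon" refer to the first and second exon the
    domain touches, not the transcript's first exons.  Returns the fraction
    of occurrences spanning exactly two exons, the mean bp in the first and
    second spanned exon (over two-exon occurrences), and the distribution
    of (upstream, downstream) flanking intron phases.
    """
    first_per_gene: dict[str, DomainExonMap] = {}
    for m in maps:
        if m.domain_name != domain_name:
            continue
        prev = first_per_gene.get(m.gene_id)
        if prev is None or m.aa_start < prev.aa_start:
            first_per_gene[m.gene_id] = m
    if not first_per_gene:
        raise ValueError(f"no maps for domain '{domain_name}'")

    chosen = list(first_per_gene.values())
    two_exon = [m for m in chosen if m.n_exons_spanned == 2]
    phase_counts: dict[tuple[object, object], int] = {}
    for m in chosen:
        key = (m.upstream_intron_phase, m.downstream_intron_phase)
        phase_counts[key] = phase_counts.get(key, 0) + 1

    def _mean_bp(position: int) -> float | None:
        if not two_exon:
            return None
        vals = [sorted(m.exon_bp.items())[position][1] for m in two_exon]
        return sum(vals) / len(vals)

    return {
        "domain": domain_name,
        "n_genes": len(chosen),
        "two_exon_fraction": len(two_exon) / len(chosen),
        "mean_bp_first_exon": _mean_bp(0),
        "mean_bp_second_exon": _mean_bp(1),
        "flanking_phase_distribution": phase_counts,
    }


def structure_table(
    genes: Iterable[GeneModel], hits_by_gene: Mapping[str, list[DomainHit]]
) -> pd.DataFrame:
    """Per-gene structure summary: intron count, phases, domain spans."""
    rows = []
    for gene in genes:
        tx = gene.representative_transcript()
        profile = intron_phases(gene)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "transcript_id": tx.transcript_id,
                "n_coding_exons": tx.n_coding_exons,
                "intron_phases": ",".join(map(str, profile.phases)),
                "domains": ";".join(
                    f"{h.domain_name}:{h.aa_start}-{h.aa_end}"
                    for h in sorted(
                        hits_by_gene.get(gene.gene_id, []), key=lambda h: h.aa_start
                    )
                ),
            }
        )
    return pd.DataFrame(rows)
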