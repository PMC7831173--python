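"""Shared fixtures: tiny hand-built gene models and one synthetic genome."""

from __future__ import annotations

import pytest

from famex.io_formats import GeneModel, TranscriptModel
from famex.synthetic_data import SyntheticGenomeSpec, generate_annotation


def make_gene(
    gene_id: str,
    exon_lengths: list[int],
    intron_lengths: list[int] | None = None,
    strand: str = "+",
    chromosome: str = "chr1",
    start: int = 10_000,
    utr_exons: int = 0,
) -> GeneModel:
    """Build a single-transcript gene from 5'->3' CDS exon lengths.

    ``utr_exons`` appends that many non-coding 100-bp exons downstream of
    the CDS (in genomic orientation for '+' genes).
    """
    introns = intron_lengths if intron_lengths is not None else [500] * (
        len(exon_lengths) - 1 + utr_exons
    )
    lengths = list(exon_lengths)
    if strand == "-":
        lengths = lengths[::-1]
        introns = list(introns)[::-1]
    exons = []
    pos = start
    n_parts = len(lengths) + utr_exons
    for i in range(n_parts):
        ln = lengths[i] if i < len(lengths) else 100
        exons.append((pos, pos + ln))
        pos += ln + (introns[i] if i < n_parts - 1 else 0)
    cds = exons[: len(lengths)]
    tx = TranscriptModel(f"{gene_id}.t1", exons, cds)
    return GeneModel(gene_id, chromosome, strand, [tx])


@pytest.fixture(scope="session")
def synthetic_genome():
    """Default synthetic annotation (seed 1), shared read-only."""
    return generate_annotation(SyntheticGenomeSpec(), seed=1)
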