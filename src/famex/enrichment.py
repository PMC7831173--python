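"""Enrichment statistics: TE flank density, domain overrepresentation, FPKM.

TE density around a gene is the fraction of its (up to) 10-kb upstream and
downstream flanks covered by merged TE intervals of one class.  Family
versus background densities are compared with a two-sided Welch t-test.
Cross-species domain overrepresentation uses a 2x2 chi-square (focal
species versus all other species pooled, genes-with versus genes-without
the domain) with Benjamini–Hochberg adjustment across tests.  Expression
is summarised as FPKM = reads_in_gene * 1e9 / (total_reads_in_genes *
gene_length), with genes silent below a mean-FPKM threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel, TEInterval

__all__ = [
    "FlankDensity",
    "EnrichmentTestResult",
    "OverrepresentationResult",
    "merge_intervals",
    "te_flank_density",
    "te_enrichment_test",
    "domain_overrepresentation",
    "fpkm",
    "filter_silent",
]

DEFAULT_FLANK_WINDOW_BP = 10_000
DEFAULT_SILENT_THRESHOLD = 0.1


@dataclass
class FlankDensity:
    gene_id: str
    te_class: str
    density: float
    flank_bp_available: int
    covered_bp: int


@dataclass
class EnrichmentTestResult:
    te_class: str
    mean_family: float
    mean_background: float
    t_statistic: float
    p_value: float
    n_family: int
    n_background: int
    degenerate: bool = False


@dataclass
class OverrepresentationResult:
    species: str
    domain: str
    focal_with: int
    focal_without: int
    other_with: int
    other_without: int
    chi2: float | None
    p_raw: float | None
    p_adjusted: float | None
    method: str = "chi2"  # chi2 | fisher | skipped


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def te_flank_density(
    gene: GeneModel,
    te_intervals: Iterable[TEInterval],
    chrom_sizes: Mapping[str, int],
    window_bp: int = DEFAULT_FLANK_WINDOW_BP,
    te_class: str = "DNA",
) -> FlankDensity:
    """Fraction of a gene's flanks covered by TEs of one class.

    Flanks are ``[start - window, start)`` and ``[end, end + window)``,
    truncated at chromosome ends; TE intervals are merged before coverage
    is summed so fragmented annotations do not overcount.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    chrom_len = chrom_sizes[gene.chromosome]
    flanks = [
        (max(0, gene.start - window_bp), gene.start),
        (gene.end, min(chrom_len, gene.end + window_bp)),
    ]
    flanks = [(s, e) for s, e in flanks if e > s]
    available = sum(e - s for s, e in flanks)

    relevant = [
        (te.start, te.end)
        for te in te_intervals
        if te.te_class == te_class and te.chromosome == gene.chromosome
    ]
    covered = 0
    for ms, me in merge_intervals(relevant):
        for fs, fe in flanks:
            covered += max(0, min(me, fe) - max(ms, fs))
    return FlankDensity(
        gene_id=gene.gene_id,
        te_class=te_class,
        density=covered / available if available else 0.0,
        flank_bp_available=available,
        covered_bp=covered,
    )


def flank_densities(
    genes: Sequence[GeneModel],
    te_intervals: Sequence[TEInterval],
    chrom_sizes: Mapping[str, int],
    window_bp: int = DEFAULT_FLANK_WINDOW_BP,
    te_class: str = "DNA",
) -> list[FlankDensity]:
    """Vectorised convenience wrapper over :func:`te_flank_density`."""
    by_chrom: dict[str, list[TEInterval]] = {}
    for te in te_intervals:
        if te.te_class == te_class:
            by_chrom.setdefault(te.chromosome, []).append(te)
    out = []
    for gene in genes:
        out.append(
            te_flank_density(
                gene, by_chrom.get(gene.chromosome, []), chrom_sizes,
                window_bp, te_class,
            )
        )
    return out


def te_enrichment_test(
    family_densities: Sequence[FlankDensity | float],
    background_densities: Sequence[FlankDensity | float],
    te_class: str = "DNA",
) -> EnrichmentTestResult:
    """Two-sided Welch t-test of family vs background flank densities."""

    def _vals(ds):
        return np.asarray(
            [d.density if isinstance(d, FlankDensity) else float(d) for d in ds]
        )

    fam, bg = _vals(family_densities), _vals(background_densities)
    if len(fam) < 2 or len(bg) < 2:
        raise ValueError("need at least two densities per group")
    degenerate = np.ptp(fam) == 0 and np.ptp(bg) == 0
    if degenerate:
        # no within-group variance: the t statistic is undefined
        diff = fam[0] - bg[0]
        t_stat = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
        p = 1.0 if diff == 0 else 0.0
    else:
        t_stat, p = stats.ttest_ind(fam, bg, equal_var=False)
    return EnrichmentTestResult(
        te_class=te_class,
        mean_family=float(fam.mean()),
        mean_background=float(bg.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_family=len(fam),
        n_background=len(bg),
        degenerate=degenerate,
    )


def domain_overrepresentation(
    matrix: pd.DataFrame,
    focal_species: str,
    correction: str = "fdr_bh",
) -> list[OverrepresentationResult]:
    """Per-domain 2x2 overrepresentation tests for one focal species.

    ``matrix`` is a :func:`famex.family_catalog.domain_presence_matrix`
    frame (species x domains, plus ``total_genes``).  Each domain is tested
    with genes-with/without the domain in the focal species against the
    pooled remaining species, using chi-square without Yates continuity
    correction; tables with an expected cell below 1 fall back to Fisher's
    exact test.  Raw p-values are adjusted across all domains.
    """
    if focal_species not in matrix.index:
        raise ValueError(f"focal species '{focal_species}' not in matrix")
    if len(matrix.index) < 2:
        raise ValueError("need at least two species")
    domains = [c for c in matrix.columns if c != "total_genes"]
    others = matrix.drop(index=focal_species)

    results: list[OverrepresentationResult] = []
    for domain in domains:
        fw = int(matrix.loc[focal_species, domain])
        ft = int(matrix.loc[focal_species, "total_genes"])
        ow = int(others[domain].sum())
        ot = int(others["total_genes"].sum())
        table = np.array([[fw, ft - fw], [ow, ot - ow]])
        if table[:, 0].sum() == 0:  # domain absent everywhere
            results.append(
                OverrepresentationResult(
                    focal_species, domain, fw, ft - fw, ow, ot - ow,
                    None, None, None, method="skipped",
                )
            )
            continue
        expected = stats.contingency.expected_freq(table)
        if (expected < 1).any():
            _, p = stats.fisher_exact(table)
            chi2 = None
            method = "fisher"
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            chi2 = float(chi2)
            method = "chi2"
        results.append(
            OverrepresentationResult(
                focal_species, domain, fw, ft - fw, ow, ot - ow,
                chi2, float(p), None, method=method,
            )
        )

    testable = [r for r in results if r.p_raw is not None]
    if testable:
        adjusted = multipletests([r.p_raw for r in testable], method=correction)[1]
        for r, padj in zip(testable, adjusted):
            r.p_adjusted = float(padj)
    return results


def fpkm(
    read_counts: pd.DataFrame, gene_lengths: Mapping[str, int] | pd.Series
) -> pd.DataFrame:
    """FPKM matrix from a gene x sample read-count matrix.

    FPKM = reads_in_gene * 1e9 / (total reads mapped in genes in that
    sample * gene length in nt).
    """
    lengths = pd.Series(gene_lengths).reindex(read_counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"gene length missing for: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = read_counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"zero total reads in sample(s): {bad}")
    return read_counts.mul(1e9).div(totals, axis=1).div(lengths, axis=0)


def filter_silent(
    expr: pd.DataFrame, threshold: float = DEFAULT_SILENT_THRESHOLD
) -> pd.Index:
    """Genes retained after dropping silent ones (mean FPKM < threshold)."""
    return expr.index[expr.mean(axis=1) >= threshold]
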