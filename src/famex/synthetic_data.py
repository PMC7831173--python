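"""Synthetic annotations, TE landscapes, codon pairs, hit tables and family
histories with planted ground truth.

The generator emulates the statistical structure of a genome carrying a
massively expanded gene family: tandem arrays of same-strand members with
no intervening genes, intronless retrocopies dispersed across chromosomes,
a spectrum of domain architectures built from a canonical two-exon BIR
module, DNA-transposon coverage elevated in family-gene flanks, codon
divergence at a chosen dN/dS, homology hits consistent with planted gene
ages, and family counts evolved along a species tree by explicit per-branch
gain/loss events.  Every emitted structure is recorded in a
:class:`GroundTruth` object so detectors can be scored exactly.

All randomness flows from one :class:`numpy.random.Generator`; the same
spec and seed give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import (
    DomainHit,
    GeneModel,
    HomologyHit,
    TEInterval,
    TranscriptModel,
    write_domain_table,
    write_gff3,
)
from .phylostratigraphy import PhylostratumMap
from .selection import GENETIC_CODE, SENSE_CODONS, STOP_CODONS

__all__ = [
    "ArraySpec",
    "SyntheticGenomeSpec",
    "GroundTruth",
    "SyntheticAnnotation",
    "generate_annotation",
    "generate_te_landscape",
    "generate_te_experiment",
    "generate_codon_pairs",
    "generate_hit_table",
    "generate_family_history",
]

# canonical two-exon BIR module: exons of 201 nt; the 198-nt (66 aa) BIR
# occupies the last 81 bp of the first exon and the first 117 bp of the
# second.  201 is a multiple of 3, keeping all module boundaries in frame.
MODULE_EXON_BP = 201
BIR_OFFSET_NT = 120
BIR_LEN_NT = 198
TAIL_EXON_BP = 201
TAIL_DOMAIN_OFFSET_NT = 60
TAIL_DOMAIN_LEN_NT = 120

TYPE_TO_DOMAINS: dict[str, tuple[str, ...]] = {
    "A": ("BIR", "BIR", "BIR", "RING"),
    "B": ("BIR", "BIR", "RING"),
    "C": ("BIR", "BIR"),
    "D": ("BIR", "BIR", "BIR", "BIR"),
    "E": ("BIR", "BIR", "BIR"),
    "F": ("BIR", "RING"),
    "G1": ("BIR",),
    "G2": ("BIR6",),
    "G3": ("BIR", "PC4"),
}

FAMILY_DESCRIPTION = "baculoviral IAP repeat-containing protein"
BACKGROUND_DESCRIPTIONS = (
    "hypothetical protein",
    "kinesin-like protein",
    "serine/threonine protein kinase",
    "ankyrin repeat protein",
)


@dataclass(frozen=True)
class ArraySpec:
    """One planted tandem array."""

    chromosome: str
    start_bp: int
    size: int
    strand: str = "+"
    spacing_bp: int = 2_000


@dataclass
class SyntheticGenomeSpec:
    """Study conditions for one synthetic genome annotation."""

    n_chromosomes: int = 4
    chromosome_length_bp: int = 3_000_000
    n_background_genes: int = 200
    arrays: list[ArraySpec] = field(
        default_factory=lambda: [
            ArraySpec("chr1", 1_200_000, 6, "+", 2_000),
            ArraySpec("chr2", 800_000, 4, "+", 3_000),
            ArraySpec("chr3", 500_000, 3, "-", 5_000),
        ]
    )
    n_retrocopies: int = 8
    n_dispersed_members: int = 6
    #: architecture labels cycled over non-retrocopy members
    architectures: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G1", "G2", "G3")
    intergenic_gap_bp: tuple[int, int] = (8_000, 30_000)
    intron_bp: tuple[int, int] = (200, 2_000)


@dataclass
class GroundTruth:
    arrays: list[list[str]]
    retrocopy_ids: list[str]
    member_ids: list[str]
    architectures: dict[str, str]
    bir_module_bp: tuple[int, int]  # planted (first-exon, second-exon) bp
    flank_coverage: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticAnnotation:
    genes: list[GeneModel]
    domain_hits: list[DomainHit]
    cds: dict[str, str]
    proteins: dict[str, str]
    annotation_table: dict[str, str]
    chrom_sizes: dict[str, int]
    truth: GroundTruth

    @property
    def family_ids(self) -> list[str]:
        return self.truth.member_ids

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff3": outdir / "annotation.gff3",
            "cds": outdir / "cds.fasta",
            "proteins": outdir / "proteins.fasta",
            "domains": outdir / "domains.tsv",
            "annotations": outdir / "annotations.tsv",
            "chrom_sizes": outdir / "chrom.sizes",
            "truth": outdir / "truth.json",
        }
        write_gff3(self.genes, paths["gff3"])
        _write_fasta(self.cds, paths["cds"])
        _write_fasta(self.proteins, paths["proteins"])
        write_domain_table(self.domain_hits, paths["domains"])
        with open(paths["annotations"], "w") as fh:
            fh.write("#gene_id\tdescription\n")
            for gid in sorted(self.annotation_table):
                fh.write(f"{gid}\t{self.annotation_table[gid]}\n")
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom in sorted(self.chrom_sizes):
                fh.write(f"{chrom}\t{self.chrom_sizes[chrom]}\n")
        self.truth.to_json(paths["truth"])
        return paths


def _write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"]
    codons += [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 1)]
    return "".join(codons)


def _translate(cds: str) -> str:
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _member_structure(
    domains: Sequence[str],
) -> tuple[list[int], list[DomainHit]]:
    """CDS exon lengths and domain hits (template gene id) for one member.

    Each BIR/BIR6 contributes the canonical two-exon module; RING and PC4
    sit fully inside an appended tail exon, matching the single-exon RING
    convention at gene ends.
    """
    exon_lengths: list[int] = []
    hits: list[DomainHit] = []
    offset = 0
    for name in domains:
        if name in ("BIR", "BIR6"):
            nt_start = offset + BIR_OFFSET_NT
            hits.append(
                DomainHit(
                    "template",
                    name,
                    nt_start // 3 + 1,
                    (nt_start + BIR_LEN_NT) // 3,
                    1e-20,
                    100.0,
                )
            )
            exon_lengths += [MODULE_EXON_BP, MODULE_EXON_BP]
            offset += 2 * MODULE_EXON_BP
        else:  # RING, PC4 or other single-exon tail domain
            nt_start = offset + TAIL_DOMAIN_OFFSET_NT
            hits.append(
                DomainHit(
                    "template",
                    name,
                    nt_start // 3 + 1,
                    (nt_start + TAIL_DOMAIN_LEN_NT) // 3,
                    1e-15,
                    80.0,
                )
            )
            exon_lengths.append(TAIL_EXON_BP)
            offset += TAIL_EXON_BP
    return exon_lengths, hits


def _build_gene(
    gene_id: str,
    chromosome: str,
    strand: str,
    start: int,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
) -> GeneModel:
    """Lay CDS exon lengths (5'->3') onto the genome at ``start``.

    On the minus strand the 5'-most exon is rightmost, so transcript
    exon order is reversed before genomic placement.
    """
    lengths = list(exon_lengths)
    if strand == "-":
        lengths = lengths[::-1]
        intron_lengths = list(intron_lengths)[::-1]
    intervals = []
    pos = start
    for i, ln in enumerate(lengths):
        intervals.append((pos, pos + ln))
        pos += ln
        if i < len(lengths) - 1:
            pos += intron_lengths[i]
    tx = TranscriptModel(f"{gene_id}.t1", intervals, list(intervals))
    return GeneModel(gene_id, chromosome, strand, [tx])


def _gene_span(exon_lengths: Sequence[int], intron_lengths: Sequence[int]) -> int:
    return sum(exon_lengths) + sum(intron_lengths)


def generate_annotation(
    spec: SyntheticGenomeSpec, seed: int
) -> SyntheticAnnotation:
    """Emit a synthetic genome annotation with planted family structure."""
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    chrom_sizes = {c: spec.chromosome_length_bp for c in chroms}
    for a in spec.arrays:
        if a.chromosome not in chrom_sizes:
            raise ValueError(f"array chromosome '{a.chromosome}' not in genome")

    genes: list[GeneModel] = []
    hits: list[DomainHit] = []
    cds: dict[str, str] = {}
    annotation_table: dict[str, str] = {}
    truth_arrays: list[list[str]] = []
    architectures: dict[str, str] = {}
    member_ids: list[str] = []
    retro_ids: list[str] = []

    arch_cycle = list(spec.architectures)
    arch_i = 0

    def next_architecture() -> str:
        nonlocal arch_i
        label = arch_cycle[arch_i % len(arch_cycle)]
        arch_i += 1
        return label

    def add_member(
        gene_id: str, chromosome: str, strand: str, start: int, label: str
    ) -> GeneModel:
        domains = TYPE_TO_DOMAINS[label]
        exon_lengths, template_hits = _member_structure(domains)
        introns = [
            int(rng.integers(*spec.intron_bp)) for _ in range(len(exon_lengths) - 1)
        ]
        gene = _build_gene(gene_id, chromosome, strand, start, exon_lengths, introns)
        genes.append(gene)
        for h in template_hits:
            hits.append(
                DomainHit(gene_id, h.domain_name, h.aa_start, h.aa_end, h.e_value, h.score)
            )
        cds[gene_id] = _random_cds(rng, sum(exon_lengths) // 3)
        annotation_table[gene_id] = FAMILY_DESCRIPTION
        architectures[gene_id] = label
        member_ids.append(gene_id)
        return gene

    # 1. planted tandem arrays (reserve their regions)
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    member_n = 0
    for a in spec.arrays:
        ids = []
        pos = a.start_bp
        for _ in range(a.size):
            member_n += 1
            gid = f"fam{member_n:03d}"
            gene = add_member(gid, a.chromosome, a.strand, pos, next_architecture())
            ids.append(gid)
            pos = gene.end + a.spacing_bp
        truth_arrays.append(ids)
        span = (a.start_bp - 1_000, pos + 1_000)
        if span[1] > chrom_sizes[a.chromosome]:
            raise ValueError(f"array on {a.chromosome} exceeds chromosome length")
        for other in reserved[a.chromosome]:
            if span[0] < other[1] and other[0] < span[1]:
                raise ValueError("planted arrays overlap")
        reserved[a.chromosome].append(span)

    # 2. everything else: background genes, dispersed members, retrocopies,
    # scattered across chromosomes in genomic order with random gaps
    retro_parent_label = "G1"
    queue: list[tuple[str, str]] = []  # (kind, label)
    for _ in range(spec.n_dispersed_members):
        queue.append(("member", next_architecture()))
    queue += [("retro", retro_parent_label)] * spec.n_retrocopies
    queue += [("background", "")] * spec.n_background_genes
    order = rng.permutation(len(queue))
    queue = [queue[i] for i in order]

    # a dispersed G1 member acts as the retrocopies' parent
    member_n += 1
    parent_id = f"fam{member_n:03d}"
    parent_exons, parent_hits = _member_structure(TYPE_TO_DOMAINS[retro_parent_label])
    parent_placed = False

    cursors = {c: 50_000 for c in chroms}
    bg_n = 0
    retro_n = 0

    # family genes outside planted arrays must never sit close enough to an
    # array (or to each other) to chain into an unplanned tandem array
    min_family_sep = 120_000
    family_spans: dict[str, list[tuple[int, int]]] = {
        c: list(reserved[c]) for c in chroms
    }

    def advance(chrom: str, span: int, family_kind: bool = False) -> int:
        """Next free start position on ``chrom``, skipping reserved regions."""
        pos = cursors[chrom] + int(rng.integers(*spec.intergenic_gap_bp))
        moved = True
        while moved:
            moved = False
            for rs, re_ in sorted(reserved[chrom]):
                if pos < re_ and rs < pos + span:
                    pos = re_ + int(rng.integers(*spec.intergenic_gap_bp))
                    moved = True
            if family_kind:
                for fs, fe in sorted(family_spans[chrom]):
                    if pos < fe + min_family_sep and fs - min_family_sep < pos + span:
                        pos = fe + min_family_sep + int(
                            rng.integers(*spec.intergenic_gap_bp)
                        )
                        moved = True
        return pos

    items = [("parent", retro_parent_label)] + queue
    for kind, label in items:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "parent":
            introns = [
                int(rng.integers(*spec.intron_bp))
                for _ in range(len(parent_exons) - 1)
            ]
            start = advance(chrom, _gene_span(parent_exons, introns), family_kind=True)
            gene = _build_gene(parent_id, chrom, strand, start, parent_exons, introns)
            genes.append(gene)
            for h in parent_hits:
                hits.append(
                    DomainHit(parent_id, h.domain_name, h.aa_start, h.aa_end,
                              h.e_value, h.score)
                )
            cds[parent_id] = _random_cds(rng, sum(parent_exons) // 3)
            annotation_table[parent_id] = FAMILY_DESCRIPTION
            architectures[parent_id] = retro_parent_label
            member_ids.append(parent_id)
            parent_placed = True
        elif kind == "member":
            member_n += 1
            gid = f"fam{member_n:03d}"
            domains = TYPE_TO_DOMAINS[label]
            exon_lengths, _ = _member_structure(domains)
            start = advance(chrom, _gene_span(exon_lengths, [2_000] * len(exon_lengths)),
                            family_kind=True)
            add_member(gid, chrom, strand, start, label)
        elif kind == "retro":
            assert parent_placed
            retro_n += 1
            gid = f"retro{retro_n:03d}"
            total = sum(parent_exons)
            start = advance(chrom, total, family_kind=True)
            gene = _build_gene(gid, chrom, strand, start, [total], [])
            genes.append(gene)
            for h in parent_hits:
                hits.append(
                    DomainHit(gid, h.domain_name, h.aa_start, h.aa_end,
                              h.e_value, h.score)
                )
            cds[gid] = cds[parent_id]
            annotation_table[gid] = FAMILY_DESCRIPTION
            architectures[gid] = retro_parent_label
            member_ids.append(gid)
            retro_ids.append(gid)
        else:  # background
            bg_n += 1
            gid = f"bg{bg_n:04d}"
            n_exons = int(rng.integers(1, 6))
            exon_lengths = [3 * int(rng.integers(30, 200)) for _ in range(n_exons)]
            introns = [int(rng.integers(*spec.intron_bp)) for _ in range(n_exons - 1)]
            start = advance(chrom, _gene_span(exon_lengths, introns))
            gene = _build_gene(gid, chrom, strand, start, exon_lengths, introns)
            genes.append(gene)
            cds[gid] = _random_cds(rng, sum(exon_lengths) // 3)
            annotation_table[gid] = BACKGROUND_DESCRIPTIONS[
                int(rng.integers(0, len(BACKGROUND_DESCRIPTIONS)))
            ]
            protein_len = sum(exon_lengths) // 3
            r = rng.random()
            if r < 0.15 and protein_len > 120:
                # decoy domains that must not draw background genes into the
                # family: RING alone, or BIR above the e-value cutoff
                if r < 0.075:
                    hits.append(DomainHit(gid, "RING", 10, 49, 1e-12, 60.0))
                else:
                    hits.append(DomainHit(gid, "BIR", 10, 75, 1e-3, 12.0))
            elif r < 0.3 and protein_len > 120:
                hits.append(DomainHit(gid, "Pkinase", 5, 100, 1e-25, 150.0))
        gene = genes[-1]
        if gene.end > chrom_sizes[chrom] - 20_000:
            raise ValueError(
                f"chromosome {chrom} too short for the requested gene load"
            )
        cursors[chrom] = gene.end
        if kind != "background":
            family_spans[chrom].append((gene.start, gene.end))

    proteins = {gid: _translate(s) for gid, s in cds.items()}
    truth = GroundTruth(
        arrays=truth_arrays,
        retrocopy_ids=retro_ids,
        member_ids=member_ids,
        architectures=architectures,
        bir_module_bp=(MODULE_EXON_BP - BIR_OFFSET_NT, BIR_LEN_NT - (MODULE_EXON_BP - BIR_OFFSET_NT)),
    )
    return SyntheticAnnotation(
        genes=genes,
        domain_hits=hits,
        cds=cds,
        proteins=proteins,
        annotation_table=annotation_table,
        chrom_sizes=chrom_sizes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# TE landscape
# ---------------------------------------------------------------------------

def _place_coverage(
    rng: np.random.Generator,
    flank: tuple[int, int],
    target_bp: int,
    occupied: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Place non-overlapping intervals summing to ``target_bp`` in a flank.

    ``occupied`` is the sorted global list of already-placed intervals on
    the chromosome; new intervals avoid them, so merged coverage inside the
    flank equals the placed bp exactly.
    """
    placed: list[tuple[int, int]] = []
    remaining = target_bp
    attempts = 0
    while remaining > 0 and attempts < 10_000:
        attempts += 1
        length = int(min(remaining, rng.integers(150, 800)))
        if remaining - length < 100:
            length = remaining
        lo, hi = flank
        if hi - lo < length:
            break
        start = int(rng.integers(lo, hi - length + 1))
        end = start + length
        i = bisect_left(occupied, (start, start))
        clash = False
        for j in (i - 1, i):
            if 0 <= j < len(occupied):
                os_, oe = occupied[j]
                if start < oe and os_ < end:
                    clash = True
                    break
        if clash:
            continue
        insort(occupied, (start, end))
        placed.append((start, end))
        remaining -= length
    return placed


def generate_te_landscape(
    genes: Sequence[GeneModel],
    family_ids: Sequence[str],
    chrom_sizes: Mapping[str, int],
    seed: int,
    family_coverage: Mapping[str, float] | None = None,
    background_coverage: Mapping[str, float] | None = None,
    window_bp: int = 10_000,
) -> tuple[list[TEInterval], dict[str, dict[str, float]]]:
    """Plant per-class TE coverage in the flanks of every gene.

    Coverage fractions are realised per flank to within one interval's
    resolution (well inside +-0.2 percentage points).  Returns the TE
    intervals and the realised per-group mean coverage per class.
    """
    family_coverage = dict(family_coverage or {"DNA": 0.12, "LINE": 0.07})
    background_coverage = dict(background_coverage or {"DNA": 0.05, "LINE": 0.07})
    for cov in (family_coverage, background_coverage):
        for klass, frac in cov.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"coverage for {klass} outside [0, 1]")
    rng = np.random.default_rng(seed)
    family = set(family_ids)
    tes: list[TEInterval] = []
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}
    realized: dict[str, dict[str, list[float]]] = {}

    for gene in genes:
        coverage = family_coverage if gene.gene_id in family else background_coverage
        group = "family" if gene.gene_id in family else "background"
        chrom_len = chrom_sizes[gene.chromosome]
        flanks = [
            (max(0, gene.start - window_bp), gene.start),
            (gene.end, min(chrom_len, gene.end + window_bp)),
        ]
        flanks = [(s, e) for s, e in flanks if e > s]
        available = sum(e - s for s, e in flanks)
        for klass in sorted(coverage):
            frac = coverage[klass]
            occ = occupied.setdefault((gene.chromosome, klass), [])
            covered = 0
            for flank in flanks:
                flank_len = flank[1] - flank[0]
                # realised coverage varies within +-0.2 pp of the planted
                # fraction so groups keep a natural, non-zero variance; a
                # planted coverage of exactly 0 (or 1) stays exact
                if frac in (0.0, 1.0):
                    jittered = frac
                else:
                    jittered = min(1.0, max(0.0, frac + rng.uniform(-0.002, 0.002)))
                target = int(round(jittered * flank_len))
                for s, e in _place_coverage(rng, flank, target, occ):
                    tes.append(TEInterval(gene.chromosome, s, e, klass))
                    covered += e - s
            realized.setdefault(group, {}).setdefault(klass, []).append(
                covered / available if available else 0.0
            )

    tes.sort(key=lambda t: (t.chromosome, t.start, t.end))
    summary = {
        group: {klass: float(np.mean(vals)) for klass, vals in classes.items()}
        for group, classes in realized.items()
    }
    return tes, summary


def generate_te_experiment(
    n_family: int = 200,
    n_background: int = 2_000,
    family_coverage: float = 0.12,
    background_coverage: float = 0.05,
    window_bp: int = 10_000,
    seed: int = 42,
) -> tuple[list[GeneModel], list[str], dict[str, int], list[TEInterval]]:
    """Isolated-gene layout for TE flank-density recovery experiments.

    Genes are single-exon models spaced so that no two flanks overlap;
    DNA-transposon coverage is planted at ``family_coverage`` in family
    flanks and ``background_coverage`` in background flanks.
    """
    rng = np.random.default_rng(seed)
    gene_len = 3_000
    pitch = 2 * window_bp + gene_len + 5_000
    per_chrom = 250
    genes: list[GeneModel] = []
    family_ids: list[str] = []
    labels = ["fam"] * n_family + ["bg"] * n_background
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    chrom_sizes: dict[str, int] = {}
    for i, label in enumerate(labels):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        start = window_bp + 2_000 + slot * pitch
        gid = f"{label}{i:05d}"
        tx = TranscriptModel(f"{gid}.t1", [(start, start + gene_len)],
                             [(start, start + gene_len)])
        genes.append(GeneModel(gid, chrom, "+", [tx]))
        if label == "fam":
            family_ids.append(gid)
        chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), start + gene_len + window_bp + 2_000)
    tes, _ = generate_te_landscape(
        genes,
        family_ids,
        chrom_sizes,
        seed=int(rng.integers(0, 2**31 - 1)),
        family_coverage={"DNA": family_coverage},
        background_coverage={"DNA": background_coverage},
        window_bp=window_bp,
    )
    return genes, family_ids, chrom_sizes, tes


# ---------------------------------------------------------------------------
# codon-pair evolution
# ---------------------------------------------------------------------------

def generate_codon_pairs(
    omega: float,
    target_substitutions: int,
    n_codons: int,
    seed: int,
) -> tuple[str, str, dict[str, int]]:
    """Evolve one aligned CDS pair at a planted dN/dS.

    An ancestor of ``n_codons`` uniform sense codons accumulates accepted
    single-nucleotide substitutions: synonymous proposals are accepted with
    relative probability 1, nonsynonymous with ``omega``; proposals
    creating stop codons are rejected outright.  The truth dict records the
    realised synonymous/nonsynonymous event counts.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if n_codons < 1:
        raise ValueError("n_codons must be positive")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    ancestor = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    derived = list(ancestor)
    n_syn = n_nonsyn = 0
    guard = 0
    max_attempts = 2_000 * max(1, target_substitutions)
    while n_syn + n_nonsyn < target_substitutions and guard < max_attempts:
        guard += 1
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        codon = derived[ci]
        base = bases[int(rng.integers(0, 4))]
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
        if not synonymous and rng.random() >= omega:
            continue
        derived[ci] = mutant
        if synonymous:
            n_syn += 1
        else:
            n_nonsyn += 1
    truth = {"n_syn_events": n_syn, "n_nonsyn_events": n_nonsyn}
    return "".join(ancestor), "".join(derived), truth


# ---------------------------------------------------------------------------
# hit tables and family histories
# ---------------------------------------------------------------------------

def generate_hit_table(
    age_assignments: Mapping[str, int],
    pmap: PhylostratumMap,
    seed: int,
    decoy_probability: float = 0.3,
) -> tuple[list[HomologyHit], dict[str, str]]:
    """Homology hits consistent with planted gene ages.

    Each gene gets qualifying hits (e < 1e-10) only in species whose rank
    is >= its planted rank, with at least one hit at the rank itself;
    decoy hits at e = 1e-9 may appear in older (lower-rank) species and
    must not change the assignment.  Returns hits plus the subject->species
    map for the emitted subject identifiers.
    """
    rng = np.random.default_rng(seed)
    by_rank: dict[int, list[str]] = {}
    for sp, rank in pmap.species_rank.items():
        by_rank.setdefault(rank, []).append(sp)
    for rank in by_rank:
        by_rank[rank].sort()

    hits: list[HomologyHit] = []
    subject_map: dict[str, str] = {}
    n_subject = 0

    def emit(gene: str, species: str, e_value: float) -> None:
        nonlocal n_subject
        n_subject += 1
        subject = f"{species}|p{n_subject:05d}"
        subject_map[subject] = species
        hits.append(HomologyHit(gene, species, e_value))

    for gene in sorted(age_assignments):
        rank = age_assignments[gene]
        if rank not in by_rank:
            raise ValueError(f"planted rank {rank} has no species in the map")
        anchor = by_rank[rank][int(rng.integers(0, len(by_rank[rank])))]
        emit(gene, anchor, 10.0 ** -float(rng.integers(12, 60)))
        # extra qualifying hits in the same or younger strata
        for _ in range(int(rng.integers(0, 3))):
            younger = [
                sp for r in range(rank, pmap.n_strata + 1) for sp in by_rank.get(r, [])
            ]
            sp = younger[int(rng.integers(0, len(younger)))]
            emit(gene, sp, 10.0 ** -float(rng.integers(12, 60)))
        if rank > 1 and rng.random() < decoy_probability:
            older = [sp for r in range(1, rank) for sp in by_rank.get(r, [])]
            sp = older[int(rng.integers(0, len(older)))]
            emit(gene, sp, 1e-9)  # above the strict < 1e-10 cutoff
    return hits, subject_map


def generate_family_history(
    tree: dendropy.Tree,
    root_count: int,
    seed: int,
    events: Mapping[str, int] | None = None,
    max_gain: int = 3,
    max_loss: int = 2,
) -> tuple[dict[str, int], dict[str, int], int]:
    """Evolve family counts along a tree by per-branch gain/loss deltas.

    ``events`` maps child-node labels to signed deltas; unspecified
    branches (or all, when ``events`` is None) draw a delta uniformly from
    [-max_loss, +max_gain].  Raises if any branch would drive a count
    negative.  Returns (leaf counts, all node counts, total event count).
    """
    rng = np.random.default_rng(seed)
    tree = tree.clone(depth=1)
    i = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"node{i}"
            i += 1
    counts: dict[str, int] = {}
    total_events = 0
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.is_leaf() else node.label
        if node.parent_node is None:
            counts[label] = root_count
            continue
        parent_label = (
            node.parent_node.taxon.label
            if node.parent_node.is_leaf()
            else node.parent_node.label
        )
        if events is not None and label in events:
            delta = int(events[label])
        elif events is not None:
            delta = 0
        else:
            delta = int(rng.integers(-max_loss, max_gain + 1))
        value = counts[parent_label] + delta
        if value < 0:
            raise ValueError(
                f"branch to '{label}' drives the count below zero "
                f"({counts[parent_label]} {delta:+d})"
            )
        counts[label] = value
        total_events += abs(delta)
    leaf_counts = {
        leaf.taxon.label: counts[leaf.taxon.label] for leaf in tree.leaf_node_iter()
    }
    return leaf_counts, counts, total_events
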