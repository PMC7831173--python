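"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are normalised to a single internal convention:
0-based, half-open ``[start, end)``.  GFF3 (1-based, closed) is converted on
read and write; BED is already half-open and passes through unchanged.
Protein coordinates in domain hits stay 1-based inclusive, as in Pfam/HMMER
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "FormatWarning",
    "ParseError",
    "TranscriptModel",
    "GeneModel",
    "DomainHit",
    "TEInterval",
    "HomologyHit",
    "read_gff3",
    "write_gff3",
    "read_domain_table",
    "read_te_bed",
    "read_newick",
    "read_hit_table",
    "read_counts_table",
    "read_chrom_sizes",
]

TE_CLASSES = ("DNA", "LINE", "LTR", "SINE", "other")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class FormatWarning(UserWarning):
    """Non-fatal irregularity in an input file (skipped or defaulted)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

Interval = tuple[int, int]


@dataclass
class TranscriptModel:
    """One transcript: exon and CDS intervals in genomic coordinates.

    ``exons`` and ``cds`` are sorted ascending by genomic start regardless of
    strand; transcript (5'->3') orientation is recovered on demand from the
    parent gene's strand.
    """

    transcript_id: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    partial: bool = False

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def n_coding_exons(self) -> int:
        """Number of exons that carry at least one CDS base."""
        return sum(
            1
            for es, ee in self.exons
            if any(cs < ee and es < ce for cs, ce in self.cds)
        )

    def validate(self) -> None:
        for s, e in self.exons + self.cds:
            if e <= s:
                raise ParseError(
                    f"transcript {self.transcript_id}: empty interval [{s}, {e})"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ParseError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )


@dataclass
class GeneModel:
    """One gene: chromosome, strand and its transcripts."""

    gene_id: str
    chromosome: str
    strand: str
    transcripts: list[TranscriptModel]
    source_line: int = -1
    flags: list[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for t in self.transcripts for s, _ in t.exons)

    @property
    def end(self) -> int:
        return max(e for t in self.transcripts for _, e in t.exons)

    def representative_transcript(self) -> TranscriptModel:
        """The transcript with the greatest coding length.

        Ties are broken lexicographically by transcript id so the choice is
        deterministic, mirroring longest-transcript selection.
        """
        return min(self.transcripts, key=lambda t: (-t.coding_length, t.transcript_id))


@dataclass(frozen=True)
class DomainHit:
    """A protein-domain hit in 1-based inclusive amino-acid coordinates."""

    gene_id: str
    domain_name: str
    aa_start: int
    aa_end: int
    e_value: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ParseError(
                f"domain hit {self.gene_id}/{self.domain_name}: "
                f"invalid coordinates {self.aa_start}..{self.aa_end}"
            )
        if self.e_value < 0:
            raise ParseError(
                f"domain hit {self.gene_id}/{self.domain_name}: negative e-value"
            )

    @property
    def aa_length(self) -> int:
        return self.aa_end - self.aa_start + 1


@dataclass(frozen=True)
class TEInterval:
    """A transposable-element interval, 0-based half-open."""

    chromosome: str
    start: int
    end: int
    te_class: str = "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(
                f"TE interval {self.chromosome}:{self.start}-{self.end} is empty"
            )


@dataclass(frozen=True)
class HomologyHit:
    query_gene: str
    subject_species: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ParseError(f"homology hit {self.query_gene}: negative e-value")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GENE_TYPES = {"gene"}
_TRANSCRIPT_TYPES = {"mRNA", "transcript"}
_PART_TYPES = {"exon", "CDS"}


def _parse_attributes(col: str, line_no: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"line {line_no}: malformed attribute '{item}'")
        key, value = item.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 annotation into :class:`GeneModel` objects.

    Requires gene / mRNA / exon / CDS features linked by ``ID``/``Parent``.
    Coordinates are converted from GFF3 1-based closed to internal 0-based
    half-open.  Unknown feature types are skipped with one counted warning.
    A CDS interval not contained in any exon of its transcript flags the gene
    (``cds_outside_exon``) with a warning rather than failing.
    """
    rows = []  # (line_no, chrom, ftype, start0, end, strand, attrs)
    unknown_types: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"line {line_no}: expected 9 tab-separated columns, got {len(cols)}"
                )
            ftype = cols[2]
            try:
                start1, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"line {line_no}: non-numeric coordinates") from exc
            if end < start1:
                raise ParseError(
                    f"line {line_no}: end ({end}) < start ({start1})"
                )
            if ftype not in _GENE_TYPES | _TRANSCRIPT_TYPES | _PART_TYPES:
                unknown_types[ftype] = unknown_types.get(ftype, 0) + 1
                continue
            attrs = _parse_attributes(cols[8], line_no)
            rows.append((line_no, cols[0], ftype, start1 - 1, end, cols[6], attrs))

    if unknown_types:
        total = sum(unknown_types.values())
        warnings.warn(
            f"ignored {total} features of unknown type(s): "
            + ", ".join(sorted(unknown_types)),
            FormatWarning,
            stacklevel=2,
        )

    genes: dict[str, GeneModel] = {}
    tx_rows: dict[str, tuple[int, str, str]] = {}  # tx_id -> (line, gene_id, chrom)
    tx_parts: dict[str, dict[str, list[Interval]]] = {}

    for line_no, chrom, ftype, start, end, strand, attrs in rows:
        if ftype in _GENE_TYPES:
            gid = attrs.get("ID")
            if gid is None:
                raise ParseError(f"line {line_no}: gene feature without ID")
            if gid in genes:
                raise ParseError(f"line {line_no}: duplicate gene ID '{gid}'")
            genes[gid] = GeneModel(gid, chrom, strand, [], source_line=line_no)
    for line_no, chrom, ftype, start, end, strand, attrs in rows:
        if ftype in _TRANSCRIPT_TYPES:
            tid, parent = attrs.get("ID"), attrs.get("Parent")
            if tid is None:
                raise ParseError(f"line {line_no}: transcript feature without ID")
            if parent is None or parent not in genes:
                raise ParseError(
                    f"line {line_no}: transcript '{tid}' has missing or "
                    f"unresolvable Parent '{parent}'"
                )
            tx_rows[tid] = (line_no, parent, chrom)
            tx_parts[tid] = {"exon": [], "CDS": []}
    for line_no, chrom, ftype, start, end, strand, attrs in rows:
        if ftype in _PART_TYPES:
            parent = attrs.get("Parent")
            if parent is None or parent not in tx_parts:
                raise ParseError(
                    f"line {line_no}: {ftype} has missing or unresolvable "
                    f"Parent '{parent}'"
                )
            tx_parts[parent][ftype].append((start, end))

    for tid, (line_no, gene_id, chrom) in tx_rows.items():
        exons = sorted(tx_parts[tid]["exon"])
        cds = sorted(tx_parts[tid]["CDS"])
        tx = TranscriptModel(tid, exons, cds)
        tx.validate()
        gene = genes[gene_id]
        for cs, ce in cds:
            if not any(es <= cs and ce <= ee for es, ee in exons):
                warnings.warn(
                    f"transcript {tid} (line {line_no}): CDS [{cs},{ce}) not "
                    "contained in any exon; gene flagged",
                    FormatWarning,
                    stacklevel=2,
                )
                if "cds_outside_exon" not in gene.flags:
                    gene.flags.append("cds_outside_exon")
        if tx.coding_length % 3 != 0:
            tx.partial = True
        gene.transcripts.append(tx)

    empty = [g for g in genes.values() if not g.transcripts]
    if empty:
        raise ParseError(
            f"gene(s) without transcripts: {', '.join(g.gene_id for g in empty)}"
        )
    return list(genes.values())


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3, converting back to 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            fh.write(
                "\t".join(
                    [
                        gene.chromosome,
                        "famex",
                        "gene",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={gene.gene_id}",
                    ]
                )
                + "\n"
            )
            for tx in gene.transcripts:
                tx_start = min(s for s, _ in tx.exons)
                tx_end = max(e for _, e in tx.exons)
                fh.write(
                    "\t".join(
                        [
                            gene.chromosome,
                            "famex",
                            "mRNA",
                            str(tx_start + 1),
                            str(tx_end),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={tx.transcript_id};Parent={gene.gene_id}",
                        ]
                    )
                    + "\n"
                )
                for ftype, ivals in (("exon", tx.exons), ("CDS", tx.cds)):
                    for s, e in ivals:
                        fh.write(
                            "\t".join(
                                [
                                    gene.chromosome,
                                    "famex",
                                    ftype,
                                    str(s + 1),
                                    str(e),
                                    ".",
                                    gene.strand,
                                    "." if ftype == "exon" else "0",
                                    f"Parent={tx.transcript_id}",
                                ]
                            )
                            + "\n"
                        )


# ---------------------------------------------------------------------------
# domain hit tables
# ---------------------------------------------------------------------------

def read_domain_table(
    path: str | Path, dialect: str = "simple_tsv"
) -> list[DomainHit]:
    """Read per-gene domain hits.

    ``simple_tsv``: columns gene_id, domain_name, aa_start, aa_end, e_value
    and optional score; ``#`` comment lines ignored.

    ``domtblout``: HMMER3 ``hmmscan --domtblout`` layout (whitespace
    separated).  The protein is the query (column 4), the domain model the
    target (column 1); envelope coordinates come from columns 20-21 and the
    per-domain independent E-value from column 13 (all 1-based column
    numbers).
    """
    if dialect not in ("simple_tsv", "domtblout"):
        raise ValueError(f"unknown dialect '{dialect}'")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                if dialect == "simple_tsv":
                    cols = line.split()
                    gene_id, domain = cols[0], cols[1]
                    aa_start, aa_end = int(cols[2]), int(cols[3])
                    e_value = float(cols[4])
                    score = float(cols[5]) if len(cols) > 5 else 0.0
                else:
                    cols = line.split()
                    domain, gene_id = cols[0], cols[3]
                    e_value, score = float(cols[12]), float(cols[13])
                    aa_start, aa_end = int(cols[19]), int(cols[20])
                hits.append(
                    DomainHit(gene_id, domain, aa_start, aa_end, e_value, score)
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: unparsable row at line {line_no}: {exc}")
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tdomain\taa_start\taa_end\te_value\tscore\n")
        for h in hits:
            fh.write(
                f"{h.gene_id}\t{h.domain_name}\t{h.aa_start}\t{h.aa_end}"
                f"\t{h.e_value:g}\t{h.score:g}\n"
            )


# ---------------------------------------------------------------------------
# BED / TE annotation
# ---------------------------------------------------------------------------

def read_te_bed(path: str | Path) -> list[TEInterval]:
    """Read a TE annotation from BED3+ (class in column 4, default 'other')."""
    tes: list[TEInterval] = []
    n_skipped = 0
    n_other = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(
                    f"{path}: line {line_no}: non-numeric coordinates"
                ) from exc
            if end <= start:
                n_skipped += 1
                continue
            te_class = cols[3] if len(cols) > 3 else "other"
            if te_class not in TE_CLASSES:
                n_other += 1
                te_class = "other"
            tes.append(TEInterval(chrom, start, end, te_class))
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} zero-length interval(s)",
            FormatWarning,
            stacklevel=2,
        )
    if n_other:
        warnings.warn(
            f"{path}: {n_other} interval(s) of unrecognised class bucketed "
            "as 'other'",
            FormatWarning,
            stacklevel=2,
        )
    return tes


def write_te_bed(tes: Iterable[TEInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            fh.write(f"{te.chromosome}\t{te.start}\t{te.end}\t{te.te_class}\n")


# ---------------------------------------------------------------------------
# trees, hit tables, counts
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted species tree from Newick.

    A basal polytomy (root with more than two children) is accepted but the
    tree is flagged via ``tree.basal_polytomy`` because ancestral-count
    reconstruction interprets the tree as rooted as given.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ParseError(f"{path}: duplicate leaf labels in species tree")
    tree.basal_polytomy = len(tree.seed_node.child_nodes()) > 2
    if tree.basal_polytomy:
        warnings.warn(
            f"{path}: basal polytomy at the root; tree treated as rooted "
            "as written",
            FormatWarning,
            stacklevel=2,
        )
    return tree


def read_hit_table(
    path: str | Path, subject_species: Mapping[str, str]
) -> list[HomologyHit]:
    """Reduce a 12-column tabular alignment file to homology hits.

    Columns follow BLAST ``-outfmt 6`` (query, subject, identity, length,
    mismatches, gap opens, qstart, qend, sstart, send, evalue, bitscore);
    only query, subject and e-value are retained, the subject being mapped
    to a species via ``subject_species``.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 12:
                raise ParseError(
                    f"{path}: line {line_no}: expected 12 columns, got {len(cols)}"
                )
            query, subject = cols[0], cols[1]
            try:
                e_value = float(cols[10])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {line_no}: bad e-value '{cols[10]}'"
                ) from exc
            if subject not in subject_species:
                raise ParseError(
                    f"{path}: line {line_no}: subject '{subject}' absent from "
                    "subject->species map"
                )
            hits.append(HomologyHit(query, subject_species[subject], e_value))
    return hits


def read_counts_table(path: str | Path) -> dict[str, int]:
    """Read per-species family counts from a TSV with header species<TAB>count."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("species"):
            raise ParseError(f"{path}: expected header 'species\\tcount'")
        for line_no, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 2:
                raise ParseError(f"{path}: line {line_no}: expected 2 columns")
            species, count = cols[0], int(cols[1])
            if species in counts:
                raise ParseError(
                    f"{path}: line {line_no}: duplicate species '{species}'"
                )
            if count < 0:
                raise ParseError(f"{path}: line {line_no}: negative count")
            counts[species] = count
    return counts


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """Generic key<TAB>value map (e.g. subject->species); '#' lines ignored."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            key, value = line.split()[:2]
            mapping[key] = value
    return mapping


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from a two-column TSV or a FASTA .fai index."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            sizes[cols[0]] = int(cols[1])
    return sizes
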