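# Methods

`famex` analyses the genomic signatures of a massively expanded gene
family — the motivating case is the bivalve IAP (inhibitor of apoptosis
protein) repertoire, where a family defined by the BIR domain expands into
dozens to hundreds of copies through tandem duplication and retroposition.
This note documents the models and procedures each module implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Coordinate conventions

All interval arithmetic uses 0-based, half-open genomic coordinates.
GFF3 (1-based, closed) is converted on read and write; BED is half-open
and passes through. Protein coordinates in domain-hit tables remain
1-based inclusive, following HMMER/Pfam convention; the envelope
coordinates of a hit (not its alignment coordinates) define the domain's
extent. Each gene's *representative transcript* is the one with the
greatest coding length, ties broken lexicographically by transcript id —
the deterministic version of longest-transcript selection.

## Family selection and architecture typing

A gene joins the family when it has at least one hit of a required
diagnostic domain (default `BIR` or `BIR6`) with e-value ≤ 1e-5 and, if a
functional-annotation table is supplied, a description matching at least
one family keyword (default: "inhibitor of apoptosis", "IAP",
"baculoviral IAP repeat"). The keyword filter is the reproducible
replacement for manual curation; explicit include/exclude lists restore
curation where needed.

A gene's ordered N→C domain string is resolved from its hits: sorted by
protein start, and when two hits overlap by more than 50% of the shorter
one, the better hit is kept (lower e-value, then higher score, then longer
span). Architectures are classified by an ordered first-match rule table
keyed on BIR copy number, RING presence and marker domains:

| rule (in order) | label |
|---|---|
| contains BIR6 | G2 |
| PC4 and exactly one BIR | G3 |
| four BIR | D |
| three BIR + RING / without RING | A / E |
| two BIR + RING / without RING | B / C |
| one BIR + RING / without RING | F / G1 |
| otherwise | unclassified |

The letter↔structure correspondence for the one- and two-BIR types (B, C,
F, G1) cannot be fixed unambiguously from published descriptions, which
treat them collectively; the table above is therefore an explicit,
documented convention, overridable via a custom `TypeRuleTable`.
Auxiliary domains (UBA, CARD, NACHT, …) are recorded in the domain string
but ignored by the default rules. Classification is a total function of
the domain string and is invariant to input hit order.

## Tandem arrays and retrocopies

Tandem arrays are maximal chains of family genes in chromosomal gene
order. Two consecutive members chain when (a) their intergenic gap is ≤
`max_gap_bp` (default 100 kb), (b) at most `max_intervening` non-family
genes lie between them (default 0), and (c) optionally their strands
agree (off by default — strand agreement is *reported* per array either
way). "Densely linked" has no published quantitative definition; the
defaults are chosen so that the canonical worked example — six same-strand
family genes within a ~90-kb window with no interspersed genes — forms
exactly one array, and all three thresholds are exposed in the config.

Retrocopy candidates are members whose representative transcript has a
single CDS-bearing exon (intron count 0). Counting CDS-bearing exons
rather than all exons means UTR-only exons cannot mask a retrocopy:
retroposition acts on the mRNA, and the diagnostic is the intronless
coding structure. Whether published per-chromosome member counts refer to
array members only or to all members on the chromosome is ambiguous, so
the chromosome-distribution table reports all members per chromosome and
the array table reports array membership separately.

## Intron phases and domain/exon structure

Intron phase is the number of coding nucleotides 5' of the intron modulo
3, computed on the CDS intervals of the representative transcript in
transcript orientation. Whether published phase diagrams use CDS-only or
full-transcript coordinates is not stated; CDS-only is the default here
(`cds_only=False` switches to exon-length accumulation). Introns entirely
outside the CDS are counted but not phased.

A domain at protein positions `aa_start..aa_end` occupies coding
nucleotides `[(aa_start−1)·3, aa_end·3)`; walking this footprint across
the ordered CDS segments yields per-exon bp (which must sum to 3× the
domain's aa length — an invariant the tests enforce) and the phases of the
flanking introns. In boundary summaries, "first/second exon" means the
first and second exon *the domain touches*, generalising the canonical
"BIR spans the last ~80 bp of exon 1 and first ~120 bp of exon 2"
description to internal repeats.

## Ka/Ks (NG86)

Pairwise Ka/Ks uses the Nei–Gojobori (1986) counting method. Synonymous
site counts per codon classify each of the nine single-nucleotide
neighbours under the standard genetic code; mutations to stop codons are
excluded and each position is renormalised to one full site, so every
codon contributes exactly 3 sites. Observed substitutions between two
codons are averaged over all orderings of the differing positions whose
intermediates avoid stop codons; codon pairs whose every pathway is
blocked are skipped with a warning. Proportions pS = Sd/S and pN = Nd/N
are corrected for multiple hits with Jukes–Cantor, −(3/4)·ln(1 − 4p/3),
undefined at p ≥ 3/4. Departure from Ka/Ks = 1 is assessed by a
two-sided Fisher exact test on the rounded 2×2 table
[Sd, Nd; S−Sd, N−Nd]. Input must be pre-aligned codon alignments; a
back-translation helper threads unaligned CDS onto an aligned protein
pair, but alignment itself is out of scope. The original analyses this
replaces used a standalone calculator whose exact model option is
unpublished; NG86 + JC + Fisher is that family of tools' classic mode, and
exact reproduction of previously printed p-values is not claimed.

Calibration (enforced by the test suite): under neutral simulation
(ω = 1, 10,000 codons) the mean estimate lies in [0.9, 1.1]; a planted
ω = 0.2 is recovered within the simulation confidence interval over 200
replicates and flagged significant in ≥ 90% of them.

## TE flank enrichment

TE density of a gene is the fraction of its flanks — `[start−w, start)` ∪
`[end, end+w)`, w = 10 kb, truncated at chromosome ends — covered by
merged TE intervals of one class. Coverage fraction was chosen as the
density metric because it is bounded, scale-free, and invariant to how the
repeat annotation fragments intervals; a count-per-kb variant can be
derived from the exported per-gene table. Family and background (all
non-family genes) densities are compared per TE class with a two-sided
Welch t-test; the variance flavour of previously published t-tests is
unstated, and Welch is the safer default under unequal group sizes.
Groups with no within-group variance are reported as degenerate rather
than tested.

## Cross-species domain overrepresentation

From per-species presence counts (a domain with multiple copies in one
protein counts once), each domain is tested in a 2×2 table: genes
with/without the domain in the focal species versus all other species
pooled, chi-square without Yates continuity correction, falling back to
Fisher's exact test when an expected cell is below 1. "All annotated genes
as background" is implemented as focal-versus-pooled-others; raw p-values
are Benjamini–Hochberg adjusted across domains (the published correction
method is unnamed; BH is the documented default, configurable).

## Expression

FPKM follows the printed formula exactly:
`FPKM = reads_in_gene × 10⁹ / (total reads mapped in genes × gene length in nt)`.
A gene is silent when its mean FPKM across samples is below 0.1 (strict
inequality); silent genes are excluded from downstream expression
summaries. Differential-expression calling is out of scope.

## Phylostratigraphy

Species are ranked into phylostrata (PS1 = origin of cellular life =
oldest). A gene's age is the minimum rank among species holding a
homology hit with e-value strictly below 1e-10 ("< e−10" is read as a
strict inequality). Genes with no qualifying hit are excluded rather than
assumed lineage-specific; an opt-in `self_rank` treats them as young
lineage-specific genes instead. The number of strata is configurable, not
hard-coded — published accounts disagree internally on whether 10 or 13
ranks were used, so the rank map ships as an editable TSV. Two
monotonicity laws hold and are tested: adding a hit can only decrease a
gene's rank, and tightening the cutoff can only increase it.

## Ancestral family sizes (Wagner parsimony)

Leaf counts on a rooted species tree are reconstructed by linear-cost
(Wagner) parsimony: dynamic programming over integer states 0..max(leaf
count) computes each node's convex cost profile (a bottom-up Farris-style
pass, generalised to multifurcations); the top-down pass assigns the root
the minimum of its optimal interval and every other node the value in its
optimal interval closest to its parent — fixed tie-breaks so output is
reproducible. Per-branch gains/losses are the positive/negative parts of
child − parent, and their sum equals the total cost (asserted at run
time against the DP minimum). This is a deliberate, documented substitute
for stochastic birth–death likelihood methods (CAFÉ-style λ estimation and
family-wise p-values are non-goals): it is deterministic and verifiable
against exhaustive enumeration, at the price of ignoring branch lengths
and rate estimation, so published ancestral counts from birth–death models
are qualitative, not numeric, reference points.

## Synthetic data: what it emulates, and what it does not

The generator plants every structure the detectors look for, at study-like
conditions, from a single seed (identical spec + seed ⇒ byte-identical
files):

- **Genome layout** — default 4 chromosomes × 3 Mb carrying 200 background
  genes and a family of ~28: three tandem arrays (6, 4 and 3 members;
  2–5 kb spacing; fixed strands), 7 dispersed multi-exon members, and 8
  retrocopies emitted as single-exon copies of a dispersed G1 parent's
  spliced CDS. Dispersed family genes are kept ≥ 120 kb from arrays and
  from each other so planted arrays are exactly the detectable ones.
- **Gene structure** — every BIR is a canonical two-exon module (201-bp
  exons; the 198-nt domain spans the last 81 bp of the first exon and
  first 117 bp of the second), RING/PC4 sit inside a single tail exon;
  background genes have 1–5 exons with random in-frame lengths.
- **TE landscape** — per-class coverage planted per flank to within
  ±0.2 percentage points (defaults: DNA 0.12 in family flanks vs 0.05 in
  background, the reported contrast; LINE 0.07 in both as a null class).
  A dedicated isolated-gene layout (`generate_te_experiment`) spaces genes
  so no two flanks overlap; in the arrayed genome, neighbouring members'
  flanks overlap and realised densities exceed the per-flank target, which
  is realistic for tandem arrays but means parameter-recovery claims use
  the isolated layout.
- **Codon divergence** — ancestor of uniform sense codons; proposed
  single-nt changes accepted with probability 1 (synonymous) or ω
  (nonsynonymous), stops rejected; realised event counts recorded.
- **Ages and histories** — homology hits below the cutoff only in species
  at or younger than the planted stratum, plus decoy hits at e = 1e-9 in
  older species; family counts evolved by explicit per-branch gain/loss
  events (reconstruction cost ≤ event count is the tested parsimony
  bound).

It does **not** emulate: realistic nucleotide composition or codon usage,
sequence-level homology (hits are asserted, not aligned), TE family
taxonomy or nested insertions, alternative splicing (one transcript per
gene except in dedicated fixtures), assembly artefacts, or annotation
error. Passing closure tests therefore demonstrates correctness of the
detectors' logic under clean inputs, not robustness to noisy real-world
annotations.

## Problem sizes and numerical choices

Default test-suite problem sizes — a ~230-gene genome, 2,200 genes in the
TE recovery experiment, 200 Ka/Ks replicates of 500 codons, 50 neutral
replicates of 10,000 codons, and the exhaustive Wagner sweep (all rooted
binary shapes ≤ 6 leaves; all count tuples ≤ 5 leaves, a seeded sample of
400 per shape at 6) — were chosen as the smallest sizes at which the
statistical claims are stable across seeds. All randomness flows through
`numpy.random.default_rng` from explicit seeds; no global random state is
touched. Percentages in distribution tables are rounded to 0.1%;
reported fractions are kept at full precision alongside.

## Known limitations

- NG86 underestimates divergence at high substitution loads; no
  maximum-likelihood codon models (GY94/YN00) are provided.
- Wagner parsimony ignores branch lengths; gains and losses on long
  branches are not penalised differently.
- The tandem-array chain rule is purely positional; no synteny or
  Ks-dating evidence is used to separate old from recent arrays.
- The overrepresentation background pools all non-focal species, which
  weights large genomes more heavily.
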