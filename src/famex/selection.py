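"""Nei–Gojobori (1986) Ka/Ks for aligned coding-sequence pairs.

Synonymous/nonsynonymous *sites* are counted per codon by classifying the
single-nucleotide mutational neighbourhood under the standard genetic code
(mutations to stop codons excluded, each position renormalised to one
site).  Observed substitutions between two codons are averaged over all
orderings of the differing positions whose intermediate codons avoid
stops.  Proportions are corrected for multiple hits with the Jukes–Cantor
formula, and departure from Ka/Ks = 1 is tested with a two-sided Fisher
exact test on the rounded substitution/site contingency table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from scipy.stats import fisher_exact

from .io_formats import FormatWarning

__all__ = [
    "KaKsResult",
    "SENSE_CODONS",
    "STOP_CODONS",
    "translate_codon",
    "count_sites_ng86",
    "count_substitutions_ng86",
    "kaks_pair",
]

_BASES = "ACGT"

# Standard genetic code, codon -> one-letter amino acid ('*' = stop).
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))


def translate_codon(codon: str) -> str:
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        raise ValueError(f"invalid codon '{codon}'") from None


@dataclass
class KaKsResult:
    pair: tuple[str, str]
    n_codons: int  # codons actually compared (after pairwise dropping)
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    p_value: float


@lru_cache(maxsize=None)
def count_sites_ng86(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    At each position the synonymous fraction is (synonymous single-nt
    mutations) / (mutations not creating a stop), so each position always
    contributes one full site and syn + nonsyn == 3.
    """
    codon = codon.upper()
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError(f"stop codon '{codon}' has no site counts")
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            n_valid += 1
            if GENETIC_CODE[mutant] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def count_substitutions_ng86(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    Every ordering of the differing positions defines a mutational pathway;
    pathways passing through a stop codon are discarded and each step of
    the remaining pathways is classified synonymous or nonsynonymous.
    Returns (0, 0) for identical codons; raises if every pathway is blocked
    by stop codons.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if translate_codon(c) == "*":
            raise ValueError(f"stop codon '{c}' in substitution counting")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in permutations(diff):
        current = codon_a
        steps: list[tuple[str, str]] = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append((current, nxt))
            current = nxt
        if blocked:
            continue
        n_paths += 1
        for frm, to in steps:
            if GENETIC_CODE[frm] == GENETIC_CODE[to]:
                syn_total += 1
            else:
                nonsyn_total += 1
    if n_paths == 0:
        raise ValueError(
            f"all mutational pathways between {codon_a} and {codon_b} pass "
            "through stop codons"
        )
    return syn_total / n_paths, nonsyn_total / n_paths


def _jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; undefined at p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _iter_codon_pairs(a: str, b: str):
    for i in range(0, len(a), 3):
        yield a[i : i + 3], b[i : i + 3]


def kaks_pair(
    cds_a: str,
    cds_b: str,
    ids: tuple[str, str] = ("seq_a", "seq_b"),
) -> KaKsResult:
    """NG86 Ka/Ks for one aligned codon-sequence pair.

    Sequences must be equal length and a multiple of 3.  Codon columns with
    a gap, an ambiguous base or a stop codon in either sequence are dropped
    pairwise.  Site counts are averaged over the two sequences.  The ratio
    is undefined (None) when Ks == 0 or pS >= 3/4.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError(f"aligned sequences differ in length ({ids[0]} vs {ids[1]})")
    if len(cds_a) % 3 != 0:
        raise ValueError("alignment length is not a multiple of 3")

    S = N = Sd = Nd = 0.0
    n_codons = 0
    n_blocked = 0
    for ca, cb in _iter_codon_pairs(cds_a, cds_b):
        if any(base not in _BASES for base in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        try:
            sd, nd = count_substitutions_ng86(ca, cb)
        except ValueError:
            n_blocked += 1
            continue
        sa, na = count_sites_ng86(ca)
        sb, nb = count_sites_ng86(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_blocked:
        warnings.warn(
            f"{n_blocked} codon pair(s) skipped: all pathways hit stop codons",
            FormatWarning,
            stacklevel=2,
        )
    if n_codons == 0:
        raise ValueError("no comparable codons left after filtering")

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    ratio = None
    if Ks is not None and Ka is not None and Ks > 0:
        ratio = Ka / Ks

    table = [
        [round(Sd), round(Nd)],
        [round(S - Sd), round(N - Nd)],
    ]
    _, p_value = fisher_exact(table, alternative="two-sided")

    return KaKsResult(
        pair=ids,
        n_codons=n_codons,
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
        p_value=float(p_value),
    )


def back_translate_alignment(protein_aln_a: str, protein_aln_b: str,
                             cds_a: str, cds_b: str) -> tuple[str, str]:
    """Thread unaligned CDS onto an aligned protein pair (gaps -> '---')."""
    out = []
    for prot, cds in ((protein_aln_a, cds_a), (protein_aln_b, cds_b)):
        if len(cds) % 3 != 0:
            raise ValueError("CDS length not a multiple of 3")
        if len(prot) - prot.count("-") != len(cds) // 3:
            raise ValueError("protein alignment does not match CDS length")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        pieces = []
        k = 0
        for aa in prot:
            if aa == "-":
                pieces.append("---")
            else:
                pieces.append(codons[k])
                k += 1
        out.append("".join(pieces))
    return out[0], out[1]
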