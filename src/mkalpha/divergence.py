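"""Nei–Gojobori (1986) style counting of synonymous and non-synonymous
sites and substitutions for pairwise codon alignments.

Each codon position carries a fractional synonymous "site" weight given by
the proportion of its single-nucleotide mutational opportunities that are
synonymous.  Substitutions between codons differing at several positions
are averaged with equal weight over every ordering of single-nucleotide
steps that avoids stop-codon intermediates.  Site counts for a pair are the
arithmetic mean of the two sequences' compositions.

Two conventions for mutations that would create a stop codon are offered:

``exclude``
    stop mutants are removed from both numerator and denominator of the
    per-position synonymous fraction (mutational-opportunity convention,
    the default), so every position still contributes exactly one site;
``nonsyn``
    stop mutants count as non-synonymous changes out of three.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from .codons import DNA_BASES, GENETIC_CODE, is_stop, translate_codon

__all__ = [
    "SiteCounts",
    "SubstCounts",
    "GeneDivergence",
    "codon_site_composition",
    "count_substitutions",
    "gene_divergence",
    "p_distance",
    "jukes_cantor",
]


@dataclass(frozen=True)
class SiteCounts:
    """Fractional non-synonymous (N) and synonymous (S) site totals."""

    N: float
    S: float
    codons_used: int

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.N + other.N, self.S + other.S,
                          self.codons_used + other.codons_used)


@dataclass(frozen=True)
class SubstCounts:
    """Pathway-averaged substitution counts plus raw difference tallies."""

    Dn: float
    Ds: float
    nt_diffs: int
    aa_diffs: int

    def __add__(self, other: "SubstCounts") -> "SubstCounts":
        return SubstCounts(self.Dn + other.Dn, self.Ds + other.Ds,
                           self.nt_diffs + other.nt_diffs,
                           self.aa_diffs + other.aa_diffs)


class ExcludedCodon(ValueError):
    """Raised for codons that cannot be counted (stop / ambiguous / gapped)."""


def _check_countable(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in DNA_BASES for b in codon):
        raise ExcludedCodon(f"ambiguous or gapped codon {codon!r}")
    if is_stop(codon):
        raise ExcludedCodon(f"stop codon {codon!r}")
    return codon


@lru_cache(maxsize=None)
def codon_site_composition(codon: str, stop_policy: str = "exclude") -> tuple[float, float]:
    """Return ``(n_sites, s_sites)`` for one codon; ``n + s == 3`` exactly
    under the default ``exclude`` policy.

    Raises :class:`ExcludedCodon` for stop or ambiguous codons.
    """
    codon = _check_countable(codon)
    n = s = 0.0
    for pos in range(3):
        syn = 0
        opportunities = 0
        for b in DNA_BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(mutant):
                if stop_policy == "nonsyn":
                    opportunities += 1
                continue
            opportunities += 1
            if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
                syn += 1
        if stop_policy == "nonsyn":
            opportunities = 3
        if opportunities == 0:  # cannot occur with the standard code
            n += 1.0
            continue
        f_syn = syn / opportunities
        s += f_syn
        n += 1.0 - f_syn if stop_policy == "exclude" else (3 - syn) / 3
    if stop_policy == "nonsyn":
        # renormalise so a codon still spans 3 sites with stop mutants
        # counted as non-synonymous opportunities
        n = 3.0 - s
    return n, s


@lru_cache(maxsize=None)
def _pair_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (non-synonymous, synonymous) step counts over all stop-free
    single-step pathways from codon ``c1`` to ``c2``.

    Raises :class:`ExcludedCodon` when every pathway passes through a stop.
    """
    c1, c2 = _check_countable(c1), _check_countable(c2)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    totals_n = totals_s = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        path_n = path_s = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if translate_codon(nxt) == translate_codon(cur):
                path_s += 1
            else:
                path_n += 1
            cur = nxt
        if ok:
            totals_n += path_n
            totals_s += path_s
            n_paths += 1
    if n_paths == 0:
        raise ExcludedCodon(f"all pathways {c1}->{c2} pass through stop codons")
    return totals_n / n_paths, totals_s / n_paths


def count_substitutions(seq_a: str, seq_b: str, *, skipped: list | None = None) -> SubstCounts:
    """Pathway-averaged Dn/Ds over the codon columns of an aligned pair.

    Codon columns containing gaps, ambiguity codes or stop codons — and the
    rare pairs whose every mutational pathway crosses a stop — are skipped
    (their indices are appended to ``skipped`` when given).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    dn = ds = 0.0
    nt_diffs = aa_diffs = 0
    for i in range(0, len(seq_a) - len(seq_a) % 3, 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        try:
            pn, ps = _pair_path_counts(ca, cb)
        except ExcludedCodon:
            if skipped is not None:
                skipped.append(i // 3)
            continue
        dn += pn
        ds += ps
        nt_diffs += sum(a != b for a, b in zip(ca, cb))
        if translate_codon(ca) != translate_codon(cb):
            aa_diffs += 1
    return SubstCounts(dn, ds, nt_diffs, aa_diffs)


def _pair_site_counts(seq_a: str, seq_b: str, stop_policy: str = "exclude") -> SiteCounts:
    """Mean of the two sequences' site compositions over countable columns."""
    n = s = 0.0
    used = 0
    for i in range(0, len(seq_a) - len(seq_a) % 3, 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        try:
            na, sa = codon_site_composition(ca, stop_policy)
            nb, sb = codon_site_composition(cb, stop_policy)
        except ExcludedCodon:
            continue
        n += (na + nb) / 2
        s += (sa + sb) / 2
        used += 1
    return SiteCounts(n, s, used)


def p_distance(seq_a: str, seq_b: str, alphabet: str = "ACGT") -> float:
    """Uncorrected mismatch proportion over columns where both symbols are
    unambiguous members of ``alphabet`` (gaps and N excluded)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    compared = mism = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in alphabet and b in alphabet:
            compared += 1
            if a != b:
                mism += 1
    return mism / compared if compared else 0.0


def aa_distance(seq_a: str, seq_b: str) -> float:
    """Mismatch proportion between the translations of an aligned codon pair,
    over columns where both codons are unambiguous sense codons."""
    compared = mism = 0
    for i in range(0, len(seq_a) - len(seq_a) % 3, 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        try:
            _check_countable(ca)
            _check_countable(cb)
        except ExcludedCodon:
            continue
        compared += 1
        if translate_codon(ca) != translate_codon(cb):
            mism += 1
    return mism / compared if compared else 0.0


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a raw substitution proportion."""
    if p <= 0:
        return 0.0
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass(frozen=True)
class GeneDivergence:
    """Per-gene divergence summary for one trimmed codon alignment."""

    sites: SiteCounts
    subs: SubstCounts
    p_dist: float
    aa_dist: float
    dS_raw: float
    dN_raw: float
    dS_jc: float
    dN_jc: float


def gene_divergence(seq_a: str, seq_b: str, stop_policy: str = "exclude") -> GeneDivergence:
    """Site counts, pathway-averaged Dn/Ds and distance summaries for an
    aligned in-frame pair.

    dS = Ds/S and dN = Dn/N are reported both raw and Jukes–Cantor
    corrected; p-distance and amino-acid distance are uncorrected.
    Symmetric in its two arguments.
    """
    sites = _pair_site_counts(seq_a, seq_b, stop_policy)
    if sites.codons_used == 0:
        raise ExcludedCodon("no countable codons in alignment")
    subs = count_substitutions(seq_a, seq_b)
    ds_raw = subs.Ds / sites.S if sites.S > 0 else 0.0
    dn_raw = subs.Dn / sites.N if sites.N > 0 else 0.0
    return GeneDivergence(
        sites=sites,
        subs=subs,
        p_dist=p_distance(seq_a, seq_b),
        aa_dist=aa_distance(seq_a, seq_b),
        dS_raw=ds_raw,
        dN_raw=dn_raw,
        dS_jc=jukes_cantor(ds_raw),
        dN_jc=jukes_cantor(dn_raw),
    )
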