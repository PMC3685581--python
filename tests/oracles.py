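"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive and routed through Biopython's translation tables so
they share no code with the package's own codon machinery.
"""

from __future__ import annotations

import itertools
from math import comb

from Bio.Seq import Seq

DNA = "ACGT"


def bio_translate(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return bio_translate(codon) == "*"


def site_composition_enumerated(codon: str) -> tuple[float, float]:
    """(n_sites, s_sites) by enumerating all 9 single-nt mutants, stop
    mutants excluded from each position's opportunity count."""
    n = s = 0.0
    for pos in range(3):
        syn = opportunities = 0
        for b in DNA:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            opportunities += 1
            if bio_translate(mutant) == bio_translate(codon):
                syn += 1
        frac = syn / opportunities if opportunities else 0.0
        s += frac
        n += 1.0 - frac
    return n, s


def pathway_counts_enumerated(c1: str, c2: str):
    """Equal-weight (nonsyn, syn) averages over all orderings of single
    steps from c1 to c2 avoiding stop intermediates; None if no path."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, n, s = c1, 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if bio_translate(nxt) == bio_translate(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            results.append((n, s))
    if not results:
        return None
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def snp_effect_translated(codon: str, within: int, allele1: str, allele2: str) -> str:
    """silent/non-silent by translating the codon with each allele."""
    c1 = codon[:within] + allele1 + codon[within + 1 :]
    c2 = codon[:within] + allele2 + codon[within + 1 :]
    return "silent" if bio_translate(c1) == bio_translate(c2) else "non-silent"


def longest_closed_orf_scan(contig: str, min_aa: int = 30):
    """Six-frame scan for the longest ATG..stop ORF, ties by earlier
    forward start then + strand.  Returns (strand, start, end, seq) with
    1-based inclusive forward coordinates, or None."""
    contig = contig.upper()
    rc = str(Seq(contig).reverse_complement())
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for strand, work in (("+", contig), ("-", rc)):
        for frame in range(3):
            i = frame
            start = None
            while i + 3 <= len(work):
                cod = work[i : i + 3]
                if start is None and cod == "ATG":
                    start = i
                elif start is not None and cod in stops:
                    if (i - start) // 3 >= min_aa:
                        if strand == "+":
                            s, e = start + 1, i + 3
                        else:
                            s, e = len(contig) - (i + 3) + 1, len(contig) - start
                        cand = (-(i + 3 - start), s, 0 if strand == "+" else 1,
                                (strand, s, e, work[start : i + 3]))
                        if best is None or cand[:3] < best[:3]:
                            best = cand
                    start = None
                i += 3
    return best[3] if best else None


def binomial_tail(depth: int, freq: float, min_minor: int) -> float:
    """P(X >= min_minor) for X ~ Binomial(depth, freq), by direct summation."""
    return sum(comb(depth, k) * freq**k * (1 - freq) ** (depth - k)
               for k in range(min_minor, depth + 1))


def bh_stepup(pvals):
    """Benjamini–Hochberg adjusted p-values, written out by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj


def pearson_chi2_2x2(a, b, c, d) -> float:
    """Pearson χ² (no continuity correction) for [[a, b], [c, d]]."""
    n = a + b + c + d
    expected = [
        [(a + b) * (a + c) / n, (a + b) * (b + d) / n],
        [(c + d) * (a + c) / n, (c + d) * (b + d) / n],
    ]
    observed = [[a, b], [c, d]]
    return sum((observed[i][j] - expected[i][j]) ** 2 / expected[i][j]
               for i in range(2) for j in range(2))
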