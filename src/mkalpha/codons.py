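"""Standard genetic code tables and small codon utilities.

The translation table is built locally (NCBI table 1) so the counting
machinery does not depend on any external library's code tables; test
oracles translate through Biopython instead, keeping the two routes
independent.
"""

from __future__ import annotations

BASES = "TCAG"
DNA_BASES = "ACGT"

_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

#: codon -> one-letter amino acid; stop codons map to '*'
GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(BASES)
    for j, b2 in enumerate(BASES)
    for k, b3 in enumerate(BASES)
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(c for c in GENETIC_CODE if c not in STOP_CODONS)
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def translate_codon(codon: str) -> str:
    """One-letter amino acid for ``codon`` ('*' for stops, 'X' if ambiguous)."""
    return GENETIC_CODE.get(codon.upper(), "X")


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide sequence (length truncated to codons)."""
    n = len(seq) - len(seq) % 3
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, n, 3))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def codons_of(seq: str):
    """Iterate successive codons of an in-frame sequence."""
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i : i + 3]
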