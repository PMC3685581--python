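"""Pairwise codon alignments of orthologous ORFs.

Within an ortholog cluster the single best cross-species ORF pair is kept
(global protein alignment score, BLOSUM62, affine gaps), the proteins are
globally aligned and the alignment is mapped back to codons.  Alignments
are then end-trimmed by 15 nt on each side — transcript ends of pooled
454 assemblies frequently carry homopolymer frame shifts — and pairs whose
post-trim nucleotide p-distance exceeds 0.1 are discarded as residual
mis-alignments or paralogs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .codons import codons_of, is_stop
from .divergence import p_distance
from .orf import OrfRecord

__all__ = [
    "CodonAlignment",
    "make_aligner",
    "select_best_pair",
    "align_and_backtranslate",
    "trim_alignment",
    "TRIM_NT",
    "MAX_P_DISTANCE",
]

TRIM_NT = 15
MAX_P_DISTANCE = 0.1

GAP_CODON = "---"


@dataclass(frozen=True)
class CodonAlignment:
    """A length-matched pair of aligned in-frame coding sequences."""

    gene_id: str
    seq_a: str
    seq_b: str
    orf_a: str = ""
    orf_b: str = ""
    trimmed: bool = False

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("aligned length not divisible by 3")

    @property
    def aligned_length(self) -> int:
        return len(self.seq_a)

    @property
    def p_dist(self) -> float:
        return p_distance(self.seq_a, self.seq_b)


def make_aligner(open_gap: float = 10.0, extend_gap: float = 0.5) -> Align.PairwiseAligner:
    """Global protein aligner with BLOSUM62 scoring and affine gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


class TranslationError(ValueError):
    """ORF does not translate cleanly (internal stop or partial codon)."""


def _protein_or_raise(orf: OrfRecord) -> str:
    cds = orf.coding_sequence
    if len(cds) % 3:
        raise TranslationError(f"{orf.contig_id}: coding length not a codon multiple")
    prot = orf.protein
    if "*" in prot:
        raise TranslationError(f"{orf.contig_id}: internal stop codon")
    if not prot:
        raise TranslationError(f"{orf.contig_id}: empty translation")
    return prot


def select_best_pair(
    orfs_a: Sequence[OrfRecord],
    orfs_b: Sequence[OrfRecord],
    aligner: Optional[Align.PairwiseAligner] = None,
    metric: str = "score",
) -> Optional[tuple[OrfRecord, OrfRecord]]:
    """Pick the cross-species ORF pair with the highest protein similarity.

    ``metric`` is the global alignment ``"score"`` (default) or percent
    ``"identity"``.  Ties go to the longer summed ORF length, then to the
    lexicographically smallest id pair.  Returns ``None`` when either
    species is absent from the cluster.
    """
    if not orfs_a or not orfs_b:
        return None
    aligner = aligner or make_aligner()
    candidates = []
    for oa, ob in itertools.product(orfs_a, orfs_b):
        try:
            pa, pb = _protein_or_raise(oa), _protein_or_raise(ob)
        except TranslationError:
            continue
        if metric == "identity":
            aln = aligner.align(pa, pb)[0]
            a_row, b_row = str(aln[0]), str(aln[1])
            ident = sum(x == y for x, y in zip(a_row, b_row) if x != "-" and y != "-")
            compared = sum(1 for x, y in zip(a_row, b_row) if x != "-" and y != "-")
            value = ident / compared if compared else 0.0
        else:
            value = aligner.score(pa, pb)
        candidates.append(
            (-value, -(len(oa.sequence) + len(ob.sequence)),
             (oa.contig_id, ob.contig_id), (oa, ob))
        )
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[:3])
    return candidates[0][3]


def align_and_backtranslate(
    orf_a: OrfRecord,
    orf_b: OrfRecord,
    gene_id: str = "",
    aligner: Optional[Align.PairwiseAligner] = None,
) -> CodonAlignment:
    """Globally align the two ORF proteins and map the alignment back to
    codons, so every aligned residue column becomes one codon column and
    every gap becomes ``---``.

    Raises :class:`TranslationError` when an ORF does not translate.
    """
    pa, pb = _protein_or_raise(orf_a), _protein_or_raise(orf_b)
    aligner = aligner or make_aligner()
    aln = aligner.align(pa, pb)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    cod_a = list(codons_of(orf_a.coding_sequence))
    cod_b = list(codons_of(orf_b.coding_sequence))
    out_a, out_b = [], []
    ia = ib = 0
    for ra, rb in zip(row_a, row_b):
        if ra == "-":
            out_a.append(GAP_CODON)
        else:
            out_a.append(cod_a[ia])
            ia += 1
        if rb == "-":
            out_b.append(GAP_CODON)
        else:
            out_b.append(cod_b[ib])
            ib += 1
    return CodonAlignment(
        gene_id=gene_id or f"{orf_a.contig_id}|{orf_b.contig_id}",
        seq_a="".join(out_a),
        seq_b="".join(out_b),
        orf_a=orf_a.contig_id,
        orf_b=orf_b.contig_id,
        trimmed=False,
    )


def trim_alignment(
    aln: CodonAlignment,
    trim_nt: int = TRIM_NT,
    max_p_distance: float = MAX_P_DISTANCE,
) -> Optional[CodonAlignment]:
    """End-trim and divergence-filter a raw codon alignment.

    Removes ``trim_nt`` columns from each end, snapping inward to the next
    codon boundary, and returns ``None`` when no complete codon survives or
    the post-trim p-distance is strictly above ``max_p_distance``
    (a pair at exactly the threshold is retained).  Applied once per
    alignment: a second application would remove a further 2×``trim_nt``.
    """
    lo = 3 * ((trim_nt + 2) // 3)  # snap inward
    hi = len(aln.seq_a) - lo
    if hi - lo < 3:
        return None
    trimmed = replace(aln, seq_a=aln.seq_a[lo:hi], seq_b=aln.seq_b[lo:hi], trimmed=True)
    # drop codon columns that are now all-gap in either sequence? keep: gap
    # columns are ignored by downstream counting.
    if trimmed.p_dist > max_p_distance:
        return None
    if all(is_stop(c) or c == GAP_CODON for c in codons_of(trimmed.seq_a)):
        return None
    return trimmed
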