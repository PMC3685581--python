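"""Open-reading-frame extraction from transcript contigs.

Two modes mirror how transcriptome contigs are usually handled when only a
fraction carries a protein homology hit:

* **anchored** — a frame/strand hint (e.g. from a protein database search)
  is given; the ORF is the maximal in-frame, stop-free extension through
  the anchored frame and may be open at either end;
* **de novo** — no hint; the longest *closed* ORF (ATG .. stop, no internal
  stop) of at least 30 amino acids is taken across both strands and all
  six frames, ties broken by earlier start on the forward contig, then by
  the + strand.

The reported sequence of a closed ORF includes its terminal stop codon;
the amino-acid minimum counts coding codons only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .codons import START_CODON, is_stop, reverse_complement, translate

__all__ = ["OrfRecord", "Anchor", "predict_orf", "MIN_ORF_AA"]

MIN_ORF_AA = 30
_VALID = set("ACGTN")


@dataclass(frozen=True)
class OrfRecord:
    """An in-frame coding region located on a contig.

    ``start``/``end`` are 1-based inclusive coordinates on the *forward*
    contig; ``sequence`` reads 5'→3' on ``strand`` (it equals the reverse
    complement of the forward slice when ``strand == '-'``).
    """

    contig_id: str
    strand: str
    start: int
    end: int
    sequence: str
    anchored: bool = False
    closed: bool = True

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    @property
    def coding_sequence(self) -> str:
        """Sequence without the terminal stop codon, if one is included."""
        if len(self.sequence) >= 3 and is_stop(self.sequence[-3:]):
            return self.sequence[:-3]
        return self.sequence

    @property
    def protein(self) -> str:
        return translate(self.coding_sequence)


@dataclass(frozen=True)
class Anchor:
    """Frame/strand hint for anchored ORF extraction.

    ``frame`` is 0–2 on the reading of ``strand``; ``position`` (optional,
    1-based forward coordinate) selects the stop-free codon run containing
    it when a frame holds several runs — otherwise the longest run is used.
    """

    strand: str = "+"
    frame: int = 0
    position: Optional[int] = None


def _validate(contig: str) -> str:
    contig = contig.upper()
    bad = set(contig) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN characters in contig: {sorted(bad)}")
    return contig


def _forward_coords(strand: str, contig_len: int, off0: int, off1: int) -> tuple[int, int]:
    """Map a 0-based [off0, off1) slice of the working strand to 1-based
    inclusive forward-contig coordinates."""
    if strand == "+":
        return off0 + 1, off1
    return contig_len - off1 + 1, contig_len - off0


def _closed_orfs(working: str, strand: str, contig_len: int, min_aa: int) -> Iterable[tuple]:
    """Yield (length_nt, fwd_start, strand_rank, record_args) for every
    closed ORF of the three frames of one strand of ``working``."""
    strand_rank = 0 if strand == "+" else 1
    for frame in range(3):
        start_at: Optional[int] = None
        i = frame
        while i + 3 <= len(working):
            codon = working[i : i + 3]
            if start_at is None:
                if codon == START_CODON:
                    start_at = i
            elif is_stop(codon):
                aa = (i - start_at) // 3
                if aa >= min_aa:
                    s, e = _forward_coords(strand, contig_len, start_at, i + 3)
                    yield (i + 3 - start_at, s, strand_rank,
                           (strand, s, e, working[start_at : i + 3]))
                start_at = None
            i += 3
    return


def _denovo(contig: str, contig_id: str, min_aa: int) -> Optional[OrfRecord]:
    candidates = []
    for strand, working in (("+", contig), ("-", reverse_complement(contig))):
        candidates.extend(_closed_orfs(working, strand, len(contig), min_aa))
    if not candidates:
        return None
    # longest; then earliest forward start; then + strand
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    strand, s, e, seq = candidates[0][3]
    return OrfRecord(contig_id, strand, s, e, seq, anchored=False, closed=True)


def _anchored(contig: str, contig_id: str, anchor: Anchor) -> Optional[OrfRecord]:
    working = contig if anchor.strand == "+" else reverse_complement(contig)
    frame = anchor.frame % 3
    runs = []  # (off0, off1_coding, has_terminal_stop)
    run_start = None
    i = frame
    while i + 3 <= len(working):
        if is_stop(working[i : i + 3]):
            if run_start is not None:
                runs.append((run_start, i, True))
                run_start = None
        elif run_start is None:
            run_start = i
        i += 3
    if run_start is not None:
        runs.append((run_start, i, False))
    if not runs:
        return None
    chosen = None
    if anchor.position is not None:
        for off0, off1, has_stop in runs:
            end_off = off1 + (3 if has_stop else 0)
            s, e = _forward_coords(anchor.strand, len(contig), off0, end_off)
            if s <= anchor.position <= e:
                chosen = (off0, off1, has_stop)
                break
    if chosen is None:
        chosen = max(runs, key=lambda r: r[1] - r[0])
    off0, off1, has_stop = chosen
    end_off = off1 + (3 if has_stop else 0)
    if end_off - off0 < 3:
        return None
    s, e = _forward_coords(anchor.strand, len(contig), off0, end_off)
    seq = working[off0:end_off]
    closed = has_stop and seq.startswith(START_CODON)
    return OrfRecord(contig_id, anchor.strand, s, e, seq, anchored=True, closed=closed)


def predict_orf(
    contig: str,
    contig_id: str = "contig",
    anchor: Optional[Anchor] = None,
    min_aa: int = MIN_ORF_AA,
) -> Optional[OrfRecord]:
    """Extract the coding frame of a transcript contig.

    With ``anchor`` the stop-free codon run through the hinted frame is
    returned (open ends allowed); without it the longest closed ORF of at
    least ``min_aa`` amino acids over all six frames is returned, or
    ``None`` if there is none.
    """
    contig = _validate(contig)
    if len(contig) < 3 or set(contig) == {"N"}:
        return None
    if anchor is not None:
        return _anchored(contig, contig_id, anchor)
    return _denovo(contig, contig_id, min_aa)
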