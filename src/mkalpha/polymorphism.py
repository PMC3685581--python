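"""SNP calling from pooled-sample pileups, silent/non-silent classification
and per-gene pooling.

Reads from a pool of many individuals are summarised per position as
allele counts; allele frequencies are therefore plug-in read proportions,
never genotypes.  A diallelic SNP is accepted only if it passes ALL of the
conjunctive quality filters (defaults):

* mapping depth >= 10,
* exactly two alleles observed (triallelic columns are rejected outright),
* the rarer allele observed >= 2 times,
* SNP quality score >= 20,
* at most 3 bases in the +-3 neighbourhood with quality < 15.

SNPs inside an ORF are silent when both alleles encode the same amino
acid.  Rarer-allele frequencies are binned into low (< 5%), moderate
(5–15%) and common (15–50%) classes; the lower class boundaries are
half-open ([0.05, 0.15)) and the common class is closed at 0.5.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Iterator, Optional, Tuple

from scipy.stats import binom

from .codons import DNA_BASES, translate_codon, reverse_complement
from .orf import OrfRecord

__all__ = [
    "PileupColumn",
    "SnpRecord",
    "SnpFilters",
    "read_pileup",
    "write_pileup",
    "call_snps",
    "classify_snp",
    "bin_by_frequency",
    "pool_gene_counts",
    "detection_probability",
    "PILEUP_COLUMNS",
]

log = logging.getLogger(__name__)

PILEUP_COLUMNS = [
    "contig", "pos", "ref_base", "depth",
    "countA", "countC", "countG", "countT",
    "base_quality_min", "neighborhood_low_quality_count",
]

FREQ_CLASSES = ("low", "moderate", "common")


@dataclass(frozen=True)
class PileupColumn:
    """One position of a pooled-read pileup (1-based coordinates)."""

    contig_id: str
    pos: int
    ref_base: str
    counts: Tuple[int, int, int, int]  # A, C, G, T
    snp_quality: float
    neighborhood_low_q: int

    @property
    def depth(self) -> int:
        return sum(self.counts)

    def count_of(self, base: str) -> int:
        return self.counts[DNA_BASES.index(base)]


@dataclass(frozen=True)
class SnpRecord:
    """A diallelic polymorphic site that passed all filters."""

    contig_id: str
    pos: int
    major_allele: str
    minor_allele: str
    minor_count: int
    depth: int
    species: str = ""
    effect: str = "outside_orf"  # silent | non-silent | outside_orf
    in_orf: bool = False

    @property
    def minor_freq(self) -> float:
        return self.minor_count / self.depth

    @property
    def freq_class(self) -> str:
        return bin_by_frequency(self.minor_freq)


@dataclass(frozen=True)
class SnpFilters:
    """The conjunctive pooled-SNP acceptance filters."""

    min_depth: int = 10
    min_minor_count: int = 2
    min_quality: float = 20.0
    max_low_q_neighbors: int = 3


class PileupParseError(ValueError):
    def __init__(self, line_no: int, message: str):
        super().__init__(f"pileup line {line_no}: {message}")
        self.line_no = line_no


def read_pileup(path, errors: Optional[list] = None) -> Iterator[PileupColumn]:
    """Stream a pileup TSV; malformed lines are reported (appended to
    ``errors`` or logged) and skipped, the stream continues."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != PILEUP_COLUMNS:
            raise ValueError(f"{path}: not a pileup TSV (bad header)")
        for line_no, row in enumerate(reader, start=2):
            try:
                counts = tuple(int(x) for x in row[4:8])
                depth = int(row[3])
                if depth != sum(counts):
                    raise ValueError("depth != sum of allele counts")
                yield PileupColumn(
                    contig_id=row[0],
                    pos=int(row[1]),
                    ref_base=row[2],
                    counts=counts,  # type: ignore[arg-type]
                    snp_quality=float(row[8]),
                    neighborhood_low_q=int(row[9]),
                )
            except (ValueError, IndexError) as exc:
                err = PileupParseError(line_no, str(exc))
                if errors is not None:
                    errors.append(err)
                else:
                    log.warning("%s", err)


def write_pileup(path, columns: Iterable[PileupColumn]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PILEUP_COLUMNS)
        for c in columns:
            writer.writerow([
                c.contig_id, c.pos, c.ref_base, c.depth, *c.counts,
                f"{c.snp_quality:g}", c.neighborhood_low_q,
            ])


def call_snps(
    columns: Iterable[PileupColumn],
    filters: SnpFilters = SnpFilters(),
    species: str = "",
) -> Iterator[SnpRecord]:
    """Emit a :class:`SnpRecord` for every column passing all filters.

    The filters are conjunctive, so their order of application cannot
    change the emitted set.
    """
    for col in columns:
        nonzero = [(n, b) for n, b in zip(col.counts, DNA_BASES) if n > 0]
        if len(nonzero) != 2:
            continue
        if col.depth < filters.min_depth:
            continue
        nonzero.sort(key=lambda nb: (-nb[0], nb[1]))
        (major_n, major_b), (minor_n, minor_b) = nonzero
        if minor_n < filters.min_minor_count:
            continue
        if col.snp_quality < filters.min_quality:
            continue
        if col.neighborhood_low_q > filters.max_low_q_neighbors:
            continue
        yield SnpRecord(
            contig_id=col.contig_id,
            pos=col.pos,
            major_allele=major_b,
            minor_allele=minor_b,
            minor_count=minor_n,
            depth=col.depth,
            species=species,
        )


def classify_snp(snp: SnpRecord, orf: Optional[OrfRecord]) -> SnpRecord:
    """Attach the silent/non-silent effect of a SNP within its host ORF.

    The two observed alleles are substituted into the ORF codon covering
    the position (strand-aware); the SNP is silent iff both codons encode
    the same amino acid.  Positions outside the ORF get
    ``effect='outside_orf'``; codons containing N raise
    :class:`AmbiguousCodon` so callers can exclude and log them.
    """
    if orf is None or not (orf.start <= snp.pos <= orf.end):
        return replace(snp, effect="outside_orf", in_orf=False)
    if orf.strand == "+":
        idx = snp.pos - orf.start
        major, minor = snp.major_allele, snp.minor_allele
    else:
        idx = orf.end - snp.pos
        major = reverse_complement(snp.major_allele)
        minor = reverse_complement(snp.minor_allele)
    codon_i, within = divmod(idx, 3)
    codon = orf.sequence[3 * codon_i : 3 * codon_i + 3]
    if len(codon) < 3:
        return replace(snp, effect="outside_orf", in_orf=False)
    if "N" in codon.upper():
        raise AmbiguousCodon(f"{snp.contig_id}:{snp.pos}: codon contains N")
    cod_major = codon[:within] + major + codon[within + 1 :]
    cod_minor = codon[:within] + minor + codon[within + 1 :]
    effect = "silent" if translate_codon(cod_major) == translate_codon(cod_minor) else "non-silent"
    return replace(snp, effect=effect, in_orf=True)


class AmbiguousCodon(ValueError):
    """SNP falls in a codon containing N/gap; effect is undefined."""


def bin_by_frequency(minor_freq: float) -> str:
    """Frequency class of a rarer-allele frequency in (0, 0.5]."""
    if not 0 < minor_freq <= 0.5:
        raise ValueError(f"minor allele frequency {minor_freq} outside (0, 0.5]")
    if minor_freq < 0.05:
        return "low"
    if minor_freq < 0.15:
        return "moderate"
    return "common"


def pool_gene_counts(
    snps: Iterable[SnpRecord],
    gene_of_contig: Dict[str, str],
    exclusion: str = "none",
) -> Dict[str, Tuple[int, int]]:
    """Sum silent/non-silent SNP counts per gene across species.

    ``exclusion`` drops frequency classes before summing: ``"none"``,
    ``"low"`` (drop SNPs with rarer-allele frequency < 5%) or
    ``"low_moderate"`` (drop < 15%).  Returns gene_id -> (Pn, Ps); only
    in-ORF SNPs with a defined effect contribute.
    """
    dropped = {
        "none": (),
        "low": ("low",),
        "low_moderate": ("low", "moderate"),
    }[exclusion]
    out: Dict[str, list] = {}
    for snp in snps:
        if not snp.in_orf or snp.effect not in ("silent", "non-silent"):
            continue
        if snp.freq_class in dropped:
            continue
        gene = gene_of_contig.get(snp.contig_id)
        if gene is None:
            continue
        pn_ps = out.setdefault(gene, [0, 0])
        if snp.effect == "non-silent":
            pn_ps[0] += 1
        else:
            pn_ps[1] += 1
    return {g: (pn, ps) for g, (pn, ps) in out.items()}


def detection_probability(depth: int, freq: float, min_minor: int = 2) -> float:
    """Probability that a segregating allele at population frequency
    ``freq`` is read at least ``min_minor`` times in a pool sequenced to
    ``depth`` — i.e. the binomial upper tail P(X >= min_minor),
    X ~ Binomial(depth, freq)."""
    if freq <= 0:
        return 0.0
    if depth < 1:
        return 0.0
    return float(binom.sf(min_minor - 1, depth, freq))
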