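"""Synthetic ortholog pairs, pooled polymorphism and pileups with known
ground truth.

The generator emulates the data model of a two-species larval
transcriptome comparison between closely related midges: pairs of
orthologous ORFs diverged ~1.5% at the nucleotide level, within-species
polymorphism sampled from a pool of 60 diploid individuals, and pooled
reads at moderate coverage with ~1% substitution error.

Model (per gene):

* an ancestral in-frame ORF (ATG + random sense codons + stop) embedded
  in short C/G/T-only UTRs (so no spurious ATG can displace the ORF);
* fixed differences placed codon-aware on one of the two lineages, at
  most one mutational hit per codon (a good approximation at ~1.5%
  divergence) and never creating a stop codon.  A substitution is
  synonymous with probability 1/(1+r'), r' = r/(1-a), where r is the
  neutral non-synonymous:synonymous ratio shared with polymorphism and
  a is the adaptive fraction — adaptive fixations add non-synonymous
  divergence on top of the neutral ratio, so the aggregate α estimator
  is consistent (E[α̂] ≈ a);
* independent diallelic SNPs per species with rarer-allele frequencies
  drawn from a folded neutral (∝ 1/i) spectrum on a pool of 2×60
  chromosomes; an optional slightly-deleterious non-synonymous class is
  constrained to frequencies below 15%;
* pooled pileups with Poisson depth, binomial allele sampling at SNP
  sites and uniform substitution-only sequencing error.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .codons import DNA_BASES, GENETIC_CODE, SENSE_CODONS, STOP_CODONS, is_stop
from .polymorphism import PileupColumn

log = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SubstitutionTruth",
    "SnpTruth",
    "GenePair",
    "neutral_folded_spectrum",
    "simulate_ortholog_pair",
    "simulate_genes",
    "simulate_pileup",
    "simulate_dataset",
    "true_alpha",
]


def _single_nt_changes() -> dict:
    """codon -> {'syn': [(pos, base)...], 'nonsyn': [...]}, stops excluded."""
    table = {}
    for codon in SENSE_CODONS:
        syn, nonsyn = [], []
        for pos in range(3):
            for b in DNA_BASES:
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1 :]
                if is_stop(mutant):
                    continue
                (syn if GENETIC_CODE[mutant] == GENETIC_CODE[codon] else nonsyn).append((pos, b))
        table[codon] = {"syn": syn, "nonsyn": nonsyn}
    return table


_CHANGES = _single_nt_changes()
_STOPS = tuple(sorted(STOP_CODONS))


def neutral_folded_spectrum(n_chromosomes: int = 120) -> Tuple[np.ndarray, np.ndarray]:
    """Discretised neutral 1/i allele-frequency spectrum folded to (0, 0.5].

    Returns (frequencies, probabilities) over rarer-allele counts
    i = 1 .. n/2 on a pool of ``n_chromosomes`` chromosomes, with folded
    weight 1/i + 1/(n-i) (halved at i = n/2).
    """
    n = n_chromosomes
    i = np.arange(1, n // 2 + 1)
    w = 1.0 / i + 1.0 / (n - i)
    if n % 2 == 0:
        w[-1] = 1.0 / i[-1]
    return i / n, w / w.sum()


@dataclass
class SimConfig:
    """Study conditions for the synthetic transcriptome pair.

    Defaults mirror the two-midge comparison the pipeline targets:
    ~1.53% nucleotide divergence, an adaptive amino-acid substitution
    fraction of 0.25, pooled sequencing of 60 diploid individuals per
    species, ~1% per-base substitution error, and mean gene length of
    134 codons (~402 bp alignments).  ``n_genes`` defaults to a
    desk-scale 2,000 genes.
    """

    n_genes: int = 2000
    mean_len_codons: int = 134
    divergence_target: float = 0.0153
    adaptive_fraction: float = 0.25
    rate_shape: float = 0.6
    theta: float = 0.006
    nonsyn_syn_ratio: float = 1.1
    deleterious_fraction: float = 0.0
    pool_chromosomes: int = 120
    allele_freq_spectrum: Optional[Tuple[Sequence[float], Sequence[float]]] = None
    coverage_mean: float = 30.0
    error_rate: float = 0.01
    quality_dropout: float = 0.02
    utr_len_range: Tuple[int, int] = (20, 60)
    seed: int = 0

    def validate(self) -> "SimConfig":
        for name in ("divergence_target", "adaptive_fraction", "theta",
                     "deleterious_fraction", "error_rate", "quality_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.divergence_target == 0 and self.adaptive_fraction > 0:
            raise ValueError("adaptive_fraction > 0 requires divergence_target > 0")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if self.mean_len_codons < 30:
            raise ValueError("mean_len_codons must be >= 30")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.nonsyn_syn_ratio <= 0:
            raise ValueError("nonsyn_syn_ratio must be > 0")
        if self.rate_shape < 0:
            raise ValueError("rate_shape must be >= 0 (0 disables rate variation)")
        if self.adaptive_fraction >= 1.0 and self.divergence_target > 0:
            raise ValueError("adaptive_fraction must be < 1")
        return self

    def spectrum(self) -> Tuple[np.ndarray, np.ndarray]:
        if self.allele_freq_spectrum is not None:
            f = np.asarray(self.allele_freq_spectrum[0], dtype=float)
            w = np.asarray(self.allele_freq_spectrum[1], dtype=float)
            if np.any(f <= 0) or np.any(f > 0.5):
                raise ValueError("spectrum frequencies must lie in (0, 0.5]")
            return f, w / w.sum()
        return neutral_folded_spectrum(self.pool_chromosomes)


@dataclass(frozen=True)
class SubstitutionTruth:
    """One fixed difference between the two lineages."""

    gene_id: str
    lineage: str  # 'a' | 'b'
    pos: int  # 1-based on the contig (both contigs share coordinates)
    codon_index: int
    cls: str  # 'syn' | 'nonsyn'
    adaptive: bool


@dataclass(frozen=True)
class SnpTruth:
    """One segregating site within one species."""

    gene_id: str
    species: str  # 'a' | 'b'
    contig_id: str
    pos: int  # 1-based on the contig
    major_allele: str
    minor_allele: str
    minor_freq: float
    cls: str  # 'silent' | 'non-silent'
    deleterious: bool

    @property
    def freq_class(self) -> str:
        if self.minor_freq < 0.05:
            return "low"
        if self.minor_freq < 0.15:
            return "moderate"
        return "common"


@dataclass
class GenePair:
    """A simulated ortholog pair plus its truth rows."""

    gene_id: str
    contig_a: str
    contig_b: str
    utr5_len: int
    cds_len: int  # nt, including the stop codon
    substitutions: List[SubstitutionTruth] = field(default_factory=list)
    snps: List[SnpTruth] = field(default_factory=list)

    @property
    def contig_id_a(self) -> str:
        return f"{self.gene_id}_a"

    @property
    def contig_id_b(self) -> str:
        return f"{self.gene_id}_b"

    @property
    def cds_a(self) -> str:
        return self.contig_a[self.utr5_len : self.utr5_len + self.cds_len]

    @property
    def cds_b(self) -> str:
        return self.contig_b[self.utr5_len : self.utr5_len + self.cds_len]

    def truth_counts(self) -> dict:
        dn = sum(1 for s in self.substitutions if s.cls == "nonsyn")
        ds = sum(1 for s in self.substitutions if s.cls == "syn")
        pn = sum(1 for s in self.snps if s.cls == "non-silent")
        ps = sum(1 for s in self.snps if s.cls == "silent")
        adaptive = sum(1 for s in self.substitutions if s.adaptive)
        return {"gene_id": self.gene_id, "Dn": dn, "Ds": ds, "Pn": pn,
                "Ps": ps, "adaptive_Dn": adaptive}


def _random_coding(rng: np.random.Generator, n_codons: int) -> list:
    codons = ["ATG"]
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    codons.extend(SENSE_CODONS[i] for i in idx)
    return codons


def _draw_change(rng: np.random.Generator, codon: str, cls: str):
    options = _CHANGES[codon][cls]
    if not options:
        return None
    return options[rng.integers(0, len(options))]


def simulate_ortholog_pair(config: SimConfig, gene_index: int) -> GenePair:
    """Simulate one gene: ancestral ORF, lineage-specific fixed
    differences, per-species SNPs, contigs with UTRs.

    Deterministic in ``(config.seed, gene_index)``.
    """
    config.validate()
    rng = np.random.default_rng([abs(config.seed), gene_index])
    gene_id = f"gene{gene_index:05d}"

    n_codons = max(30, int(rng.poisson(config.mean_len_codons)))
    coding = _random_coding(rng, n_codons)
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    len5, len3 = rng.integers(config.utr_len_range[0], config.utr_len_range[1] + 1, size=2)
    utr_bases = "CGT"
    utr5 = "".join(utr_bases[i] for i in rng.integers(0, 3, size=len5))
    utr3 = "".join(utr_bases[i] for i in rng.integers(0, 3, size=len3))

    coding_a = list(coding)
    coding_b = list(coding)
    touched = set()  # codon indices carrying any mutation, ATG excluded below
    mutable = list(range(1, n_codons))

    subs: List[SubstitutionTruth] = []
    n_nt = 3 * n_codons
    # among-gene rate variation: Gamma(shape, mean 1) multiplier, so the
    # divergence distribution is overdispersed (many near-identical genes,
    # a long tail) while its mean stays at divergence_target
    gene_rate = config.divergence_target
    if config.rate_shape > 0:
        gene_rate *= rng.gamma(config.rate_shape, 1.0 / config.rate_shape)
    n_sub = rng.binomial(n_nt, min(1.0, gene_rate))
    a = config.adaptive_fraction
    r_div = config.nonsyn_syn_ratio / (1.0 - a) if a < 1 else np.inf
    p_nonsyn_div = r_div / (1.0 + r_div)

    def place(cls: str):
        """Pick an untouched codon offering a change of class ``cls``."""
        for _ in range(200):
            k = mutable[rng.integers(0, len(mutable))]
            if k in touched:
                continue
            change = _draw_change(rng, coding[k], cls)
            if change is not None:
                touched.add(k)
                return k, change
        return None

    for _ in range(n_sub):
        cls = "nonsyn" if rng.random() < p_nonsyn_div else "syn"
        placed = place(cls)
        if placed is None:
            break
        k, (pos, base) = placed
        lineage = "a" if rng.random() < 0.5 else "b"
        target = coding_a if lineage == "a" else coding_b
        target[k] = target[k][:pos] + base + target[k][pos + 1 :]
        adaptive = cls == "nonsyn" and rng.random() < a
        subs.append(SubstitutionTruth(gene_id, lineage, len5 + 3 * k + pos + 1,
                                      k, cls, adaptive))

    # polymorphism: independent sites per species
    freqs, probs = config.spectrum()
    low_mask = freqs < 0.15
    phi = config.nonsyn_syn_ratio / (1.0 + config.nonsyn_syn_ratio)
    f_del = config.deleterious_fraction
    p_del = f_del * phi / (1.0 - f_del + f_del * phi) if f_del > 0 else 0.0

    snps: List[SnpTruth] = []
    for species, coding_sp in (("a", coding_a), ("b", coding_b)):
        n_snp = rng.binomial(n_nt, config.theta)
        for _ in range(n_snp):
            u = rng.random()
            if u < p_del:
                cls, deleterious = "nonsyn", True
            elif u < p_del + (1.0 - p_del) * phi:
                cls, deleterious = "nonsyn", False
            else:
                cls, deleterious = "syn", False
            placed = place(cls)
            if placed is None:
                break
            k, (pos, base) = placed
            major = coding_sp[k][pos]
            if deleterious:
                w = probs * low_mask
                freq = float(rng.choice(freqs, p=w / w.sum()))
            else:
                freq = float(rng.choice(freqs, p=probs))
            snps.append(SnpTruth(
                gene_id, species, f"{gene_id}_{species}",
                len5 + 3 * k + pos + 1, major, base, freq,
                "non-silent" if cls == "nonsyn" else "silent", deleterious))

    contig_a = utr5 + "".join(coding_a) + stop + utr3
    contig_b = utr5 + "".join(coding_b) + stop + utr3
    return GenePair(gene_id, contig_a, contig_b, int(len5),
                    3 * (n_codons + 1), subs, snps)


def simulate_genes(config: SimConfig) -> Iterator[GenePair]:
    """Yield all ``config.n_genes`` simulated ortholog pairs."""
    config.validate()
    for i in range(config.n_genes):
        yield simulate_ortholog_pair(config, i)


def gene_counts_from_simulation(gene: GenePair, exclusion: str = "none"):
    """Estimator-ready per-gene counts for a simulated ortholog pair.

    Dn/Ds are counted from the emitted coding sequences with the package's
    pathway-averaged counting; Pn/Ps come from the gene's segregating
    sites, after dropping the requested rarer-allele frequency classes
    (``none`` / ``low`` / ``low_moderate``).
    """
    from .divergence import count_substitutions, _pair_site_counts
    from .selection import GeneCounts

    dropped = {"none": (), "low": ("low",),
               "low_moderate": ("low", "moderate")}[exclusion]
    subs = count_substitutions(gene.cds_a, gene.cds_b)
    sites = _pair_site_counts(gene.cds_a, gene.cds_b)
    kept = [s for s in gene.snps if s.freq_class not in dropped]
    pn = sum(1 for s in kept if s.cls == "non-silent")
    ps = sum(1 for s in kept if s.cls == "silent")
    return GeneCounts(gene.gene_id, subs.Dn, subs.Ds, pn, ps,
                      N=sites.N, S=sites.S)


def true_alpha(genes: Sequence[GenePair]) -> float:
    """Realised adaptive fraction: adaptive / all non-synonymous fixations."""
    dn = adaptive = 0
    for g in genes:
        for s in g.substitutions:
            if s.cls == "nonsyn":
                dn += 1
                adaptive += s.adaptive
    return adaptive / dn if dn else float("nan")


_BASE_IDX = {b: i for i, b in enumerate(DNA_BASES)}


def simulate_pileup(
    sequence: str,
    snps: Sequence[SnpTruth],
    coverage_mean: float,
    error_rate: float,
    seed,
    contig_id: str = "contig",
    quality_dropout: float = 0.02,
) -> List[PileupColumn]:
    """Pooled-read pileup columns over one contig.

    Depth is Poisson(``coverage_mean``); at SNP positions the rarer-allele
    read count is Binomial(depth, true frequency); every read base is then
    substituted with probability ``error_rate`` to a uniformly chosen
    other base.

    Base-call errors carry low quality in real data — that correlation is
    what makes the downstream quality filter informative — so the emitted
    column quality (the minimum quality of the reads supporting the rarer
    allele) is high (25–40) for genuine alleles apart from a
    ``quality_dropout`` fraction of low-quality columns, while a rarer
    allele supported *only* by error reads draws a low quality (5–19)
    with probability 1 − 0.1^k for k error reads.  The neighbourhood
    counter reports low-quality columns within ±3 positions.
    """
    L = len(sequence)
    if coverage_mean <= 0:
        warnings.warn("coverage_mean <= 0: empty pileup emitted")
        return []
    rng = np.random.default_rng(seed)
    depth = rng.poisson(coverage_mean, size=L)
    genuine = np.zeros((L, 4), dtype=np.int64)
    base_idx = np.fromiter((_BASE_IDX.get(b, 0) for b in sequence.upper()),
                           dtype=np.int64, count=L)
    genuine[np.arange(L), base_idx] = depth
    for snp in snps:
        i = snp.pos - 1
        if not 0 <= i < L:
            raise ValueError(f"SNP position {snp.pos} outside sequence")
        d = depth[i]
        m = rng.binomial(d, snp.minor_freq)
        genuine[i, :] = 0
        genuine[i, _BASE_IDX[snp.major_allele]] = d - m
        genuine[i, _BASE_IDX[snp.minor_allele]] = m
    err_in = np.zeros((L, 4), dtype=np.int64)
    if error_rate > 0:
        err_out = rng.binomial(genuine, error_rate)
        genuine -= err_out
        for j in range(4):
            others = [k for k in range(4) if k != j]
            dest = rng.multinomial(err_out[:, j], [1 / 3] * 3)
            for col, k in enumerate(others):
                err_in[:, k] += dest[:, col]
    counts = genuine + err_in
    low = rng.random(L) < quality_dropout
    qual = rng.integers(25, 41, size=L)
    qual[low] = rng.integers(5, 20, size=int(low.sum()))
    # columns whose rarer allele rests on error reads alone read low quality
    order = np.argsort(counts, axis=1, kind="stable")
    multi = (counts > 0).sum(axis=1) >= 2
    for i in np.nonzero(multi)[0]:
        minor = order[i, -2]
        if genuine[i, minor] == 0:
            k = int(err_in[i, minor])
            if rng.random() > 0.1 ** k:
                qual[i] = rng.integers(5, 20)
                low[i] = qual[i] < 15
    kernel = np.ones(7, dtype=np.int64)
    nb = np.convolve(low.astype(np.int64), kernel, mode="same") - low
    return [
        PileupColumn(contig_id, i + 1, sequence[i],
                     tuple(int(c) for c in counts[i]),
                     float(qual[i]), int(nb[i]))
        for i in range(L)
    ]


def _fasta_write(path: Path, records: Sequence[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def simulate_dataset(config: SimConfig, outdir) -> dict:
    """Simulate the full two-species dataset and write it to ``outdir``.

    Writes per-species contig FASTA and pileup TSV, a cluster map, truth
    tables (substitutions, SNPs, per-gene counts) and the configuration.
    Returns a small summary dict (paths and totals).
    """
    import pandas as pd

    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = list(simulate_genes(config))

    _fasta_write(outdir / "species_a.fasta",
                 [(g.contig_id_a, g.contig_a) for g in genes])
    _fasta_write(outdir / "species_b.fasta",
                 [(g.contig_id_b, g.contig_b) for g in genes])

    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tspecies\tcontig_id\n")
        for g in genes:
            fh.write(f"{g.gene_id}\ta\t{g.contig_id_a}\n")
            fh.write(f"{g.gene_id}\tb\t{g.contig_id_b}\n")

    for species in ("a", "b"):
        path = outdir / f"pileup_{species}.tsv"
        with open(path, "w", newline="") as fh:
            fh.write("\t".join(
                ["contig", "pos", "ref_base", "depth", "countA", "countC",
                 "countG", "countT", "base_quality_min",
                 "neighborhood_low_quality_count"]) + "\n")
        all_cols: List[PileupColumn] = []
        for i, g in enumerate(genes):
            contig = g.contig_a if species == "a" else g.contig_b
            cid = g.contig_id_a if species == "a" else g.contig_id_b
            cols = simulate_pileup(
                contig,
                [s for s in g.snps if s.species == species],
                config.coverage_mean, config.error_rate,
                seed=[abs(config.seed), i, 1 if species == "a" else 2],
                contig_id=cid, quality_dropout=config.quality_dropout)
            all_cols.extend(cols)
            if len(all_cols) > 50000 or i == len(genes) - 1:
                _append_pileup(path, all_cols)
                all_cols = []

    pd.DataFrame([
        {"gene_id": s.gene_id, "lineage": s.lineage, "pos": s.pos,
         "codon_index": s.codon_index, "class": s.cls, "adaptive": s.adaptive}
        for g in genes for s in g.substitutions
    ]).to_csv(outdir / "truth_substitutions.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"gene_id": s.gene_id, "species": s.species, "contig_id": s.contig_id,
         "pos": s.pos, "major_allele": s.major_allele,
         "minor_allele": s.minor_allele, "minor_freq": s.minor_freq,
         "class": s.cls, "freq_class": s.freq_class,
         "deleterious": s.deleterious}
        for g in genes for s in g.snps
    ]).to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
    pd.DataFrame([g.truth_counts() for g in genes]).to_csv(
        outdir / "truth_genes.tsv", sep="\t", index=False)

    cfg = asdict(config)
    cfg["allele_freq_spectrum"] = (
        None if config.allele_freq_spectrum is None
        else [list(map(float, config.allele_freq_spectrum[0])),
              list(map(float, config.allele_freq_spectrum[1]))])
    cfg["utr_len_range"] = list(config.utr_len_range)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    return {
        "outdir": str(outdir),
        "n_genes": len(genes),
        "n_substitutions": sum(len(g.substitutions) for g in genes),
        "n_snps": sum(len(g.snps) for g in genes),
        "true_alpha": true_alpha(genes),
    }


def _append_pileup(path, cols: Sequence[PileupColumn]) -> None:
    with open(path, "a", newline="") as fh:
        for c in cols:
            fh.write(f"{c.contig_id}\t{c.pos}\t{c.ref_base}\t{c.depth}\t"
                     f"{c.counts[0]}\t{c.counts[1]}\t{c.counts[2]}\t{c.counts[3]}\t"
                     f"{c.snp_quality:g}\t{c.neighborhood_low_q}\n")
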