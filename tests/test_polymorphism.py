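"""Pooled-SNP filters, silent/non-silent classification, frequency
binning, per-gene pooling and the binomial detection probability."""

import itertools

import pytest

from mkalpha.codons import SENSE_CODONS, reverse_complement
from mkalpha.orf import OrfRecord
from mkalpha.polymorphism import (AmbiguousCodon, PileupColumn, SnpFilters,
                                  SnpRecord, bin_by_frequency, call_snps,
                                  classify_snp, detection_probability,
                                  pool_gene_counts)

from oracles import binomial_tail, snp_effect_translated


def _col(counts, quality=30.0, neighbors=0, pos=1):
    return PileupColumn("c1", pos, "A", counts, quality, neighbors)


def _called(cols, **kw):
    return list(call_snps(cols, SnpFilters(**kw) if kw else SnpFilters()))


def test_passing_column_is_emitted_with_minor_freq():
    snps = _called([_col((9, 0, 3, 0))])
    assert len(snps) == 1
    snp = snps[0]
    assert (snp.major_allele, snp.minor_allele) == ("A", "G")
    assert snp.minor_freq == pytest.approx(0.25)
    assert snp.depth == 12


@pytest.mark.parametrize(
    "counts,quality,neighbors",
    [
        ((6, 0, 3, 0), 30, 0),    # depth 9 < 10
        ((49, 1, 0, 0), 30, 0),   # rarer allele seen once
        ((20, 0, 0, 0), 30, 0),   # monoallelic
        ((10, 5, 3, 0), 30, 0),   # three alleles
        ((9, 0, 3, 0), 19.9, 0),  # SNP quality below 20
        ((9, 0, 3, 0), 30, 4),    # > 3 low-quality neighbours
    ],
)
def test_failing_columns_are_rejected(counts, quality, neighbors):
    assert _called([_col(counts, quality, neighbors)]) == []


def test_filters_are_conjunctive_so_order_is_irrelevant(rng):
    def random_col(i):
        counts = tuple(rng.choice([0, 0, 1, 2, 3, 8, 15]) for _ in range(4))
        return _col(counts, quality=rng.choice([10, 25, 40]),
                    neighbors=rng.choice([0, 2, 4]), pos=i + 1)

    cols = [random_col(i) for i in range(500)]

    filters = [
        lambda c: c.depth >= 10,
        lambda c: sum(n > 0 for n in c.counts) == 2,
        lambda c: sorted(c.counts)[-2] >= 2 and sum(n > 0 for n in c.counts) >= 2,
        lambda c: c.snp_quality >= 20,
        lambda c: c.neighborhood_low_q <= 3,
    ]
    reference = {c.pos for c in cols if all(f(c) for f in filters)}
    assert {s.pos for s in _called(cols)} == reference
    for perm in itertools.permutations(range(5)):
        surviving = cols
        for i in perm:
            surviving = [c for c in surviving if filters[i](c)]
        assert {c.pos for c in surviving} == reference


def _plus_orf(cds):
    return OrfRecord("c1", "+", 11, 10 + len(cds), cds)


def test_third_position_synonymous_snp_is_silent():
    orf = _plus_orf("ATGCCTTAA")
    snp = SnpRecord("c1", 16, "T", "A", 3, 12)  # 3rd base of CCT
    assert classify_snp(snp, orf).effect == "silent"  # CCT<->CCA, Pro


def test_first_position_snp_is_non_silent():
    orf = _plus_orf("ATGCCTTAA")
    snp = SnpRecord("c1", 14, "C", "G", 3, 12)  # CCT<->GCT, Pro<->Ala
    assert classify_snp(snp, orf).effect == "non-silent"


def test_positions_outside_orf_and_missing_orf():
    orf = _plus_orf("ATGCCTTAA")
    assert classify_snp(SnpRecord("c1", 2, "C", "G", 3, 12), orf).effect == "outside_orf"
    assert classify_snp(SnpRecord("c1", 2, "C", "G", 3, 12), None).effect == "outside_orf"


def test_ambiguous_codon_raises():
    orf = OrfRecord("c1", "+", 1, 9, "ATGCNTTAA")
    with pytest.raises(AmbiguousCodon):
        classify_snp(SnpRecord("c1", 4, "C", "G", 3, 12), orf)


def test_classification_matches_translation_oracle_on_random_cases(rng):
    for _ in range(1000):
        cds = "ATG" + "".join(rng.choice(SENSE_CODONS) for _ in range(20))
        strand = rng.choice("+-")
        start = rng.randrange(1, 50)
        end = start + len(cds) - 1
        orf = OrfRecord("c1", strand, start, end, cds)
        idx = rng.randrange(3, len(cds))  # skip ATG for variety of codons
        codon_i, within = divmod(idx, 3)
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        major = codon[within]
        minor = rng.choice([b for b in "ACGT" if b != major])
        # map the ORF index back to a forward-contig position and alleles
        if strand == "+":
            pos = start + idx
            rec = SnpRecord("c1", pos, major, minor, 3, 12)
        else:
            pos = end - idx
            rec = SnpRecord("c1", pos, reverse_complement(major),
                            reverse_complement(minor), 3, 12)
        got = classify_snp(rec, orf)
        assert got.in_orf
        assert got.effect == snp_effect_translated(codon, within, major, minor)


@pytest.mark.parametrize(
    "minor,depth,expected",
    [
        (2, 100, "low"),        # 2%
        (2, 40, "moderate"),    # exactly 5% -> moderate (half-open bins)
        (5, 40, "moderate"),    # 12.5%
        (6, 40, "common"),      # exactly 15% -> common
        (20, 60, "common"),     # 33%
        (30, 60, "common"),     # 50%, upper boundary included
    ],
)
def test_frequency_class_boundaries(minor, depth, expected):
    assert bin_by_frequency(minor / depth) == expected


def test_frequency_outside_range_raises():
    with pytest.raises(ValueError):
        bin_by_frequency(0.0)
    with pytest.raises(ValueError):
        bin_by_frequency(0.6)


def _snp(contig, effect, minor_count=20, depth=60, species="a"):
    return SnpRecord(contig, 1, "A", "G", minor_count, depth,
                     species=species, effect=effect, in_orf=True)


def test_pool_adds_both_species_counts_per_gene():
    gene_map = {"c_a": "g1", "c_b": "g1"}
    snps = ([_snp("c_a", "non-silent")] * 3 + [_snp("c_a", "silent")] * 2
            + [_snp("c_b", "non-silent", species="b")]
            + [_snp("c_b", "silent", species="b")] * 4)
    assert pool_gene_counts(snps, gene_map) == {"g1": (4, 6)}


def test_pool_exclusion_drops_only_the_requested_classes():
    gene_map = {"c": "g"}
    snps = [
        _snp("c", "non-silent", 2, 100),   # low, 2%
        _snp("c", "silent", 4, 40),        # moderate, 10%
        _snp("c", "non-silent", 20, 60),   # common
    ]
    assert pool_gene_counts(snps, gene_map, "none") == {"g": (2, 1)}
    assert pool_gene_counts(snps, gene_map, "low") == {"g": (1, 1)}
    assert pool_gene_counts(snps, gene_map, "low_moderate") == {"g": (1, 0)}


def test_pool_with_no_snps_is_empty():
    assert pool_gene_counts([], {"c": "g"}) == {}


@pytest.mark.parametrize(
    "depth,freq,min_minor",
    [(10, 0.25, 2), (200, 0.25, 2), (50, 0.05, 2), (30, 0.5, 5)],
)
def test_detection_probability_matches_binomial_sum(depth, freq, min_minor):
    assert detection_probability(depth, freq, min_minor) == pytest.approx(
        binomial_tail(depth, freq, min_minor), abs=1e-9)


def test_detection_probability_known_values():
    # the depth-10 pool detects a 25% allele (2+ reads) only ~76% of the time
    assert detection_probability(10, 0.25, 2) == pytest.approx(0.7560, abs=5e-4)
    assert detection_probability(200, 0.25, 2) > 0.999
    assert detection_probability(100, 0.0, 2) == 0.0
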