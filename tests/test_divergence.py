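"""NG86 site composition, pathway-averaged substitution counting and
per-gene divergence summaries, cross-checked against exhaustive oracles."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mkalpha.codons import SENSE_CODONS
from mkalpha.divergence import (ExcludedCodon, _pair_path_counts,
                                codon_site_composition, count_substitutions,
                                gene_divergence, jukes_cantor, p_distance)

from oracles import pathway_counts_enumerated, site_composition_enumerated

sense_codons = st.sampled_from(SENSE_CODONS)


@pytest.mark.parametrize(
    "codon,expected_n,expected_s",
    [
        ("TTT", 8 / 3, 1 / 3),  # Phe: only third-position TTC is synonymous
        ("TGG", 3.0, 0.0),      # Trp: no synonymous mutational opportunity
        ("CCC", 2.0, 1.0),      # Pro: fourfold-degenerate third position
    ],
)
def test_site_composition_known_codons(codon, expected_n, expected_s):
    n, s = codon_site_composition(codon)
    assert n == pytest.approx(expected_n, abs=1e-12)
    assert s == pytest.approx(expected_s, abs=1e-12)


def test_site_composition_matches_enumeration_for_all_sense_codons():
    for codon in SENSE_CODONS:
        n, s = codon_site_composition(codon)
        n_o, s_o = site_composition_enumerated(codon)
        assert n == pytest.approx(n_o, abs=1e-12)
        assert s == pytest.approx(s_o, abs=1e-12)
        # conservation: each codon spans exactly three sites
        assert n + s == pytest.approx(3.0, abs=1e-9)


def test_site_composition_rejects_stop_and_ambiguous():
    with pytest.raises(ExcludedCodon):
        codon_site_composition("TAA")
    with pytest.raises(ExcludedCodon):
        codon_site_composition("ANT")


@pytest.mark.parametrize(
    "c1,c2,dn,ds",
    [
        ("CCT", "CCA", 0.0, 1.0),  # Pro->Pro, single synonymous step
        ("CCT", "GCT", 1.0, 0.0),  # Pro->Ala
        ("AAA", "AAA", 0.0, 0.0),
        # two pathways: via GTT ends with a synonymous Val->Val step,
        # via TTA both steps are non-synonymous -> average (1.5, 0.5)
        ("TTT", "GTA", 1.5, 0.5),
    ],
)
def test_pathway_counts_known_pairs(c1, c2, dn, ds):
    assert _pair_path_counts(c1, c2) == pytest.approx((dn, ds), abs=1e-12)


@given(sense_codons, sense_codons)
def test_pathway_counts_match_enumeration(c1, c2):
    oracle = pathway_counts_enumerated(c1, c2)
    if oracle is None:
        with pytest.raises(ExcludedCodon):
            _pair_path_counts(c1, c2)
        return
    dn, ds = _pair_path_counts(c1, c2)
    assert (dn, ds) == pytest.approx(oracle, abs=1e-12)
    # conservation: classified steps account for every nucleotide difference
    n_diff = sum(a != b for a, b in zip(c1, c2))
    assert dn + ds == pytest.approx(n_diff, abs=1e-9)


@given(sense_codons, sense_codons)
def test_pathway_counts_symmetric(c1, c2):
    try:
        forward = _pair_path_counts(c1, c2)
    except ExcludedCodon:
        with pytest.raises(ExcludedCodon):
            _pair_path_counts(c2, c1)
        return
    assert _pair_path_counts(c2, c1) == pytest.approx(forward, abs=1e-12)


def test_count_substitutions_over_alignment_skips_gap_codons():
    a = "CCTGGG---TTT"
    b = "CCAGGGAAATTT"
    skipped = []
    subs = count_substitutions(a, b, skipped=skipped)
    assert subs.Ds == pytest.approx(1.0)
    assert subs.Dn == pytest.approx(0.0)
    assert skipped == [2]


def test_p_distance_and_gene_divergence_basics():
    a = "ATG" + "CCT" * 33  # 100 codons total would be unwieldy; 34 codons
    b = "ATG" + "CCT" * 31 + "CCA" + "CGT"
    assert p_distance(a, a) == 0.0
    d = gene_divergence(a, b)
    assert d.subs.Ds == pytest.approx(1.0)
    assert d.subs.Dn == pytest.approx(1.0)
    assert d.p_dist == pytest.approx(2 / len(a))
    # identical pair
    d0 = gene_divergence(a, a)
    assert d0.dS_raw == d0.dN_raw == 0.0
    assert d0.p_dist == 0.0


def test_gene_divergence_symmetric(rng):
    from mkalpha.simulate import SimConfig, simulate_ortholog_pair

    g = simulate_ortholog_pair(SimConfig(n_genes=1, seed=5), 0)
    fwd = gene_divergence(g.cds_a, g.cds_b)
    rev = gene_divergence(g.cds_b, g.cds_a)
    for attr in ("p_dist", "aa_dist", "dS_raw", "dN_raw"):
        assert getattr(fwd, attr) == pytest.approx(getattr(rev, attr), abs=1e-12)
    assert fwd.subs.Dn == pytest.approx(rev.subs.Dn, abs=1e-12)
    assert fwd.sites.N == pytest.approx(rev.sites.N, abs=1e-12)


def test_sites_sum_to_three_per_codon_in_gene_divergence():
    seq = "ATGAAATTTCCCGGG"
    d = gene_divergence(seq, seq)
    assert d.sites.N + d.sites.S == pytest.approx(3 * d.sites.codons_used, abs=1e-9)


def test_jukes_cantor_correction():
    assert jukes_cantor(0.0) == 0.0
    p = 0.06
    assert jukes_cantor(p) == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))
    assert jukes_cantor(0.8) == math.inf
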