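"""The synthetic-data generator: determinism, ground-truth consistency,
divergence calibration and pileup sampling."""

import numpy as np
import pytest

from mkalpha.codons import translate_codon
from mkalpha.divergence import p_distance
from mkalpha.polymorphism import read_pileup
from mkalpha.simulate import (SimConfig, neutral_folded_spectrum,
                              simulate_dataset, simulate_genes,
                              simulate_ortholog_pair, simulate_pileup,
                              true_alpha)


def test_invalid_configurations_are_rejected():
    with pytest.raises(ValueError):
        SimConfig(divergence_target=0.0, adaptive_fraction=0.3).validate()
    with pytest.raises(ValueError):
        SimConfig(coverage_mean=0).validate()
    with pytest.raises(ValueError):
        SimConfig(theta=1.5).validate()


def test_zero_divergence_yields_identical_sequences():
    cfg = SimConfig(n_genes=5, divergence_target=0.0, adaptive_fraction=0.0,
                    theta=0.0, seed=3)
    for i in range(5):
        g = simulate_ortholog_pair(cfg, i)
        assert g.contig_a == g.contig_b
        assert g.truth_counts()["Dn"] == g.truth_counts()["Ds"] == 0


def test_generation_is_deterministic_in_the_seed(tmp_path):
    cfg = SimConfig(n_genes=6, seed=1)
    d1, d2 = tmp_path / "run1", tmp_path / "run2"
    simulate_dataset(cfg, d1)
    simulate_dataset(cfg, d2)
    for name in ("species_a.fasta", "species_b.fasta", "pileup_a.tsv",
                 "truth_genes.tsv", "clusters.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_mean_p_distance_hits_the_divergence_target():
    cfg = SimConfig(n_genes=200, mean_len_codons=300, divergence_target=0.015,
                    theta=0.0, seed=0)
    dists = [p_distance(g.cds_a, g.cds_b) for g in simulate_genes(cfg)]
    assert np.mean(dists) == pytest.approx(0.015, abs=0.003)


def test_truth_table_matches_reconstructed_codon_differences():
    cfg = SimConfig(n_genes=30, seed=9)
    for g in simulate_genes(cfg):
        a, b = g.cds_a, g.cds_b
        differing = 0
        syn = nonsyn = 0
        for i in range(0, len(a), 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            if ca != cb:
                differing += 1
                assert sum(x != y for x, y in zip(ca, cb)) == 1
                if translate_codon(ca) == translate_codon(cb):
                    syn += 1
                else:
                    nonsyn += 1
        t = g.truth_counts()
        assert t["Dn"] + t["Ds"] == differing
        assert (t["Dn"], t["Ds"]) == (nonsyn, syn)


def test_realised_alpha_tracks_the_adaptive_fraction():
    cfg = SimConfig(n_genes=400, adaptive_fraction=0.4, seed=2)
    genes = list(simulate_genes(cfg))
    assert true_alpha(genes) == pytest.approx(0.4, abs=0.05)


def test_snp_truth_effects_match_translation():
    cfg = SimConfig(n_genes=20, theta=0.01, seed=4)
    for g in simulate_genes(cfg):
        for snp in g.snps:
            contig = g.contig_a if snp.species == "a" else g.contig_b
            idx = snp.pos - 1 - g.utr5_len
            codon_i, within = divmod(idx, 3)
            cds = g.cds_a if snp.species == "a" else g.cds_b
            codon = cds[3 * codon_i : 3 * codon_i + 3]
            assert contig[snp.pos - 1] == snp.major_allele
            alt = codon[:within] + snp.minor_allele + codon[within + 1 :]
            same_aa = translate_codon(codon) == translate_codon(alt)
            assert (snp.cls == "silent") == same_aa
            assert 0 < snp.minor_freq <= 0.5


def test_neutral_folded_spectrum_is_a_distribution():
    f, w = neutral_folded_spectrum(120)
    assert w.sum() == pytest.approx(1.0)
    assert f.min() == pytest.approx(1 / 120)
    assert f.max() == pytest.approx(0.5)
    assert np.all(np.diff(w) < 0)  # rarer variants are more probable


class TestPileup:
    def test_binomial_minor_allele_sampling(self):
        from mkalpha.simulate import SnpTruth

        seq = "A" * 101
        snp = SnpTruth("g", "a", "c", 51, "A", "G", 0.5, "silent", False)
        means = []
        for seed in range(30):
            cols = simulate_pileup(seq, [snp], coverage_mean=200,
                                   error_rate=0.0, seed=seed)
            means.append(cols[50].count_of("G"))
        # E[minor reads] = 200 * 0.5 = 100; SE of the 30-seed mean ~ 1.3
        assert np.mean(means) == pytest.approx(100, abs=5)

    def test_no_snps_no_error_gives_monoallelic_columns(self):
        cols = simulate_pileup("ACGT" * 30, [], 50, 0.0, seed=1)
        for c in cols:
            assert sum(n > 0 for n in c.counts) <= 1
            assert c.count_of(c.ref_base) == c.depth

    def test_pileup_bytes_are_deterministic(self, tmp_path):
        from mkalpha.polymorphism import write_pileup

        paths = []
        for run in range(2):
            cols = simulate_pileup("ACGT" * 50, [], 30, 0.01, seed=99)
            p = tmp_path / f"run{run}.tsv"
            write_pileup(p, cols)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_zero_coverage_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert simulate_pileup("ACGT", [], 0, 0.0, seed=1) == []


def test_dataset_roundtrips_through_package_readers(tmp_path):
    cfg = SimConfig(n_genes=4, seed=8)
    simulate_dataset(cfg, tmp_path)
    genes = list(simulate_genes(cfg))
    cols = list(read_pileup(tmp_path / "pileup_a.tsv"))
    by_contig = {}
    for c in cols:
        by_contig.setdefault(c.contig_id, []).append(c)
    for g in genes:
        assert len(by_contig[g.contig_id_a]) == len(g.contig_a)
    from Bio import SeqIO

    recs = {r.id: str(r.seq) for r in SeqIO.parse(tmp_path / "species_a.fasta", "fasta")}
    assert recs == {g.contig_id_a: g.contig_a for g in genes}
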