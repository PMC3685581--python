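"""End-to-end orchestration: ORFs → codon alignments → divergence counts
→ pooled SNPs → McDonald-Kreitman tests and α.

Every stage writes a TSV under the output directory and drops a
``.done_<stage>`` marker, so a re-run (``resume=True``) reuses cached
upstream outputs byte-identically.  INFO logging records each filter's
in/out counts, giving the pipeline a funnel report (contigs → ORFs →
clusters → retained alignments → MKT-eligible genes).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
from Bio import SeqIO

from .align import (MAX_P_DISTANCE, TRIM_NT, CodonAlignment, TranslationError,
                    align_and_backtranslate, make_aligner, select_best_pair,
                    trim_alignment)
from .divergence import ExcludedCodon, gene_divergence
from .orf import MIN_ORF_AA, OrfRecord, predict_orf
from .polymorphism import (AmbiguousCodon, SnpFilters, bin_by_frequency,
                           call_snps, classify_snp, pool_gene_counts,
                           read_pileup)
from .selection import GeneCounts, estimate_alpha, mkt_table

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

EXCLUSION_MODES = ("none", "low", "low_moderate")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and options for a full run.

    Threshold defaults are the study's published filter settings: mapping
    depth 10, SNP quality 20, p-distance 0.1, end-trim 15 nt, minimum ORF
    length 30 aa.
    """

    fasta_a: str = ""
    fasta_b: str = ""
    pileup_a: str = ""
    pileup_b: str = ""
    clusters: str = ""
    outdir: str = "mkalpha_out"
    min_depth: int = 10
    min_minor_count: int = 2
    min_quality: float = 20.0
    max_low_q_neighbors: int = 3
    max_p_distance: float = MAX_P_DISTANCE
    trim_nt: int = TRIM_NT
    min_orf_aa: int = MIN_ORF_AA
    fdr_level: float = 0.05
    n_bootstrap: int = 1000
    chi2_method: str = "chi2"
    seed: int = 0
    resume: bool = False
    write_alignments: bool = True

    def filters(self) -> SnpFilters:
        return SnpFilters(self.min_depth, self.min_minor_count,
                          self.min_quality, self.max_low_q_neighbors)


def _marker(outdir: Path, stage: str) -> Path:
    return outdir / f".done_{stage}"


def _stage_cached(cfg: PipelineConfig, outdir: Path, stage: str, outputs: List[Path]) -> bool:
    return cfg.resume and _marker(outdir, stage).exists() and all(p.exists() for p in outputs)


def predict_orfs_stage(cfg: PipelineConfig, outdir: Path) -> Dict[str, Dict[str, OrfRecord]]:
    """Stage 1: longest-closed-ORF prediction per contig per species."""
    orfs: Dict[str, Dict[str, OrfRecord]] = {}
    for species, fasta in (("a", cfg.fasta_a), ("b", cfg.fasta_b)):
        per = {}
        n_contigs = 0
        for rec in SeqIO.parse(fasta, "fasta"):
            n_contigs += 1
            orf = predict_orf(str(rec.seq), rec.id, min_aa=cfg.min_orf_aa)
            if orf is not None:
                per[rec.id] = orf
        log.info("species %s: %d/%d contigs yielded an ORF >= %d aa",
                 species, len(per), n_contigs, cfg.min_orf_aa)
        orfs[species] = per
        rows = [{"contig_id": o.contig_id, "strand": o.strand, "start": o.start,
                 "end": o.end, "length_nt": len(o.sequence), "closed": o.closed}
                for o in per.values()]
        pd.DataFrame(rows, columns=["contig_id", "strand", "start", "end",
                                    "length_nt", "closed"]).to_csv(
            outdir / f"orfs_{species}.tsv", sep="\t", index=False)
        with open(outdir / f"orfs_{species}.fasta", "w") as fh:
            for o in per.values():
                fh.write(f">{o.contig_id}\n{o.sequence}\n")
    _marker(outdir, "orfs").touch()
    return orfs


def align_stage(cfg: PipelineConfig, outdir: Path,
                orfs: Dict[str, Dict[str, OrfRecord]]) -> Dict[str, CodonAlignment]:
    """Stage 2: best-pair selection, protein alignment, back-translation,
    trimming and the p-distance filter."""
    clusters = pd.read_csv(cfg.clusters, sep="\t")
    aligner = make_aligner()
    retained: Dict[str, CodonAlignment] = {}
    rows = []
    n_single_species = 0
    aln_dir = outdir / "alignments"
    if cfg.write_alignments:
        aln_dir.mkdir(exist_ok=True)
    for gene_id, grp in clusters.groupby("cluster_id", sort=True):
        members_a = [orfs["a"][c] for c in grp.loc[grp.species == "a", "contig_id"]
                     if c in orfs["a"]]
        members_b = [orfs["b"][c] for c in grp.loc[grp.species == "b", "contig_id"]
                     if c in orfs["b"]]
        pair = select_best_pair(members_a, members_b, aligner=aligner)
        if pair is None:
            n_single_species += 1
            continue
        try:
            raw = align_and_backtranslate(pair[0], pair[1], gene_id=str(gene_id),
                                          aligner=aligner)
        except TranslationError as exc:
            log.warning("gene %s skipped: %s", gene_id, exc)
            continue
        trimmed = trim_alignment(raw, trim_nt=cfg.trim_nt,
                                 max_p_distance=cfg.max_p_distance)
        row = {"gene_id": str(gene_id), "orf_a": pair[0].contig_id,
               "orf_b": pair[1].contig_id}
        if trimmed is None:
            rows.append({**row, "length": raw.aligned_length,
                         "p_distance": raw.p_dist, "retained": False})
            continue
        rows.append({**row, "length": trimmed.aligned_length,
                     "p_distance": trimmed.p_dist, "retained": True})
        retained[str(gene_id)] = trimmed
        if cfg.write_alignments:
            with open(aln_dir / f"{gene_id}.fasta", "w") as fh:
                fh.write(f">{trimmed.orf_a}\n{trimmed.seq_a}\n"
                         f">{trimmed.orf_b}\n{trimmed.seq_b}\n")
    summary = pd.DataFrame(rows, columns=["gene_id", "orf_a", "orf_b",
                                          "length", "p_distance", "retained"])
    summary.to_csv(outdir / "alignment_summary.tsv", sep="\t", index=False)
    log.info("alignment: %d clusters in, %d single-species skipped, "
             "%d aligned, %d retained after trim+p-distance",
             clusters["cluster_id"].nunique(), n_single_species,
             len(rows), len(retained))
    _marker(outdir, "align").touch()
    return retained


def count_stage(cfg: PipelineConfig, outdir: Path,
                alignments: Dict[str, CodonAlignment]) -> pd.DataFrame:
    """Stage 3: NG86 sites/substitutions and divergence per retained gene."""
    rows = []
    for gene_id in sorted(alignments):
        aln = alignments[gene_id]
        try:
            d = gene_divergence(aln.seq_a, aln.seq_b)
        except ExcludedCodon as exc:
            log.warning("gene %s excluded from counting: %s", gene_id, exc)
            continue
        rows.append({
            "gene_id": gene_id, "N": d.sites.N, "S": d.sites.S,
            "codons_used": d.sites.codons_used,
            "Dn": d.subs.Dn, "Ds": d.subs.Ds,
            "p_dist": d.p_dist, "aa_dist": d.aa_dist,
            "dS_raw": d.dS_raw, "dS_jc": d.dS_jc,
            "dN_raw": d.dN_raw, "dN_jc": d.dN_jc,
        })
    df = pd.DataFrame(rows, columns=["gene_id", "N", "S", "codons_used", "Dn",
                                     "Ds", "p_dist", "aa_dist", "dS_raw",
                                     "dS_jc", "dN_raw", "dN_jc"])
    df.to_csv(outdir / "gene_counts.tsv", sep="\t", index=False)
    _marker(outdir, "count").touch()
    return df


def snp_stage(cfg: PipelineConfig, outdir: Path,
              orfs: Dict[str, Dict[str, OrfRecord]],
              gene_of_contig: Dict[str, str]) -> pd.DataFrame:
    """Stage 4: pooled SNP calling, silent/non-silent classification."""
    filters = cfg.filters()
    all_rows = []
    for species, path in (("a", cfg.pileup_a), ("b", cfg.pileup_b)):
        if not path:
            continue
        n_called = n_excluded = 0
        for snp in call_snps(read_pileup(path), filters, species=species):
            n_called += 1
            orf = orfs[species].get(snp.contig_id)
            try:
                snp = classify_snp(snp, orf)
            except AmbiguousCodon as exc:
                n_excluded += 1
                log.warning("SNP excluded: %s", exc)
                continue
            all_rows.append({
                "contig_id": snp.contig_id, "pos": snp.pos,
                "species": species,
                "major_allele": snp.major_allele,
                "minor_allele": snp.minor_allele,
                "minor_count": snp.minor_count, "depth": snp.depth,
                "minor_freq": snp.minor_freq,
                "freq_class": bin_by_frequency(snp.minor_freq),
                "in_orf": snp.in_orf, "effect": snp.effect,
                "gene_id": gene_of_contig.get(snp.contig_id, ""),
            })
        log.info("species %s: %d SNPs passed filters, %d excluded (ambiguous codon)",
                 species, n_called, n_excluded)
    df = pd.DataFrame(all_rows, columns=["contig_id", "pos", "species",
                                         "major_allele", "minor_allele",
                                         "minor_count", "depth", "minor_freq",
                                         "freq_class", "in_orf", "effect",
                                         "gene_id"])
    df.to_csv(outdir / "snps.tsv", sep="\t", index=False)
    _marker(outdir, "snps").touch()
    return df


def _snp_records_from_df(df: pd.DataFrame):
    from .polymorphism import SnpRecord

    for row in df.itertuples(index=False):
        yield SnpRecord(row.contig_id, int(row.pos), row.major_allele,
                        row.minor_allele, int(row.minor_count), int(row.depth),
                        species=row.species, effect=row.effect,
                        in_orf=bool(row.in_orf))


def stats_stage(cfg: PipelineConfig, outdir: Path, counts: pd.DataFrame,
                snps: pd.DataFrame, gene_of_contig: Dict[str, str]) -> dict:
    """Stage 5: per-gene MKT with FDR, and α for all exclusion modes."""
    pools = {
        mode: pool_gene_counts(_snp_records_from_df(snps), gene_of_contig,
                               exclusion=mode)
        for mode in EXCLUSION_MODES
    }
    merged = counts.set_index("gene_id")
    gene_rows = []
    for gene_id in merged.index:
        row = {"gene_id": gene_id,
               "Dn": merged.at[gene_id, "Dn"], "Ds": merged.at[gene_id, "Ds"],
               "N": merged.at[gene_id, "N"], "S": merged.at[gene_id, "S"]}
        for mode in EXCLUSION_MODES:
            pn, ps = pools[mode].get(gene_id, (0, 0))
            row[f"Pn_{mode}"] = pn
            row[f"Ps_{mode}"] = ps
        gene_rows.append(row)
    joined = pd.DataFrame(gene_rows)
    joined.to_csv(outdir / "joined_counts.tsv", sep="\t", index=False)

    genes_none = [GeneCounts(r["gene_id"], r["Dn"], r["Ds"],
                             r["Pn_none"], r["Ps_none"], r["N"], r["S"])
                  for r in gene_rows]
    mkt = mkt_table(genes_none, method=cfg.chi2_method, fdr_level=cfg.fdr_level)
    mkt.to_csv(outdir / "mkt_results.tsv", sep="\t", index=False)
    n_eligible = int((mkt["excluded_reason"] == "").sum())
    n_sig = int(mkt["significant"].sum())
    log.info("MKT: %d/%d genes eligible (non-zero cells), %d significant at FDR %.2f",
             n_eligible, len(gene_rows), n_sig, cfg.fdr_level)

    alpha_rows = []
    alphas = {}
    for mode in EXCLUSION_MODES:
        genes_mode = [GeneCounts(r["gene_id"], r["Dn"], r["Ds"],
                                 r[f"Pn_{mode}"], r[f"Ps_{mode}"],
                                 r["N"], r["S"]) for r in gene_rows]
        try:
            est = estimate_alpha(genes_mode, exclusion_mode=mode,
                                 n_bootstrap=cfg.n_bootstrap, seed=cfg.seed)
        except (ZeroDivisionError, ValueError) as exc:
            log.warning("alpha (%s) undefined: %s", mode, exc)
            continue
        alphas[mode] = est
        alpha_rows.append({"exclusion_mode": mode, "alpha": est.alpha,
                           "ci_low": est.ci_low, "ci_high": est.ci_high,
                           "n_genes": est.n_genes,
                           "n_bootstrap": est.n_bootstrap})
    pd.DataFrame(alpha_rows, columns=["exclusion_mode", "alpha", "ci_low",
                                      "ci_high", "n_genes", "n_bootstrap"]
                 ).to_csv(outdir / "alpha.tsv", sep="\t", index=False)
    _marker(outdir, "stats").touch()
    return {"mkt": mkt, "alphas": alphas, "n_eligible": n_eligible,
            "n_significant": n_sig, "joined": joined}


def _divergence_histogram(counts: pd.DataFrame, width: float = 0.005,
                          top: float = 0.105) -> list:
    edges = np.arange(0.0, top + width, width)
    hist, _ = np.histogram(counts["p_dist"], bins=edges)
    return [{"bin_low": float(edges[i]), "bin_high": float(edges[i + 1]),
             "n_genes": int(hist[i])} for i in range(len(hist))]


def _snp_class_table(snps: pd.DataFrame) -> list:
    rows = []
    coding = snps[snps["effect"].isin(["silent", "non-silent"])]
    for cls in ("low", "moderate", "common"):
        sub = coding[coding["freq_class"] == cls]
        pn = int((sub["effect"] == "non-silent").sum())
        ps = int((sub["effect"] == "silent").sum())
        rows.append({"freq_class": cls, "Pn": pn, "Ps": ps,
                     "Pn_Ps": pn / ps if ps else float("nan")})
    return rows


def _load_orfs(outdir: Path) -> Dict[str, Dict[str, OrfRecord]]:
    orfs: Dict[str, Dict[str, OrfRecord]] = {}
    for species in ("a", "b"):
        seqs = {rec.id: str(rec.seq)
                for rec in SeqIO.parse(outdir / f"orfs_{species}.fasta", "fasta")}
        df = pd.read_csv(outdir / f"orfs_{species}.tsv", sep="\t")
        orfs[species] = {
            r.contig_id: OrfRecord(r.contig_id, r.strand, int(r.start),
                                   int(r.end), seqs[r.contig_id],
                                   closed=bool(r.closed))
            for r in df.itertuples(index=False)
        }
    return orfs


def _load_alignments(outdir: Path) -> Dict[str, CodonAlignment]:
    summary = pd.read_csv(outdir / "alignment_summary.tsv", sep="\t")
    out = {}
    for r in summary[summary.retained].itertuples(index=False):
        recs = list(SeqIO.parse(outdir / "alignments" / f"{r.gene_id}.fasta", "fasta"))
        out[str(r.gene_id)] = CodonAlignment(
            gene_id=str(r.gene_id), seq_a=str(recs[0].seq), seq_b=str(recs[1].seq),
            orf_a=recs[0].id, orf_b=recs[1].id, trimmed=True)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write a JSON + text summary.

    Returns the summary dict.  An empty post-filter gene set yields a
    clean zero-gene report rather than an error.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    orf_outputs = [outdir / f"orfs_{s}.{ext}" for s in "ab" for ext in ("tsv", "fasta")]
    if _stage_cached(cfg, outdir, "orfs", orf_outputs):
        log.info("orfs stage: reusing cached outputs")
        orfs = _load_orfs(outdir)
    else:
        orfs = predict_orfs_stage(cfg, outdir)
    clusters = pd.read_csv(cfg.clusters, sep="\t")
    gene_of_contig = dict(zip(clusters["contig_id"], clusters["cluster_id"].astype(str)))

    if cfg.write_alignments and _stage_cached(
            cfg, outdir, "align", [outdir / "alignment_summary.tsv"]):
        log.info("align stage: reusing cached outputs")
        alignments = _load_alignments(outdir)
    else:
        alignments = align_stage(cfg, outdir, orfs)
    if _stage_cached(cfg, outdir, "count", [outdir / "gene_counts.tsv"]):
        # round_trip parsing keeps cached floats bit-identical to the run
        # that wrote them, so resumed summaries match byte for byte
        counts = pd.read_csv(outdir / "gene_counts.tsv", sep="\t",
                             float_precision="round_trip")
    else:
        counts = count_stage(cfg, outdir, alignments)
    if _stage_cached(cfg, outdir, "snps", [outdir / "snps.tsv"]):
        snps = pd.read_csv(outdir / "snps.tsv", sep="\t",
                           float_precision="round_trip")
    else:
        snps = snp_stage(cfg, outdir, orfs, gene_of_contig)

    summary: dict = {
        "funnel": {
            "contigs_a": sum(1 for _ in SeqIO.parse(cfg.fasta_a, "fasta")),
            "contigs_b": sum(1 for _ in SeqIO.parse(cfg.fasta_b, "fasta")),
            "orfs_a": len(orfs["a"]), "orfs_b": len(orfs["b"]),
            "clusters": int(clusters["cluster_id"].nunique()),
            "alignments_retained": len(alignments),
        },
    }
    if len(counts):
        zero_div = int((counts["p_dist"] == 0).sum())
        summary["divergence"] = {
            "mean_p_dist": float(counts["p_dist"].mean()),
            "mean_aa_dist": float(counts["aa_dist"].mean()),
            "mean_dS_raw": float(counts["dS_raw"].mean()),
            "mean_dS_jc": float(counts["dS_jc"].mean()),
            "zero_divergence_alignments": zero_div,
            "zero_divergence_pct": 100.0 * zero_div / len(counts),
            "histogram": _divergence_histogram(counts),
        }
        stats = stats_stage(cfg, outdir, counts, snps, gene_of_contig)
        summary["mkt"] = {
            "n_eligible": stats["n_eligible"],
            "n_significant": stats["n_significant"],
            "pct_significant": (100.0 * stats["n_significant"] / stats["n_eligible"]
                                if stats["n_eligible"] else float("nan")),
        }
        summary["alpha"] = {
            mode: {"alpha": est.alpha, "ci_low": est.ci_low, "ci_high": est.ci_high}
            for mode, est in stats["alphas"].items()
        }
    else:
        summary["divergence"] = {"zero_divergence_alignments": 0, "histogram": []}
        summary["mkt"] = {"n_eligible": 0, "n_significant": 0}
        summary["alpha"] = {}
        log.warning("no genes survived filtering; zero-gene report written")

    if len(snps):
        per_species = {}
        for sp, grp in snps.groupby("species"):
            coding = grp[grp["effect"].isin(["silent", "non-silent"])]
            n_ns = int((coding["effect"] == "non-silent").sum())
            per_species[sp] = {
                "snps_total": int(len(grp)),
                "snps_in_orf": int(len(coding)),
                "non_silent": n_ns,
                "silent": int(len(coding)) - n_ns,
                "pct_non_silent": (100.0 * n_ns / len(coding)
                                   if len(coding) else float("nan")),
            }
        summary["snps"] = {"per_species": per_species,
                           "freq_classes": _snp_class_table(snps)}
    else:
        summary["snps"] = {"per_species": {}, "freq_classes": []}

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_text_summary(outdir / "summary.txt", summary)
    return summary


def _write_text_summary(path: Path, s: dict) -> None:
    lines = ["mkalpha pipeline summary", "=" * 24, ""]
    f = s["funnel"]
    lines += [
        f"contigs: {f['contigs_a']} (a) / {f['contigs_b']} (b)",
        f"ORFs: {f['orfs_a']} (a) / {f['orfs_b']} (b)",
        f"clusters: {f['clusters']}",
        f"retained alignments: {f['alignments_retained']}",
        "",
    ]
    d = s.get("divergence", {})
    if "mean_p_dist" in d:
        lines += [
            f"mean nucleotide divergence: {100 * d['mean_p_dist']:.2f}%",
            f"mean amino-acid divergence: {100 * d['mean_aa_dist']:.2f}%",
            f"zero-divergence alignments: {d['zero_divergence_alignments']}"
            f" ({d['zero_divergence_pct']:.1f}%)",
            "",
        ]
    m = s["mkt"]
    lines.append(f"MKT: {m.get('n_significant', 0)} significant of "
                 f"{m.get('n_eligible', 0)} eligible genes")
    for mode, a in s.get("alpha", {}).items():
        lines.append(f"alpha ({mode}): {a['alpha']:.3f} "
                     f"[{a['ci_low']:.3f}, {a['ci_high']:.3f}]")
    path.write_text("\n".join(lines) + "\n")
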