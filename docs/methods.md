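# Methods

This note documents the models, conventions and numerical choices behind
`mkalpha`, in the order data flows through the pipeline, followed by the
synthetic-data model and known limitations.

## ORF extraction

Contigs are scanned on both strands in all six frames. Without a
homology hint, the prediction is the longest *closed* ORF — ATG to stop,
no internal stop — of at least 30 amino acids (the stop codon is part of
the reported sequence; the minimum counts coding codons only). Ties are
broken by earlier start on the forward contig, then by the + strand.
With an `Anchor(strand, frame[, position])` hint, the maximal stop-free
codon run through that frame is returned and may be open at either end,
mirroring how homology-anchored predictors rescue partial transcripts.
The standard genetic code is used throughout (dipteran nuclear genes).
Codons containing N are kept in the ORF (frame preservation) but
excluded from all downstream counting.

## Ortholog pairing, alignment, trimming

Within each ortholog cluster the single best cross-species pair is the
one maximising the global protein alignment score (BLOSUM62, gap open
10, extend 0.5 in half-bit units — MUSCLE-like defaults; percent
identity is available as an alternative criterion, ties go to the longer
pair then to lexicographic ids). The protein alignment is mapped back to
codons (every residue column becomes one codon column, every gap a
`---`), giving an in-frame nucleotide alignment.

Alignments are then trimmed by exactly 15 nt at each end, snapping
inward to the next codon boundary — transcript ends of pooled
pyrosequencing assemblies frequently carry homopolymer frame shifts —
and pairs with post-trim p-distance strictly greater than 0.1 are
discarded as residual mis-alignments or paralogs (a pair at exactly 0.1
is kept). Trimming is applied exactly once; re-trimming would remove a
further 30 nt. p-distance is the uncorrected mismatch proportion over
columns where both sequences have an unambiguous base (gaps and N
excluded).

## Site and substitution counting

Counting follows the unweighted Nei–Gojobori convention. Each codon
position carries a fractional synonymous site weight: the share of its
single-nucleotide mutational opportunities that are synonymous.
Mutations that would create a stop codon are excluded from both
numerator and denominator (mutational-opportunity convention), so every
codon spans exactly 3 sites; counting stop mutants as non-synonymous
instead is available via `stop_policy="nonsyn"`. Site totals for a pair
are the arithmetic mean of the two sequences' compositions.

Codon pairs differing at one position are classified directly. Pairs
differing at 2–3 positions are averaged with equal weight over every
ordering of single steps that avoids stop intermediates; codon pairs
whose every pathway crosses a stop are excluded and logged (they are
vanishingly rare at ~1.5% divergence). dS = Ds/S and dN = Dn/N are
reported both raw and Jukes–Cantor corrected; divergence summaries
(p-distance, amino-acid distance) are reported uncorrected, matching how
closely related pairs are usually described. The divergence-time helper
uses the two-lineage convention T = dS/(2r) over a list of published
synonymous rates r (per site per lineage per My).

## Pooled SNP calling and classification

Pileup columns (a simple TSV dialect: per-position allele counts, the
minimum base quality, and the count of low-quality bases within ±3
positions) are filtered conjunctively: depth ≥ 10, exactly two alleles
(triallelic columns are rejected outright, not reduced), rarer allele
seen ≥ 2 times, SNP quality ≥ 20, at most 3 neighbouring bases below
quality 15. Because the filters are conjunctive their order is
irrelevant. Allele frequencies are plug-in read proportions — pooled
data precludes genotypes. The binomial detection probability
P(X ≥ k | depth, freq) quantifies the resulting ascertainment: at depth
10 a 25%-frequency allele is detected (k = 2) with probability 0.756,
at depth 176 with probability ~1.

A SNP inside an ORF is silent iff substituting its two alleles into the
covering codon (strand-aware) leaves the amino acid unchanged. SNPs in
codons containing N are excluded and logged. Rarer-allele frequencies
are binned low < 5% ≤ moderate < 15% ≤ common ≤ 50%; the printed class
limits "5–15%" and "15–50%" are ambiguous at their boundaries, so the
half-open convention above is fixed here and configurable.

## MKT and α

Per gene, [[Dn, Ds], [Pn, Ps]] (Pn/Ps summed over both species) is
tested for independence with Pearson χ² without continuity correction;
Fisher's exact test is available behind a flag since small counts are
common (fractional NG86 counts are rounded for it). Genes with any zero
cell are ineligible. p-values are BH-FDR adjusted over all tested genes;
significance requires q ≤ 0.05 *and* neutrality ratio
(Dn/Ds)/(Pn/Ps) > 1, i.e. only the positive-selection direction is
called.

Transcriptome-wide α uses the aggregate (summed-counts) estimator
α = 1 − (ΣDs·ΣPn)/(ΣDn·ΣPs). This is a deliberate, documented choice of
the transparent desk-verifiable form over maximum-likelihood machinery
that jointly fits the frequency distribution of deleterious effects; the
bootstrap-over-genes CI follows the same resampling logic regardless of
the point estimator. The 95% CI resamples genes with replacement at the
original n (1,000 replicates by default, seeded); resamples with
ΣDn = 0 or ΣPs = 0 are discarded. The default interval is BCa
(bias-corrected accelerated, with the acceleration from a leave-one-gene
jackknife): for ratio-of-sums statistics the plain percentile interval
has first-order coverage error, and BCa is second-order accurate.
Percentile intervals remain available (`ci_method="percentile"`).

Slightly deleterious amino-acid variants segregate at low frequency,
inflate Pn relative to Ps, and bias α downward; α is therefore always
reported for three exclusion modes (none / drop low / drop
low+moderate frequency classes).

## The synthetic-data model

The generator emulates the study design the pipeline targets: two sister
species ~1.5% diverged, pooled sequencing of 60 diploid individuals per
species, ~1% substitution error. Per gene (all defaults in `SimConfig`,
every draw deterministic in `(seed, gene_index)`):

* **Gene structure** — ancestral ORF of Poisson-mean 134 codons
  (ATG + random sense codons + stop; ~402 bp, the scale of trimmed
  transcriptome alignments), embedded in 20–60 nt UTRs drawn from a
  C/G/T alphabet so no spurious ATG (nor a reverse-strand CAT) can
  displace the embedded frame — a deliberate simplification that keeps
  ORF truth unambiguous.
* **Divergence** — the per-gene substitution rate is
  `divergence_target` (default 0.0153) times a Gamma(0.6, mean 1)
  multiplier, making the among-gene divergence distribution
  overdispersed (a realistic ~quarter of genes identical, a long tail)
  while preserving the mean. Substitutions are placed codon-aware, at
  most one mutational hit per codon (an excellent approximation at this
  divergence, and it makes per-codon truth exact), never creating
  stops, and assigned to one of the two lineages at random.
* **Selection model** — a substitution is non-synonymous with
  probability r′/(1+r′) where r′ = r/(1−a): r (default 1.1, which
  reproduces a ~53% non-silent SNP share) is the neutral
  non-synonymous:synonymous ratio shared between polymorphism and
  divergence, and a (`adaptive_fraction`, default 0.25) is the true α —
  adaptive fixations add non-synonymous divergence on top of the
  neutral ratio, which is exactly the regime in which the aggregate
  estimator is consistent. Each non-synonymous fixation is flagged
  adaptive with probability a, so the realised truth is recorded per
  substitution.
* **Polymorphism** — per species, SNP count ~ Binomial(3L, θ)
  (θ default 0.006/site), placed on untouched codons with the class
  (silent/non-silent) realised by construction. Rarer-allele
  frequencies come from a folded neutral 1/i spectrum on 120
  chromosomes. An optional slightly-deleterious class
  (`deleterious_fraction` of non-synonymous SNPs, default 0) is
  restricted to frequencies < 15%, which is what makes α rise under
  frequency-class exclusion.
* **Pileups** — depth ~ Poisson(coverage_mean, default 30×, within the
  10–200× range of pooled transcriptome mappings), rarer-allele reads ~
  Binomial(depth, freq), then every read base substituted with
  probability `error_rate` (default 0.01) to a uniform other base.
  Column qualities encode the empirical correlation between base-call
  errors and low quality: genuine alleles read high quality (25–40)
  apart from a 2% dropout of low-quality columns, while a rarer allele
  supported *only* by k error reads draws a low quality (5–19) with
  probability 1 − 0.1^k. This is what gives the quality ≥ 20 filter its
  real-world discriminating power; without it, at 1% error a
  minor-count ≥ 2 filter alone admits error columns at rates comparable
  to true SNPs.

What the generator does **not** model: linkage between sites, indel
(homopolymer) errors, read-level data (pileups are generated directly),
expression-conditioned allele sampling (each species is one panmictic
pool, where the real design pooled two rearing temperatures), multiple
hits per codon, and gene-specific selection clusters (adaptive
substitutions are spread uniformly across genes, so per-gene MKT hits
are rare in simulations even when transcriptome-wide α is high).
Passing tests on this generator therefore validate the counting,
filtering and estimation machinery — not robustness to assembly or
mapping artefacts of real data.

Two consequences worth knowing when reading pipeline output on
synthetic data: (1) the retained-alignment mean divergence sits
slightly below the generating mean because the p-distance > 0.1 filter
clips the gamma tail — the same conservative effect expected of the
real filtering; (2) α from *called* SNPs runs a few points below the
generating value because residual error-derived SNPs inflate Pn — the
direction of bias expected for pooled reads with ~1% error, making the
reported α conservative.

## Numerical and degenerate-input conventions

Pathway and site compositions are cached per codon (pair); site-count
identities hold to 1e-9. Empty clusters, missing species, translation
failures and zero-usable-codon alignments are skipped with logged
reasons, never fatal. An empty post-filter gene set produces a clean
zero-gene report. Undefined α (ΣDn = 0 or ΣPs = 0) raises a specific
error and is reported as absent rather than as a number. Bootstrap and
simulation RNG are numpy `default_rng` seeded explicitly; pipeline
re-runs and stage resumes are byte-identical (cached TSVs are re-read
with round-trip float parsing). Problem sizes used by the acceptance
script — 2,000 genes of mean 134 codons — are the package's desk-scale
default for a transcriptome-wide analysis; all thresholds (depth 10,
quality 20, p-distance 0.1, trim 15 nt, 30 aa, FDR 0.05) are named
configuration fields.
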