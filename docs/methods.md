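# Methods

`founderscan` analyzes multi-population panels of biallelic SNP genotypes
for founder-effect diversity loss and locus-specific signatures of divergent
selection. This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices that pin down otherwise ambiguous
behavior.

## The analysis model

The pipeline assumes diploid genotypes at biallelic SNPs, encoded as
alt-allele dosage (0/1/2, with missing calls), for three or more populations:
typically one large, diverse source population and one or more derived
populations founded from it by a small number of colonists.

### Filtering

Filters run in a fixed order, each functional and idempotent:

1. **Depth mask** — genotypes supported by fewer than `min_depth` (default 5)
   reads become missing. The comparison is strict: exactly 5 reads is kept.
2. **Sample drop** — samples whose missing fraction strictly exceeds
   `max_sample_missing` (default 0.90) are removed.
3. **Call rate** — loci genotyped in at least `min_call_rate` (default 0.80,
   inclusive) of the retained samples are kept.
4. **Minor-allele count** — loci need `min_minor_copies` (default 2) copies
   of the minor allele pooled over all genotyped samples. A single
   minor-allele homozygote qualifies. A frequency mode (`maf_mode:
   frequency`, cutoff `min_maf` = 0.025) is available; the two rules disagree
   exactly at the boundary (2 copies / 82 alleles = 0.0244 < 0.025), and the
   count rule is the default because it is the operational definition.
5. **Hardy-Weinberg exclusion** — per population, loci whose exact
   conditional HWE p-value is below `hwe_alpha` (default 0.05) leave that
   population's usable set. Pairwise analyses use the intersection of the
   two populations' kept sets. Loci monomorphic within a population have a
   single possible outcome (p = 1) and are retained here; they drop out of
   F_ST later only if monomorphic across the pooled pair.

### Exact HWE test

The test conditions on observed allele counts. With `n` diploids and `nA`
copies of one allele, every compatible heterozygote count `h` has
Levene/Haldane conditional probability
`P(h) = n! / (nAA! h! naa!) * 2^h * nA! na! / (2n)!`. Outcomes are ranked by
the likelihood-ratio statistic `2 * sum obs * ln(obs / expected)` (expected
counts from HWE proportions at the conditioned allele frequency); the
p-value sums the probabilities of outcomes at least as extreme, with a 1e-9
tie tolerance on the statistic. Probability ordering is available as an
option. The test is exact and mildly conservative at small `n`: simulated
HWE data at n = 15 rejects at most ~5% of loci at alpha = 0.05.

### Diversity

* `Ho` — fraction of genotyped individuals heterozygous at a locus.
* `pi` (within) — mean pairwise difference over allele copies,
  `2 j (n - j) / (n (n - 1))` with `n` copies and `j` alt copies. The
  n/(n-1) factor makes `pi = 2pq * n/(n-1)` an algebraic identity on the
  same copies.
* `d_xy` (between) — `p1 (1 - p2) + p2 (1 - p1)` from the two sample
  frequencies.

Genome-wide summaries are unweighted means over loci — not means of
chromosome means, because chromosomes carry very different locus counts.
Per-chromosome means support the chromosome-level randomization test and the
Ho-vs-pi correlation check. Percent reduction of diversity is
`100 (1 - Ho_focal / Ho_reference)`, kept at full precision internally and
rounded to the nearest integer for headline reporting.

### Randomization test

Differences in mean heterozygosity between two populations are tested by
pooled resampling: the two vectors (per-chromosome means by default,
per-SNP values optionally) are pooled and repeatedly repartitioned without
replacement into groups of the original sizes; the statistic is the absolute
difference of group means. Ties count as extreme (conservative). With
10,000 draws and no permuted statistic reaching the observed one, the result
is reported as the bound "< 0.0001". An exact mode enumerates all partitions
when C(n, n_a) <= 1e5. Calibration: across 1,000 null pairs the rejection
rate at alpha = 0.05 stays within Monte-Carlo error of 0.05.

### Differentiation and outlier calling

Per-locus F_ST is the Weir & Cockerham (1984) two-population estimator
`theta-hat = a / (a + b + c)` with the among-population (a),
among-individual (b) and within-individual (c) components computed from
sample sizes, allele frequencies and observed heterozygote proportions.
Conventions that matter:

* Negative estimates are **retained** in means and Z-scores; clamping would
  bias both the genome-wide mean and the SD the outlier rule depends on.
* `theta-hat = 1` exactly for a fixed difference with no heterozygotes.
* Loci monomorphic in the pooled pair, or with fewer than two genotyped
  diploids in either population, are undefined and excluded.
* The genome-wide summary is the unweighted mean of per-locus estimates; a
  ratio-of-sums multi-locus form is provided as an option.

Z(F_ST) standardizes per-locus values by the mean and the sample (n-1) SD
pooled across all chromosomes of one comparison; a locus is an outlier when
Z > `z_threshold` (default 5, strictly). The absolute allele-frequency
difference (AFD) and its Z-score are computed alongside as a
cross-validation statistic; their concordance (Pearson/rank correlation and
outlier-set overlap) is reported. Window summaries average theta-hat in
fixed, non-overlapping 1-based 100-kb tiles (no sliding windows — with
transcriptome-derived SNPs clustered inside genes, single fixed windows are
the appropriate summary).

### kNN / medoid scan

Each SNP with a complete vector of pairwise F_ST values (one per population
comparison) is a point in comparison space. The medoid is the observed
vector minimizing summed Euclidean distance to all others; delta-F_ST =
vector - medoid, with positive entries pointing in the local-adaptation
direction of that comparison and negative entries toward reduced divergence.
A SNP is flagged when the distance to its k-th nearest neighbor (default
k = 10) exceeds the `knn_quantile` (default 99.9th percentile) of all such
distances. k, metric and cutoff are not canonical in the literature; both
are configurable, and the quantile rule means the scan always ranks a small
extreme fraction — it is a screening statistic, used here to corroborate
Z-score outliers rather than define them.

### Local diversity profiles

For each outlier SNP, F_ST, within-population pi and between-population
d_xy at the SNP are compared with the means over all SNPs within +-50 kb
(one fixed window). Selection-driven divergence is expected to show elevated
F_ST and d_xy with depressed within-population pi relative to the window.

### Annotation and effect classification

Gene models come from GFF3 (1-based inclusive intervals) plus the reference
FASTA; the spliced CDS is stored in transcript orientation (minus-strand
genes reverse-complemented). SNPs map to their most specific feature (CDS >
UTR > intron > intergenic); a gene is an outlier gene when at least one
outlier SNP maps inside its span, and genes fall into two categories —
containing nonsynonymous outlier SNPs, or synonymous/other only.

For CDS SNPs the reading frame comes from an ORF search over the three
forward frames of the spliced CDS: candidates run from an allowed start
codon ({ATG, GTG, TTG, CTG} by default — ATG plus the standard-code
alternative initiators) to the first in-frame stop (included in the span),
or to the last complete codon when no stop follows (annotated CDS fragments
are often stop-less; this open-3'-end behavior can be disabled). The
longest ORF of at least `min_orf_len` nt (default 30) wins, ties to the
5'-most. The SNP's ref and alt alleles (strand-adjusted) are substituted and
both ORFs translated with the standard genetic code: identical peptides =
synonymous, anything else (including a premature stop) = nonsynonymous. A
substitution in the initiation codon that leaves the peptide unchanged but
destroys the start codon is flagged `start_loss`. Note the frame is the
longest ORF's, not the annotated frame; an annotated-frame mode is implicit
in supplying the spliced CDS directly to `classify_effect`.

## The synthetic-data generator

`simulate_dataset` produces complete datasets — genotypes with per-call
depth, GFF3 gene models, reference FASTA, population table, and a truth
table of planted selected loci — from a single integer seed (one global
`numpy` Generator; identical seeds give byte-identical emitted files).

The model:

1. **Genome** — `n_chromosomes` chromosomes of `chromosome_length_bp` bases
   (random sequence), with `n_genes` non-overlapping genes laid out in
   regular slots; each gene has 1-4 exons, UTRs at the transcript ends and a
   CDS whose length is a multiple of 3, on a random strand.
2. **SNPs** — `ancestral_n_loci` positions placed uniformly inside gene
   spans, with genes weighted by Poisson(`snps_per_gene_mean`) draws. This
   reproduces the within-gene clustering of transcriptome-derived SNPs.
3. **Ancestral frequencies** — symmetric Beta draws truncated so the
   expected minor-allele count in the source sample is at least one. The
   Beta concentration varies by chromosome (uniform on [0.35, 0.9], around
   the U-shaped 0.5 baseline), giving chromosomes genuinely different
   expected diversity as real genomes show; without this, chromosome means
   differ only by sampling noise.
4. **Colonization** — each derived population is founded by `founder_size`
   diploids and drifts `generations_drift` Wright-Fisher generations at that
   size; the founding binomial draw is the first generation, so expected
   heterozygosity decays exactly as `H_t = H_0 (1 - 1/(2N))^t`.
5. **Selection** — `n_selected_loci` CDS loci per derived population
   (distinct per population, or shared with
   `selection_shared_targets=True` to emulate parallel evolution) have
   their post-drift frequency shifted by `selection_target_freq_shift`
   toward fixation of the allele minor in the source, clamped to [0, 1].
   A deterministic shift gives direct control of effect size for power
   studies; realized shifts are recorded in the truth table.
6. **Genotypes and depth** — genotypes are drawn under HWE from the final
   frequencies; depth is gamma-Poisson (negative binomial) with mean
   `mean_depth` (20) and shape `depth_dispersion` (3), and calls are
   additionally dropped at `missing_base_rate` (1%) — together these create
   the depth-dependent missingness the DP filter acts on.

Default scenario: a source of 14 diploids and derived populations of 15 and
12 (a realistic post-QC RNA-seq panel); 20 chromosomes x 1 Mb carrying
1,000 genes and ~50,000 SNPs; founder size 50 drifting 30 generations.
Those drift defaults put the simulation in the regime the analysis is
designed for: pairwise mean F_ST ~0.10 against the source and ~0.19 between
the two derived populations, ~25% diversity loss per derived population,
planted strong-effect loci (realized AFD >= 0.9) reliably exceeding Z = 5
against the source, while the doubly-drifted derived-vs-derived F_ST
distribution is wide enough that neutral loci essentially never do. Stronger
bottlenecks (e.g. 25 diploids for 50 generations, the diversity-decay
validation scenario) inflate the F_ST dispersion to the point where the
Z > 5 rule cannot fire at all — a property of the statistic, not a bug.

What the generator does **not** emulate: linkage disequilibrium (loci drift
independently, even within a gene), coalescent ancestry, recombination,
sequencing reads and genotyping error, allele-frequency correlation between
the two derived populations from shared colonization history, and
reference/annotation errors. Passing tests therefore demonstrate the
correctness and calibration of the statistics under idealized independent
drift — not robustness to LD, shared coancestry (which suppresses
derived-vs-derived outliers in real serial colonizations), or caller
artifacts.

## Numerical choices

* Genotype codes int8; missing = -1; all per-locus statistics mask it.
* Z-scores use the sample (n-1) SD — negligible at genome scale but pinned
  for reproducibility.
* HWE p-values are memoized on (n, allele count, het count); per-population
  sample sizes are small, so genome scans hit a few hundred distinct tables.
* Permutation p-values count ties as extreme with a relative 1e-12
  tolerance; the "< 1/N" reporting convention is preserved in string form.
* The medoid is computed exactly (chunked all-pairs distances), not
  approximated; kNN distances come from a KD-tree.
* Emitted tables use fixed float formatting (%.10g) so reruns are
  byte-identical.
* Windows are 1-based tiles `[k*w + 1, (k+1)*w]`; position 100,001 opens the
  second 100-kb window.

## Validation problem sizes

The test suite validates against independent oracles: exact-fraction
enumeration for the HWE test (all genotype tables up to 20 diploids), a
nested-ANOVA derivation of the Weir-Cockerham estimator (1,000 simulated
loci, agreement to 1e-8; observed agreement is at machine precision),
all-partitions enumeration for the randomization test plus a 1,000-pair
null calibration, codon-by-codon translation with an independent codon
table for 500 random substitutions, and the closed-form heterozygosity
decay law over 20 bottleneck replicates at ~50,000 loci. Replicated
simulation studies (power, specificity, decay) use 10-20 replicates at the
default ~50,000-locus scale; `scripts/acceptance.py` recomputes all of the
above from scratch from one seed.

## Known limitations

* No LD-aware outlier methods or haplotype statistics; every locus is
  treated independently.
* The kNN scan's k, metric and cutoff are screening defaults, not
  calibrated decision thresholds.
* Effect classification trusts the longest ORF; where the true frame
  differs, calls can be wrong in a way the strand-consistency checks cannot
  detect.
* The generator's selection model is a frequency shift, not a per-generation
  selection coefficient; it cannot produce partial sweeps with realistic
  hitchhiking structure (no linked loci).
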