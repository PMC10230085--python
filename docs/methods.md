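# Methods

This note records the models, conventions, and numerical choices behind
`refstab`, and what its synthetic benchmarks do and do not demonstrate.

## Screening statistic

Candidates are screened on the coefficient of variation of transcript
abundance within a tissue group, CV% = 100 · s / x̄, with the sample
standard deviation (n−1 denominator; group sizes are small, so the
unbiased estimator is used) over **all member samples of the group
pooled** — no within-tissue averaging precedes the screen. Two
conventions are deliberately strict inequalities: the expression floor
keeps transcripts with abundance *strictly greater than* the floor (1.5
by default) in every sample, and a candidate passes a group when its CV is
*strictly below* the group cutoff (20% for the all-tissues group, 15%
elsewhere by default). CV is invariant to positive rescaling of a
transcript, so the screen is insensitive to the abundance unit as long as
it is proportional to expression; the floor, by contrast, is in the unit
of the input matrix. A transcript with a zero group mean has no defined
CV; it is flagged and excluded rather than given a sentinel value.

Transcripts are identified by transcript ID throughout (two isoforms of
one gene remain distinct records); gene-level counts deduplicate by gene
symbol. The packaged candidate table (`data/table1_cv.tsv`) carries a
SHA-256 digest checked at load time.

## Amplification efficiency

The standard curve is an ordinary least-squares fit of mean Ct on
log₁₀(concentration); replicate Cts are averaged per dilution point
before fitting (one point per dilution). Efficiency in percent is
E = (10^(−1/m) − 1) × 100; m = −1/log₁₀(2) ≈ −3.3219 gives exactly 100%.
The QC band (default 98–102%) is read **inclusively** at both ends, and
failing assays are flagged rather than deleted so the caller decides what
to drop. r² is reported but never used as a filter. A positive slope
yields a warning (implausible assay), not an error, because screening
runs should surface such assays in the output table.

## Stability algorithms

All four methods operate on the matrix of mean Ct values (technical
replicates are averaged upstream by `reduce_replicates`). Expression
quantities are Q = E^(minCt − Ct) per gene, so max Q = 1; E defaults to
2.0 (the efficiency QC confines assays near 100%) and measured per-gene
efficiencies can be supplied instead. Log-ratios use base 2 throughout.

* **geNorm.** M_j is the mean over partners k of the sample SD of
  log₂(Q_j/Q_k). The gene with the largest M is removed (ties broken by
  gene ID for determinism) and M recomputed until two genes remain; the
  final pair shares rank 1 and the next gene takes rank 2 (dense ranking
  at the top, matching the method's joint-pair reporting). Each gene's
  reported stability is its M at the round of its elimination, the final
  pair's the M of the two-gene round. V(n/n+1) is the SD of
  log₂(NF_n/NF_{n+1}) where NF_n is the per-sample geometric mean of the
  n most stable genes' quantities.
* **NormFinder (ungrouped default).** On y = log₂ Q, each sample column
  is centred on its across-gene mean; with z_i the sample variance of
  gene i's centred profile over samples, the per-gene variance estimate
  is σ̂_i² = max(0, (z_i − Σ_l z_l/(k(k−1))) · k/(k−2)) — unbiased under
  the additive gene + sample + noise model, undefined below k = 3, with
  the negative-variance truncation made explicit. Stability is σ̂_i.
  The opt-in grouped variant applies the same estimator within each
  sample group and adds each gene's absolute inter-group deviation plus
  the within-group standard error, without the original method's
  shrinkage of group differences toward zero — adequate for exploratory
  grouped runs, but the ungrouped estimator is the tested default.
* **BestKeeper.** Descriptives on raw Ct: the method's "SD" is the mean
  absolute deviation from the arithmetic mean (its published convention),
  CV% = 100·SD/mean, and each gene is correlated (Pearson) against the
  BestKeeper index, the per-sample geometric mean of Ct across genes.
  Ranking is by SD ascending; SD > 1 cycle is flagged inconsistent.
  BestKeeper is the one method not shift-invariant in CV% (its SD is),
  because raw Ct means enter the denominator.
* **Comparative ΔCt.** Stability of gene i is the mean over partners j of
  the SD across samples of Ct_i − Ct_j; despite the "2^−ΔΔCt" label this
  screen sometimes carries, it is a ranking by pairwise-difference SD,
  not a quantification formula.

Missing cells are rejected, not imputed: all four methods assume complete
matrices, and silent imputation would bias the SDs the rankings rest on.
Callers drop incomplete genes or samples explicitly (`CtMatrix.dropna`).

## Comprehensive ranking

Per-method ranks (average-rank ties, except geNorm's dense joint-pair
convention, which is configurable) are combined by their geometric mean;
the final ordering is ascending by geometric mean with ties broken
lexicographically by gene ID so output is reproducible. The aggregation
depends only on ranks, hence is invariant to monotone transformations of
any method's stability values and to method order.

## Relative quantification

The efficiency-corrected ratio of a target t in sample s versus a
calibrator tissue is E_t^(Ct_t,cal − Ct_t,s) divided by the geometric
mean over reference genes r of E_r^(Ct_r,cal − Ct_r,s). The calibrator Ct
per gene is the across-animal mean within the calibrator tissue; ratios
are computed per sample (per animal) and the calibrator tissue's own
ratios scatter around 1 by construction. With E = 2 for every gene the
expression collapses exactly to 2^−ΔΔCt. Group comparison runs a one-way
ANOVA on log₂ ratios (ratios are multiplicative; log₂ brings them to an
approximately additive, normal scale), followed by all pairwise pooled-
variance t tests with Bonferroni adjustment, the family being the set of
pairwise tissue comparisons for one target gene; α = 0.05, two-tailed.

## Synthetic data generator

The Ct generator draws Ct(g,t,a,r) = B_g + D_{g,t} + A_a + ε with gene
baselines B_g uniform on [18, 32] cycles, tissue effects D_{g,t} ~
N(0, σ²) drawn **once per (gene, tissue) and shared across animals** —
the stability algorithms must see structured tissue-specific instability,
as in real panels, not i.i.d. noise — an animal effect A_a ~ N(0, 0.3²),
and technical noise ε ~ N(0, 0.15²) per replicate. Planted stable genes
use σ = 0.1 cycles and unstable genes σ = 1.5; the default design is 20
genes (25% stable) × 12 tissues × 5 animals × 3 technical replicates,
mirroring the tissue-panel setting the package targets. The animal-effect
SD (0.3) and technical SD (0.15) are chosen as typical biological-
replicate and triplicate-pipetting scatter for a well-run assay; they are
modeling choices, not literature-anchored values. TPM matrices are
lognormal with log-SD σ solving CV = √(exp(σ²)−1), so realized CVs
converge to the target; dilution series use Ct = b + m·log₁₀(conc) with
m = −1/log₁₀(1 + E/100). All generators are deterministic given a seed.

What the generator does **not** emulate: correlated co-regulation between
genes, tissue-specific technical artifacts (RNA quality, inhibitors),
heteroscedastic Ct noise at low abundance, missing wells, and
compositional coupling between transcripts in TPM space. Passing the
planted-recovery benchmarks therefore shows the algorithms rank
structured tissue variation correctly, not that any particular biological
panel will behave as cleanly.

## Benchmarks and problem sizes

The planted-recovery benchmark runs 50 independent panels at the default
design and requires each method's top 5 to capture ≥ 4 of the 5 planted
stable genes in ≥ 90% of panels, and the comprehensive top 2 to contain a
planted stable gene in ≥ 95%. NormFinder's variance recovery is checked
at k = 10 genes × n = 200 samples: a single panel's per-gene variance
estimate carries ~10% relative sampling noise (so single-panel 25% bounds
fail routinely for any unbiased estimator); the benchmark therefore
averages the estimate over 10 replicate panels, which isolates estimator
bias from sampling noise. Oracle-equivalence tests compare geNorm, ΔCt,
and BestKeeper against independent brute-force double-loop
implementations at 1e−10 absolute tolerance on small random matrices.

## Known limitations

* The grouped NormFinder variant omits the original shrinkage step.
* geNorm reports stability as elimination-round M values; tools that
  report the full-panel M for every gene will differ in value (not in
  order of elimination).
* BestKeeper produces no single canonical "stability value" in its
  original description; ranking here follows SD ascending.
* The pipeline's screening stage demonstrates the screen on synthetic
  lognormal TPM; it makes no attempt to emulate a real transcriptome's
  abundance distribution.
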