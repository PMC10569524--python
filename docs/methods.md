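# Methods

## The hurdle differential-expression model

Single-cell expression of one gene within one cell population is modeled in
two parts. Let y_c be the log-normalized expression in cell c
(ln(1 + 10⁴·count/total), zero exactly when the count is zero), d_c = 1{y_c > 0}
the detection indicator, and x_c the covariate row (intercept, centered
detection rate, optionally sex, genotype).

- **Discrete part**: logistic regression of d on x, fit by IRLS.
- **Continuous part**: Gaussian linear model of y on x restricted to detected
  cells, with the variance profiled out (closed-form OLS likelihood).

Genotype is tested by a likelihood-ratio statistic summing the deviances of
the two components, referred to χ² with df equal to the number of
*non-degenerate* components. A component is degenerate — contributing zero
with zero df — when the detection indicator is constant, the IRLS fit fails
to converge or shows separation (any |coefficient| > 15 on the logit scale),
fewer detected cells remain than continuous-model columns, the genotype
column is not estimable among detected cells (no rank increase over the
reduced design), or the continuous fit is exact. Genes detected in fewer
than `min_cells_detected` (default 3) cells are reported untested.

The "linear mixed model" formula this analysis adopts contains only
fixed covariates (detection rate and sex), so the model here is a
fixed-effects two-part model; no random terms are fit.

Fold changes are log₂((mean CP10K in HET + ε)/(mean CP10K in WT + ε)) with
ε = 0.1, means over all cells including zeros. This ratio-of-means definition
makes the significance threshold of 0.14 log₂ units correspond to a 10%
difference in means (log₂ 1.102 ≈ 0.14), and the relaxed threshold 0.0704 to
5%. BH FDR is computed within each population over its tested genes; the
relaxed significance mode only re-applies thresholds, never refits.

**Calibration.** Under a two-part generating model with zero genotype effect
the LRT p-value is uniform (verified by KS test in the suite). On
negative-binomial counts with logistic dropout — a misspecified but realistic
regime — the test is mildly anti-conservative; the suite bounds the null
type-I rate at twice nominal, which the simulations meet with margin.

## Burden ranking and enrichment

Populations are compared at a fixed cell count: `n` cells per genotype
(default 300) sampled without replacement within each population, sexes
pooled, and DE re-run with the sex covariate removed. "300 per population"
is read as 300 *per genotype* (a balanced design maximizes and equalizes
power across populations); populations short of n in either genotype are
excluded with a reason rather than compared at unequal power.

Enrichment contrasts significant genes of one direction against
non-significant genes (significant genes of the opposite direction are
excluded from both rows), over tested genes with a human homolog, using a
two-sided Fisher exact test. The reported odds ratio is the sample odds
ratio ad/bc. The suite checks the p-value against a full hypergeometric-tail
enumeration for every table with margins ≤ 50.

## CLIP density percentiles

The unit is the binding-*site* count (not nucleotide coverage), normalized to
sites per kb of a configurable length column (gene vs transcript length is a
user choice; the generator supplies `length_bp`). The percentile of gene g is
the fraction of *other* genes with strictly smaller value, so ties rank low
and the statistic is invariant under strictly monotone transforms.

## Reversal scoring

Connectivity-map services compute this score server-side against a
touchstone compendium; this package implements a self-contained analogue
that preserves the standard decision rule (score in [−100, 100], candidates
below −90):

1. Query = up to 150 most-downregulated genes of a DE table (most negative
   log₂FC first, ties broken by gene id). Down genes only, matching the
   focus on downregulation.
2. For each compound, sort its z-vector descending (ties by gene id) and
   compute a weighted KS enrichment score: +|z|ʷ/N_R at query genes,
   −1/(N−N_hits) at misses, ES = running-sum value at maximal absolute
   deviation. Weight exponent w defaults to 1; w = 0 recovers the classic
   unweighted KS statistic.
3. raw = −ES, so down-query genes concentrated among a compound's most
   upregulated genes (reversal) score negative.
4. ncs = raw / mean(|raw|) over compounds of the same sign.
5. τ = sign(ncs) · 100 · (fraction of library compounds with strictly
   smaller |ncs|) — an in-library signed percentile standing in for a
   touchstone compendium. τ of the most extreme compound is ±100·(n−1)/n.
6. Candidates: τ < −90 (strict).

The overlap report gives each list's size, the intersection, the
intersection as an integer percentage of *each* list (either denominator
may be wanted), the top-k (default 20) intersection, and
per-list compound-class composition.

## Phenotype statistics

- **Permuted MWU**: pool both groups, draw n_perm (default 10,000) label
  permutations preserving group sizes, and report the fraction of permuted
  MWU p-values *strictly below* the observed one; zero counts are reported
  as the floor 1/n_perm with a flag. Observed and permuted p-values are
  computed by one internal routine — an exact U-distribution (subset-sum DP)
  when the pool is ≤ 12 and tie-free, otherwise the tie-corrected normal
  approximation with continuity correction — so the comparison is
  internally consistent; the public `mann_whitney_u` wraps scipy and agrees
  in both regimes.
- **Trial averaging**: each trial clipped to [min, cutoff] (cutoff 30 s;
  the vertical screen also has a 1 s minimum) before averaging; failures
  score the cutoff.
- **iRMS** = √frequency · pulse_width · duration · amplitude, reading the
  square root as applying to frequency only (the literal operator order of
  the formula as usually stated); the whole-product reading is available behind a
  flag since the grouping is ambiguous as printed and no worked output
  exists to discriminate.
- **ΔΔCt**: single-pass replicate filter (if SD > 0.3, drop replicates more
  than one SD from the mean; require ≥ 2 survivors), ΔCt = target − reference
  mean Ct, baselined on the batch-mean WT ΔCt, RQ = 2^(−ΔΔCt).
- **Mendelian χ²**: Pearson test of observed genotype counts against a
  normalized expected ratio (1:2:1 for an intercross), df = categories − 1.

## The synthetic-data generator

The generator emulates the study design the analysis assumes: two genotypes
× two sexes, several cell populations per region, and planted
cell-type-specific effects concentrated in one vulnerable population.

- **Counts**: NB(mean, dispersion) per gene with gene-level means log-uniform
  on [0.2, 8] counts/cell and dispersions log-uniform on [0.5, 4]; a
  lognormal per-cell size factor (sd 0.15); the genotype effect multiplies
  mutant means by 2^log₂FC in affected (gene, population) pairs; dropout is
  Bernoulli with logit linear in the log mean (midpoint −1, slope 1, i.e.
  ~50% dropout at mean ≈ 0.37 and ~12% at mean 2). These defaults give
  cells detecting a few hundred of 1,500 genes and ≥ 80% power for
  |log₂FC| ≥ 1 at 300 cells/genotype — the regime the recovery suite tests.
- **Effects**: magnitudes |N(0.8, 0.3)|, sign negative with probability 0.73
  (mirroring the observed downregulation asymmetry, and exercising the
  direction-stratified code paths); the vulnerable population receives an
  elevated planted fraction.
- **Mitochondrial block**: a designated gene block whose per-cell totals are
  set to hit a target fraction drawn uniformly inside the configured range,
  so QC thresholds are exercised deterministically.
- **Annotations**: ~10% of genes carry the excluded-class flag (the
  non-coding/ribosomal/pseudogene proxy), ~90% a human homolog; disease gene
  sets are sampled with extra weight on genes planted down in the vulnerable
  population so enrichment recovery is end-to-end testable.
- **Reference library**: reversers are the negated disease-effect vector plus
  N(0, 0.25) noise, mimics the positive copy, the rest standard normal.
- **CLIP sites**: Poisson(λ·kb) per gene (λ = 2/kb) with one designated gene
  at 50λ + 5 per kb, guaranteeing a > 99th-percentile density.
- **Phenotypes**: 16 subjects per genotype with additive mutant shifts per
  measure; latencies clipped at 30 s.

What the generator does **not** emulate: batch effects, ambient RNA,
doublets, UMI collisions, donor structure, or realistic gene-gene
correlation. Passing tests therefore demonstrate the statistical machinery
is correct and well calibrated under the assumed model, not that the model
captures every property of real tissue data.

## Problem sizes and determinism

Simulated problem sizes are chosen so the whole suite runs on one CPU in a
few minutes: null calibration at 2,000 genes × 600 cells, recovery at 1,000
genes × 600 cells, burden recovery over 20 seeded runs of 5 populations ×
640 cells each, permutation calibration over 200 runs × 1,000 permutations,
and a demo pipeline of 6 populations × 700 cells × 1,500 genes. Every source
of randomness flows through explicit integer seeds (numpy `default_rng` with
fixed SeedSequence branches per generator), so identical configurations give
bit-identical artifacts and byte-identical TSV outputs.

## Known limitations

- The hurdle test is mildly anti-conservative on overdispersed counts with
  dropout (bounded in the suite at ≤ 2× nominal); a donor-level random
  effect is out of scope (the adopted covariate formula has no random term).
- τ is an in-library percentile: with few compounds it is coarse
  (granularity 100/n), and candidate counts depend on library composition.
- The log₂FC definition (ratio of CP10K means with ε = 0.1) is one
  consistent reading; coefficient-based effect sizes would differ for
  weakly detected genes.
- QC gene-count gates (1,000–5,000 detected genes) are tuned to real 10x
  data; the demo configuration scales the lower gate to the synthetic
  detection regime.
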