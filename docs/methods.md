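# Methods

## Design

The package analyses matched two-tissue DNA methylation cohorts: every
individual contributes a beta-value profile in each of two tissues (called
BEC and PBMC throughout, after the motivating buccal/blood design) plus an
array genotype profile. Two cohorts are expected — a larger discovery cohort
and a smaller validation cohort (defaults emulate n = 79 and n = 16) — and
all headline outputs (informative sites, validated cis-mQTL, differential
CpGs) are cross-cohort consensus calls.

## Synthetic data generator

Because the real cohorts of this design are restricted-access, the generator
in `simulate.py` is first-class, tested code: it defines the study
conditions every downstream claim is evaluated under.

Generative model, per CpG *j*, tissue *t*, individual *i*:

1. **Baseline** `b_j` from a bimodal mixture (42 % Beta(2,12)-low,
   42 % Beta(12,2)-high, 16 % uniform mid-range), clipped to [0.02, 0.98] —
   echoing the U-shaped beta distribution of methylation arrays. Planted
   differential CpGs (fraction 0.35, roughly the share observed in such
   designs) receive a tissue offset `δ_j` with |δ| ∈ [0.05, 0.30], split
   ± δ/2 between tissues, random sign.
2. **Individual effect** on the logit scale:
   `logit(signal) = logit(b_jt) + σ_t · z_ij` with σ_BEC = 0.6 >
   σ_PBMC = 0.3 by default (the BEC-like tissue is planted as roughly twice
   as variable). For a fraction (0.15) of CpGs flagged *shared-variable*,
   the same standard-normal draw `z_ij` is used in both tissues — these are
   the planted informative sites; all other CpGs draw independently.
3. **Genotype effect**: mQTL CpGs (default 4 % each BEC-specific,
   PBMC-specific, shared) add `dosage × effect` on the beta scale,
   effect ∈ [0.03, 0.15] per allele, then clip — so "DNAm change per
   allele" is directly the planted quantity the scan estimates. mQTL CpG
   baselines are drawn mid-range (0.2–0.55) so additive effects stay
   on-scale and slope estimates stay unbiased.
4. **Cell mixing**: each tissue has 3 simulated pure cell profiles (the
   CpG signal plus a type-specific beta offset, sd 0.08, at 20 % of CpGs);
   observed values are Dirichlet(α = 5)-weighted averages per sample. Pure
   profiles are themselves simulated; no attempt is made to mimic probe-level
   450K chemistry.
5. **Measurement noise** on the logit scale (sd 0.08 ≈ 0.02 in beta units
   at mid-range), which also keeps values inside [0, 1].

Genotypes are drawn at Hardy–Weinberg proportions from MAF ∈ [0.05, 0.5];
a configurable 2 % of (non-mQTL) SNPs are generated with forced excess
heterozygosity to exercise the HWE filter. CpGs sit on two synthetic
chromosomes at 20 kb spacing; each mQTL CpG's SNP is placed at a random
offset of 1–4999 bp, and every other SNP mid-gap, so a SNP–CpG pair is
within the 5 kb cis window exactly when it was planted.

Truth (baselines, effects, flags, MAFs, layout) is shared across cohorts;
individuals are independent draws — so discovery→validation coherence is a
meaningful planted property. All randomness flows from one seed through
named substreams; identical config ⇒ byte-identical output.

**What passing tests do and do not show.** The generator produces additive,
roughly symmetric effects with homogeneous noise and no age structure, batch
effects, probe-type chemistry, linkage disequilibrium between SNPs, or
missing-not-at-random patterns. Recovery on these data demonstrates the
statistical machinery is implemented correctly and calibrated; it does not
certify power or error rates on real arrays. Cohort-level variability
differences attributed to age in real data are not modelled; per-tissue
logit SDs are exposed instead of an age covariate.

## Statistical conventions

* **Percentiles** (reference range): linear interpolation between order
  statistics (numpy/R "type 7"). This matters at n = 16; it is fixed and
  tested against an independent sort-and-interpolate oracle.
* **Spearman ρ**: midranks for ties, Pearson on ranks, two-sided p from the
  t approximation with n − 2 df (the same large-sample reference
  scipy.stats.spearmanr uses); constant vectors yield missing ρ. Computed
  row-vectorised; verified against scipy per-pair.
* **Paired Wilcoxon signed-rank** (probewise): zero differences dropped
  ("wilcox" rule), normal approximation with tie correction, no continuity
  correction — matching `scipy.stats.wilcoxon(method="approx")`, which the
  tests assert per probe. The single global reference-range comparison
  calls scipy directly (exact at small n without ties). All-zero-difference
  probes get p = 1 and a degenerate flag.
* **Fligner–Killeen**: the standard construction (median-centred absolute
  deviations, pooled midranks, normal quantile scores, χ²(1)), vectorised
  across probes and asserted equal to `scipy.stats.fligner` row by row.
* **BH FDR** via statsmodels, always within one tissue × cohort × analysis
  test set, never pooled across tissues.
* **HWE exact test**: enumeration of the heterozygote-count distribution
  conditional on allele counts, p = sum of probabilities ≤ the observed
  outcome's. Threshold default 1e-3 (commonly used; configurable — the
  level is a QC choice, not an inferential one).
* **Mixture threshold**: two-component Gaussian mixture on ρ of CpGs with
  RR > 0.10 in both tissues (EM, k-means++ init, 10 restarts, tol 1e-8,
  max 500 iterations, seeded). ρ spans negative values, so a Beta family
  on raw ρ is not defined; a logit-((ρ+1)/2) Gaussian variant is available
  (`family="beta"`) as a sensitivity analysis — its cutoff is the
  back-mapped μ − 2σ quantile and differs numerically from the default
  because the two scales weight the component's skew differently. The
  threshold uses the fitted component parameters (not the empirical SD of
  posterior-assigned members — the documented alternative). Fits whose
  component means are closer than 0.05 or that fail to converge raise a
  degenerate-fit error; the pipeline maps that to an empty informative set,
  which is the correct call when no concordant component exists.
* **Effect size**: OLS slope of beta on 0/1/2 dosage (equal to half the
  homozygote-mean difference under balance); a `homozygote_half` estimator
  is available behind a flag. Rank-based association is invariant to the
  0/1/2 vs 1/2/3 coding choice (tested).
* **Permutation p-values**: add-one convention (1 + #{null ≥ obs})/(N + 1);
  never zero, floor 1/(N + 1), agreeing with the exact hypergeometric tail
  within Monte-Carlo error on small instances. Null draws are uniform over
  the supplied background; stratified draws (e.g. by CGI relation) are
  available behind a flag. Background sets are always explicit arguments.
* **Boundary rules**: hit/significance filters are inclusive (FDR ≤ 0.05,
  |effect| ≥ 0.025, |Δβ| ≥ 0.05) — the inclusive/exclusive choice only
  moves exact-boundary ties. The cis window is strict (< 5000 bp).
* **Subsampling study**: without-replacement subsets of matched
  individuals, per-probe statistics recomputed per trial, arithmetic mean
  across trials — including of p-values, reproducing the upstream
  construction verbatim even though averaging p-values is statistically
  unusual; a geometric-mean option exists but is off by default.
* **Cell adjustment**: proportions by nonnegative, sum-to-one least squares
  (NNLS on an augmented system with a 1e4-weighted constraint row, then
  exact renormalisation — equivalent at this pipeline's level to the
  quadratic-programming formulation of reference-based deconvolution and
  exact on noiseless mixtures). Residualisation drops one proportion column
  (results invariant to which, given sum-to-one), adds back intercept plus
  mean composition contribution, clips to [0, 1] and reports clipped-cell
  counts. The pipeline applies it only when reference profiles are
  supplied; the synthetic generator mixes cell types but does not export
  pure profiles, so default synthetic runs leave composition in the data as
  (realistic) extra noise.

## Pipeline and thresholds

`run_all` executes: probe QC (flags → detection p > 0.01 in > 2 % of
samples → missingness > 2 %, a fixed order so report counts are
deterministic; a probe failing in either tissue is dropped from both) →
cross-cohort probe intersection → optional cell adjustment → variability →
subsampling study (n = 16 × 100 trials of the discovery cohort) →
concordance and informative consensus → SNP QC and cis-mQTL
discovery/validation/sharing → differential consensus (discovery,
validation, and the subsampled dataset, the last using trial-averaged
p-values) → permutation enrichment → categorization. Stage seeds are
SHA-256 derivations of the global seed and stage name, so stages can be
re-run in isolation reproducibly.

Defaults: RR filters 0.05 (informative, mQTL) and 0.10 (mixture subset),
cis window 5000 bp, FDR 0.05, min effect 0.025/allele, min Δβ 0.05, 10,000
permutations, SNP QC missingness 0.05 / MAF 0.05 / HWE p 1e-3, validation
min heterozygotes 2.

## Problem sizes and expected recovery

Tests and the acceptance script run the integrated pipeline at 20,000 CpGs ×
5,000 SNPs with cohorts of 79 + 16 — large enough that every stage
(including both permutation analyses at 10,000 draws and the 100-trial
subsampling study) runs at full fidelity while the whole suite stays quick
on a single core. Under the default conditions, expected recovery differs by
construction across stages: PBMC-tissue mQTL sensitivity is high (individual
variation sd 0.3 on the logit scale), BEC sensitivity is lower (sd 0.6
drowns the smallest 3 % effects), consensus differential sensitivity sits
near 0.8 (planted |Δβ| near the 0.05 boundary is genuinely underpowered at
n = 16), and discovery-vs-validation effect correlation is modest because
n = 16 slope estimates are noisy — the dedicated low-noise coherence test
shows ρ ≥ 0.9 when estimation noise is small relative to the effect spread.
Informative-site precision is near 1 while sensitivity is partial: the
mixture cutoff is conservative by construction (μ − 2σ of a tight
concordant component) and the consensus intersects two cohorts.

## Known limitations

* No IDAT/array-level preprocessing (detection-p input is accepted, not
  computed); normalization (BMIQ, color correction) is upstream scope.
* No trans-mQTL, genotype imputation, LD modelling, or region-level (DMR)
  calling.
* Cross-hybridization and polymorphic-target blacklists are accepted as
  manifest flags, not recomputed.
* The per-SNP empirical MAF of simulated genotypes matches truth only up to
  binomial sampling error (SE ≈ 0.04 at n = 79 for common alleles); tests
  assert the mean absolute error, not a per-SNP bound.
* `validate` computes FDR over the validation test set only (consistent
  with re-running the analysis in the validation cohort); a joint
  discovery+validation FDR is the documented alternative.
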