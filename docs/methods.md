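# Methods

## Scope and data model

polyscore analyses biallelic candidate-SNP panels in a case–control
design. A panel row fixes, per SNP: the major allele (allele 1), the
minor allele (allele 2) and the *favorable* allele — the allele
associated with the phenotype of interest. The major/minor designation
is taken from the panel file and never re-derived from data: the
packaged 15-SNP walking-pace panel encodes the designation used in the
source cohort, which makes every downstream statistic reproducible
regardless of the allele frequencies of the cohort being analysed.

Genotypes are stored as allele-2 dose codes (0/1/2, NaN for missing).
This is the single canonical coding; conversion to favorable-allele
doses (identity, or 2 − dose when the favorable allele is the major
one) happens only inside the scoring layer, so no file format ever
carries two codings.

### Count reconstruction from printed percentages

Published genotype tables report percentages of group sizes, not
counts. `counts_from_percentages` inverts the printing: each count is
round(pct/100 · n) with ties rounded half away from zero. If the
rounded counts miss n by exactly one — which happens when a printed
cell itself carries a typo — the cell whose rounding is least
justified is adjusted (largest-remainder repair) and the repair is
logged; a discrepancy of more than one raises, treating the table as
inconsistent. Row sums are accepted within ±0.5 of 100 because one
packaged row (rs1667369, sprinters) prints cells summing to 100.5; the
repair resolves that row to counts consistent with the SNP's published
allele frequency, and the package treats the allele frequency as the
authoritative figure. Reconstructed counts reproduce the published
favorable-allele percentage of every panel SNP in both groups to 0.1
percentage points.

### VCF import

Variants are matched by the VCF ID field. Alleles must equal the panel
pair literally or as a REF/ALT swap (in which case the dose is
flipped); anything else — including potential strand flips — drops the
SNP with a warning rather than guessing. Multi-allelic records are
dropped likewise.

## Association battery

Per SNP, the case and control genotype counts feed four contrasts:
allele (2×2 of allele counts), codominant (2×3 of genotypes), dominant
(major-homozygote vs carrier) and recessive (minor-homozygote vs
rest).

Conventions, chosen once and logged per decision at INFO level:

* **No Yates continuity correction.** The uncorrected allele-model χ²
  reproduces the source study's printed p-values at printed precision
  (e.g. χ² = 16.89 → 4e-05); the corrected statistic does not.
* **Fisher fallback** (Cochran's rule): a 2×2 table with any expected
  cell < 5 is tested exactly. The exact two-sided p sums
  hypergeometric probabilities of tables no more probable than the
  observed one. The 2×3 codominant table always uses χ² after
  empty-column removal (with df reduced); a table collapsing to fewer
  than two non-empty columns is recorded as degenerate (statistic 0,
  p 1) across all models.
* **HWE screening** at p < 0.05 per group, via the 1-df χ² of observed
  genotype counts against p²/2pq/q² expectations at the sample allele
  frequency. Screened-out SNPs skip the association battery but remain
  eligible for polygenic scoring (equilibrium failure questions the
  single-SNP test, not the additive score).
* **Two-sided tests throughout.** Direction of association is read off
  the sign of the favorable-frequency difference, not from one-sided
  testing.
* **Bonferroni**: α / (SNPs × models). The SNP count of the family is
  configurable (`bonferroni_snps`) because a study may score a panel
  subset while correcting for every SNP genotyped.

Two frequency-difference conventions coexist deliberately:
`freq_diff` is the exact difference of proportions (satisfying the
invariant diff = f_case − f_control to machine precision), while
`freq_diff_printed` subtracts the two percentages after rounding each
to one decimal — the convention of the source tables, needed to
reproduce their difference column digit for digit.

## Total genotype score

With K panel SNPs, the favorable homozygote scores 2, the heterozygote
1, the other homozygote 0; TGS = 100 · Σscores / (2K). Missing
genotypes shrink the denominator to the SNPs actually observed (the
maximum score the sample could have attained); samples missing more
than 20% of the panel are flagged. All SNPs carry equal weight — the
method is an unweighted allele count, not an effect-size-weighted
polygenic score.

Cohort descriptives mirror the published table row set: n, min/max and
mode on both the score and allele-count scales (mode ties report the
smallest count), mean, SD (n−1), adjusted Fisher–Pearson skewness
G1 = g1·√(n(n−1))/(n−2) and bias-corrected excess kurtosis G2, with
the classical normal-theory standard errors
SE_skew = √(6n(n−1)/((n−2)(n+1)(n+3))) and
SE_kurt = 2·SE_skew·√((n²−1)/((n−3)(n+5))). These formulas reproduce
the source study's printed SEs (0.207/0.411 at n=137, 0.216/0.428 at
n=126), which identifies them as the conventions its software used.
Shape moments are reported as undefined for n < 4 or zero variance.

Under SNP independence the score has closed-form moments: mean
(100/K) Σ p_k and variance (100/2K)² Σ [4P(hom_fav)+P(het) −
(2P(hom_fav)+P(het))²]. The empirical cohort mean equals the
closed-form mean evaluated at the cohort's own genotype distribution
exactly (an identity, tested as such); the SD converges only in
distribution.

## Discrimination

AUC is the normalized Mann–Whitney U: P(case > control) + ½P(tie).
The 95% CI uses the Hanley–McNeil standard error, truncated to [0,1];
DeLong-style alternatives were not needed at the precision of the
reproduced quantities. The no-discrimination p-value is the
tie-corrected asymptotic Mann–Whitney test.

The cutoff sweep dichotomizes at every observed score ("≥ cutoff"
predicts case), reporting the 2×2 table, sensitivity/specificity,
Youden index (the annotated optimum; smallest cutoff on ties), and the
odds ratio ad/bc with Woolf logit 95% CI. A zero cell triggers the
Haldane–Anscombe +0.5 correction, flagged; a fully empty margin line
is an error in strict mode and a flagged corrected estimate inside the
sweep. Both Fisher-exact and χ² p-values are attached, since published
cutoff p-values rarely state which was used.

## Quantitative-trait regression

OLS of phenotype on favorable-allele dose (0/1/2) plus covariates,
two-sided t-test on the dose coefficient. Additive coding is the
default; dominant/recessive recodings sit behind a flag. Percentages
are regressed untransformed (matching how fiber-type compositions are
reported); constant dose vectors and rank-deficient designs raise.

## Synthetic cohorts

`simulate_from_distributions` draws each SNP independently from
per-group genotype probability triples; `table2_group_model`
parameterizes it with the packaged distribution table at the study
sizes (137/126). `simulate_under_effects` draws controls under HWE at
given allele frequencies and enriches cases through per-allele odds
ratios: odds(case) = OR · odds(control), both groups in HWE at their
frequencies. With OR = 1 the two generators coincide in distribution.

Randomness is one cohort-level seed, from which an independent
`SeedSequence` stream is spawned per (group, SNP) — appending a SNP to
a panel never perturbs earlier columns, so truncated-panel draws are
prefixes of full-panel draws.

The fiber-type generator produces fast-twitch percentage = baseline +
slope·dose + γ·(age − mean age) + N(0, σ), truncated to [0,100], with
defaults at the biopsy-cohort scale of the source study: n = 67,
baseline 49.4%, σ = 17.7%, age 32.9 ± 8.9 years, allele frequency
0.155 (the favorable-allele frequency of the one fiber-associated SNP
in controls), slope 6 percentage points per allele as the working
effect size, and γ = −0.2 %/year reflecting the gradual age-related
shift away from fast-twitch fibers.

What the simulators deliberately do not model: linkage disequilibrium
(the packaged SNPs span 11 chromosomes), population structure,
genotyping error or missingness, and hybrid muscle fibers (fiber
percentages are a single response). Passing simulation-based tests
therefore demonstrates correctness of the statistics under
independence, not robustness to stratified or LD-structured cohorts.

## Problem sizes and numerical choices

Simulation-backed checks use: 100,000 per group for the
distribution-driven AUC (binomial SE ≈ 0.001), 50,000 for
law-of-large-numbers moment convergence (tolerance 0.2), 10,000 per
group for odds-ratio-driven AUC bands, 1,000 replicates for type-I
error calibration (0.05 ± 0.02) and 400 for regression power against
the closed-form noncentral-t benchmark. Exact identities (orientation
flip s → 100−s, cohort mean = closed-form mean, Fisher =
enumeration, AUC = pairwise count) are tested to 1e-9 or tighter.

Known limitations: distribution *shape* statistics (SD, skewness,
kurtosis) of the original cohorts cannot be rebuilt from printed
marginals because they depend on cross-SNP genotype correlations in
the real individuals; the package checks them only on synthetic
cohorts and through the closed-form identities. Logistic regression
with covariates for case–control status, LD-aware scoring and
weighted polygenic scores are out of scope.
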