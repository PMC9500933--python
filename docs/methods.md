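# Methods

## Model and scope

`hybridprs` implements additive polygenic scoring for diploid, biallelic
genotype panels and extends it to predicted offspring of planned crosses.
The additive model is the working assumption throughout: a trait value is
a weighted sum of allele dosages plus environment, weights are marginal
GWAS effect sizes, and dominance/epistasis are out of scope — consistent
with predicting narrow-sense genetic merit, not total hybrid performance.
The intended panels are collections of wild or industrial yeast isolates
that are homozygous at almost every site, which is exactly the regime
where offspring genotypes — and hence offspring scores — are nearly
determined by the parents.

## Scoring and marker selection

The score is PRS = Σᵢ β̂ᵢ E[dᵢ] over the selected risk markers, with
E[d] = Σⱼ wⱼ j the expected dosage under the per-locus genotype
distribution (one-hot for observed hard calls). Markers enter the risk
set when their association p-value is ≤ the threshold *P*ᴛ. Selection is
by p-value only; effect sizes are used untransformed (no shrinkage), and
scores are reported raw (unstandardized) because the downstream regression
of phenotype on PRS is scale-invariant in R².

LD clumping is available (greedy by ascending p; a marker is removed when
a retained marker within the window on the same chromosome exceeds the r²
ceiling; ties in p resolve to genome order) with defaults r² = 0.1,
window = 250 kb, but it is **off** by default in the scoring path: in
near-homozygous panels with modest marker counts the threshold scan alone
determines the score, and clumping is an explicit opt-in (`--clump`).

Missing genotypes are preserved by every reader and resolved only at
scoring time: the default policy mean-imputes a missing call with the
panel mean expected dosage at that marker (the convention of standard
scoring tools); `drop` skips the marker for that sample. A sample with no
usable marker is reported as unscored (missing), never as 0. The optional
panel filter drops markers with minor-allele frequency ≤ 5% by default.

Per-marker variance explained is computed from summary statistics as

PVE = 2β̂²f(1−f) / (2β̂²f(1−f) + se²·2n·f(1−f)),

with f the effect-allele frequency and n the association sample size —
the standard summary-statistics estimator; it requires f and n and
refuses to guess them. Set-level PVE is the sum over markers, capped at 1
with a warning, and is only meaningful when the markers are approximately
independent.

## Threshold search

`scan_thresholds` scores the panel at every threshold of a grid and
records the R² of the OLS regression of phenotype on PRS. The default
grid unions broad anchors {5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3,
0.4, 0.5, 1} with a dense sweep in steps of 5×10⁻⁵ up to 0.5, so
fine-grained optima (e.g. 0.37885) are exactly representable; the step is
configurable. Because the marker set at a larger threshold contains the
set at a smaller one, the scan accumulates per-marker contributions once,
in ascending-p order — the full ~10⁴-point curve costs a single pass over
the markers plus one correlation per grid point. The best threshold
maximizes R²; exact ties resolve to the smaller threshold (the more
parsimonious marker set), making the output deterministic. A threshold
that admits no markers is recorded with R² = 0 and flagged.

An important caveat the package's own validation respects: when the
summary statistics are estimated on the *same* samples being scored, the
in-sample R² curve increases essentially monotonically with marker count
(every marker's fitted sign aligns with the phenotype in-sample), the
best threshold drifts to 1.0, and the R² at the optimum says nothing
about heritability. Threshold-scan behaviour is therefore validated
out-of-sample — association statistics from one half of a panel, scan on
the held-out half — which is also the deployment setting, where summary
statistics come from an external GWAS. `fit_prs_phenotype` reports the
OLS slope, intercept, R², two-tailed p and 95% confidence intervals, plus
a Kolmogorov–Smirnov normality p-value for the residuals as a diagnostic
that never gates the fit. No covariates enter by default.

## F1 genotype estimation and uncertainty

With parental dosages d₁, d₂ ∈ {0, 1, 2}, the estimated offspring
genotype is the Mendelian expectation (d₁+d₂)/2 — the fractional values
0.5 and 1.5 are expectations over gametes, not observable genotypes, and
the score is linear in them, so the predicted F1 PRS equals the mean of
the parental PRSs identically. Per locus, the feasible offspring dosages
under segregation without recombination are e.g. D(1,1) = {0,1,2},
D(2,1) = {1,2}, D(0,2) = {1}; the [min, max] PRS bounds take the
feasible dosage minimizing/maximizing βd per locus (signs respected), and
`enumerate_offspring_prs` convolves the per-locus gamete laws into the
exact offspring PRS distribution, guarded at 20 uncertain loci (3ᵏ
outcomes). A locus where either parent's genotype is missing is skipped
for that cross and logged — with few crosses and many loci, imputation
would inject more bias than the skipped locus is worth. The
genotype-combination census classifies each locus into the six unordered
parental combinations (AA×AA … aa×aa) and reports the both-parents-
homozygous fraction as mean ± sd across crosses.

## Heterosis

BPH = F1 − BP, MPH = F1 − MPV, DEP = WP − F1 (BP/MPV/WP the parental
max/mean/min). Flags use strict inequalities — a cross exactly at the
mid-parent value shows no heterosis — and the identity MPH = (BPH−DEP)/2
holds algebraically. Group contrasts compare the PRS of crosses with a
flag set against the complement **within the F1 set**; the rank-sum test
uses the exact null distribution when both groups have ≤ 50 untied
observations and the tie-corrected normal approximation with continuity
correction otherwise (matching R's `wilcox.test`, whose W convention —
rank sum of group 1 minus its minimum — is reported). Two identical
constant groups are a degenerate case answered symmetrically
(W = n₁n₂/2, p = 1).

## Synthetic data

The generator emulates the target study design. Genotypes: per variant an
allele frequency f ~ Uniform(0.05, 0.5) and inbreeding coefficient F,
with dosage probabilities P(2) = f² + Ff(1−f), P(1) = 2f(1−f)(1−F);
F = 0.95 by default, reproducing the near-total homozygosity of wild
yeast panels (the default panel shows ~96% of loci with both parents
homozygous), F = 1 giving fully homozygous panels and F = 0
Hardy–Weinberg. Phenotypes: standard-normal effects on `n_causal` loci
(default 100 of 2000), environmental noise scaled so Var(g)/Var(y) = h²
(default 0.5). The association scan is per-variant simple OLS — adequate
for unstructured synthetic panels; it does not model relatedness or
population structure, which real panels require a mixed model for.
Crosses sample one gamete per parent per locus independently (no
linkage). All generators are seed-deterministic.

What passing synthetic tests do **not** show about real data: robustness
to population structure and cryptic relatedness in the GWAS, LD between
causal and tagging markers (variants are simulated independently),
genotyping error, and non-additive trait architecture. The Mendelian
algebra (linearity, bounds, enumeration) is exact regardless; the
statistical performance numbers are specific to the simulated
architecture.

## Numerical and design choices

- Dosages are floats with NaN for missing; every non-missing panel entry
  is validated to be 0/1/2 at construction.
- PLINK BED v1.00 SNP-major is encoded/decoded directly (2 bits per
  genotype, 4 samples per byte, low bits first); round trips are
  bit-exact including missingness.
- Harmonization flips dosage (d → 2−d) rather than negating β when the
  summary-statistics effect allele is the panel's other allele — scores
  then differ from the β-negation alternative only by the constant
  2Σβ over flipped markers, preserving rankings. A/T and C/G palindromic
  markers are dropped under the default strict policy since their strand
  cannot be resolved; a single internally consistent matrix may keep them
  via `keep-palindromic`.
- Validation problem sizes: 2000-sample × 2000-marker panels with 100
  causal loci for scan recovery (10 seeds per h² level, association half
  vs scan half), 20 seeds for null calibration, 10,000 offspring draws
  for segregation ratios — chosen to make Monte-Carlo noise small
  relative to the asserted effects while keeping the suite quick on a
  single CPU.

## Known limitations

No recombination or linkage in gamete simulation; no phased haplotypes,
imputed (non-integer) input dosages, BGEN/PGEN, or multiallelic sites; no
covariates or principal components in the threshold-search regression; no
shrinkage/Bayesian scores; no permutation-based empirical p-value for the
selected threshold (the reported best-threshold R² is selection-biased —
interpret it against a held-out panel). PRS ranks expected additive
merit; it cannot quantify the degree of heterosis, which is driven partly
by non-additive effects outside the model.
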