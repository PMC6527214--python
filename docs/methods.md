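# Methods

## The measurement model

A two-choice CAFE vial holds a fixed group of flies and four graduated
capillaries: two with plain sucrose medium, two with drug-supplemented
medium.  Consumption is read as the drop of the liquid column in mm
(1 mm = 0.067 μl for the 5 μl capillaries assumed here; the constant is
exposed as `traits.UL_PER_MM`).  Column drop also occurs without flies,
so each chamber carries an identical set of fly-free control vials.  The
correction subtracts, per capillary, the mean of all control capillary
readings in the same (exposure, solution) stratum, clamps each corrected
capillary at zero — negative intake is physically impossible — and sums
the two same-solution capillaries into the vial's consumption.  The
correction granularity (stratum mean rather than a single pooled scalar)
preserves solution- and exposure-specific evaporation; assay protocols
generally do not specify this, so it is a package choice.

Twelve traits are computed **per vial** and then averaged into line
means: consumption of each solution at the first and third exposures,
the two change scores (third minus first, so positive = more consumed
after repeated exposure), Preference A = drug − sucrose (mm),
Preference B = (drug − sucrose)/(drug + sucrose) at both exposures, and
the changes of both preferences.  Preference B is undefined at zero
total intake and is recorded as missing and excluded from that trait's
line mean, rather than being forced to zero.  The per-vial-then-average
convention follows from the vial being the experimental unit (the ANOVA
residual is between-vial variance); for Preference B it differs from a
ratio of line-mean consumptions, and the difference can matter at very
low intakes.

## Mixed-model ANOVA with expected mean squares

The full model for consumption is

    Y = μ + L + E + S + X + (all two-, three- and four-way
        interactions) + ε

with line L random and exposure E, solution S, sex X fixed.  The engine
is balanced-only: sums of squares are computed by inclusion–exclusion
over marginal cell means, the classical decomposition for which
sequential and marginal (Type I/III) sums of squares coincide.
Unbalanced data raise an error listing deficient cells instead of
silently switching estimators, because the method-of-moments identities
below hold only for balanced data.

Expected mean squares use the **unrestricted** mixed-model convention:
any term containing at least one random factor is a random term, and its
component σ²\_U appears in E[MS(T)] for every T ⊆ U with coefficient
N / (product of level counts of U's factors); fixed terms contribute a
quadratic form only to their own EMS.  Under this convention, for the
panel design above, E[MS(L)] = σ²ε + 120 σ²\_L + 40 σ²\_{L×E} + … +
10 σ²\_{L×E×S×X}, and the test denominator for L is the exact
combination MS(L×E) + MS(L×S) + MS(L×X) − MS(L×E×S) − MS(L×E×X) −
MS(L×S×X) + MS(L×E×S×X).  Denominators are synthesized generically by
triangular elimination over components in order of interaction depth,
which terminates exactly for any full factorial; a non-positive
synthesized denominator (possible with strongly negative components)
yields a flagged missing F rather than a negative one.  Denominator
degrees of freedom use Satterthwaite's approximation
(Σ cᵢMSᵢ)² / Σ (cᵢMSᵢ)²/dfᵢ.  The restricted convention was rejected
because it cannot simultaneously reproduce the F ratios, component
estimates and standard errors of reference analyses of this design;
the unrestricted convention reproduces all three (see the acceptance
tests).

Variance components are method-of-moments: the EMS system over the
random terms plus residual is solved against the observed mean squares.
Each estimator is a signed combination Σ cᵢMSᵢ, with standard error
√(Σ cᵢ²·2MSᵢ²/dfᵢ) from the independence and scaled-χ² distribution of
balanced-data mean squares.  Negative estimates are truncated to zero
with a flag — no constrained re-fit of the other components — and the
SE is reported as zero for truncated terms, with the raw estimate and
raw SE retained.  A constrained REML fit (what a mixed-model package
such as lme4 would do) shifts the remaining components by a few percent whenever a
truncation occurs; that divergence is inherent to the estimator choice
and is documented rather than hidden.  P-values are reported unadjusted;
multiple-testing control belongs to the association stage.

## Heritability and correlations

Broad-sense heritability sums every random component whose term involves
the line factor (post-truncation) as genetic variance ΣG:
H² = ΣG/(ΣG + σ²ε) on the vial basis and ΣG/(ΣG + σ²ε/r) on the basis
of r-vial line means.  The line-means version is the relevant precision
for line-mean association mapping and approaches 1 as r grows whenever
ΣG > 0.

The cross-condition genetic correlation is estimated as
r\_G = σ²\_L(joint)/(σ\_L1·σ\_L2): the numerator is the among-line
component of the stacked two-way line × condition ANOVA — for two
conditions this is the covariance of line effects across conditions —
and the denominators are among-line standard deviations from the
per-condition one-way ANOVAs.  Ratio estimates can exceed |1| in finite
samples; the raw value is reported alongside the clipped one, and the
estimate is flagged undefined when either per-condition among-line
component is non-positive.  No standard error is attached to r\_G (the
usual practice for this estimator in panel studies); phenotypic
correlations are Pearson correlations of line means with two-sided
t-based P-values.

## Line-mean association

For a fully inbred panel each biallelic variant splits the lines into
two homozygous classes, so the additive single-variant test on line
means is an OLS slope test, identical to the pooled-variance two-sample
t-test; both the class-mean difference (trait units) and t/P are
reported.  MAF is counted in line units over non-missing calls
(complete-case per variant), filtered at ≥ 0.05 by default; a class
with fewer than 2 lines skips the variant with a reason code.  No
relatedness or structure covariates are fitted — the intended input is
a panel pre-filtered to unrelated, inversion-free lines — and this is a
deliberate simplification relative to web pipelines that fit polygenic
covariance.  Candidates are called at P < 5×10⁻⁵; the Bonferroni bound
α/m is reported alongside.  Variants map to every gene whose body
± 1 kb (1-based inclusive; BED input converted on read) contains their
position, strand-ignorant, with intergenic variants labelled as such.
Sexes are analyzed separately by default.

## Network randomization test

The candidate-induced subnetwork keeps candidate-to-candidate edges
only; the statistic is the node count of its largest connected
component.  This statistic is a package choice (the alternative — the
number of candidates with at least one candidate edge — is a one-line
change) made because "a network of k genes" semantics refers to a
connected component.  The null draws uniform random gene sets of the
same size from the interaction graph's node universe — not from the
genome — because the curated database's coverage is the minimum the
null must respect; degree-preserving sampling is available as an
option.  The empirical p-value is add-one-smoothed,
(1 + exceedances)/(1 + permutations), with ties counted as exceedances,
so it never returns 0 and its floor at the default 1,000 permutations
is 1/1001 ≈ 9.99×10⁻⁴.

## Knockdown contrasts

RNAi-vs-control assays reuse the same engine with every factor fixed
(two specific genotypes are not a random sample), under which every
synthesized denominator provably collapses to the residual mean square.
Genotype-involving terms map to behavior categories: L → consumption,
L×S → preference, L×E → change of consumption, L×E×S → change of
preference, called at per-test α = 0.05 by default with an optional
Benjamini–Hochberg adjustment across a panel.

## The synthetic-data generator

The generator is the generative inverse of the fitted model: cell means
are μ plus zero-sum fixed-effect vectors plus one i.i.d. normal draw per
level combination of each random term (interactions drawn independently
of main effects, matching the ANOVA's assumptions), with i.i.d. normal
residuals per vial.  Defaults: 46 lines × 3 exposures × 2 solutions ×
2 sexes × 10 vials; grand mean 50 mm (≈ 3.4 μl per vial per solution,
a realistic overnight group intake); variance components
(L = 63.86, L×E = 7.71, L×S = 4.52, L×X = 15.24, L×E×S = 13.16,
L×E×X = 0.27, L×S×X = 4.23, L×E×S×X = 0.25, ε = 267.28 mm²) and fixed
effects (sex ±6.4, exposure ±2.6, solution ±1.65 mm) of magnitudes
representative of psychostimulant-consumption panel studies, so the
simulated F-ratio and heritability landscape resembles real data.
Consumption is split between the two same-solution capillaries with a
uniform (0.25–0.75) fraction — assays do not constrain this split, it
is a modeling choice — and a shared per-stratum evaporation offset
(mean 1.5 mm, ±20 % between strata, 0.2 mm per-capillary noise) is
added to vial and control capillaries alike so the correction stage is
exercised non-trivially.  Raw readings are clamped to [0, 127 mm]
(capillary length); at the default grand mean the lower clamp binds for
well under 1 % of observations, a negligible censoring.

Genotypes are homozygous biallelic with the minor-line count drawn
uniformly over the counts feasible within the MAF range, no linkage
structure (single-variant tests make LD irrelevant here), positions
1-based on a single chromosome arm.  Causal variants are placed inside
distinct gene bodies and shift the designated trait's line means by
±effect/2 by minor/major class.  The interaction network is
Erdős–Rényi background plus a planted module wired as a random
recursive tree with extra within-module edges, planted over the causal
genes, so GWA hits and the network test have a common ground truth.

All randomness derives from one integer seed through fixed-order draws
in per-stage child streams (consumption = 0, genotypes = 1,
network = 2), making studies byte-reproducible and stages independently
reproducible.

What the generator does **not** emulate: linkage disequilibrium and
population structure, mortality/unbalanced designs, heavy-tailed or
heteroskedastic residuals, evaporation drift within a stratum, and the
degree distribution of curated interaction databases (the ER background
is far more homogeneous).  Passing tests therefore demonstrate the
estimators' correctness under the stated model, not robustness to these
real-data features.

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to keep the full suite fast
while leaving Monte-Carlo error well below the tolerances tested:
EMS expectations average 300–600 simulated 96-observation designs
(agreement within 3 MC standard errors); component recovery uses
full-size 5,520-observation studies (each component within 3 propagated
SEs); GWA calibration uses ~10³ variants per phenotype and power uses
dozens of seeded replicates; the permutation test is checked against
exhaustive enumeration on 6-node graphs at 8,000–10,000 permutations.
Exact linear-algebra steps (SS decomposition, EMS solve) are checked to
1e-8 relative against independent OLS oracles.  Elimination and
denominator weights treat |w| < 1e-12 as zero; the EMS solve refuses
singular systems.

## Known limitations

* Balanced designs only; no REML/ML, no unbalanced Type III machinery.
* Genetic correlations carry no standard errors.
* The GWA stage fits no relatedness covariates.
* The network null ignores degree structure unless degree-preserving
  sampling is switched on, and the statistic choice (largest component)
  is one of several defensible options.
* Heritability truncation (negative components set to zero) biases ΣG
  upward slightly when true components are near zero.
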