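# Methods

`flymet` re-implements, as a tested library, the analysis chain of a
*Drosophila melanogaster* metabolic-profiling study design: a panel of
fully sequenced inbred wild-derived fly lines (a DGRP-style core set) is
phenotyped for six metabolites (TAG, total protein, free glycerol,
lactate, glycogen, glucose) in late third-instar larvae and six-day-old
adults of both sexes, challenged with diets of varying sugar content,
16S-profiled for gut-microbiome composition, and screened for
trait-associated SNPs. This note documents the models, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Assay quantification

Plate readings are converted to amounts via a least-squares linear
standard curve `reading = a·conc + b`. The intercept is fitted rather
than forced through the origin: blanks are part of the standard series
and the intercept absorbs plate background. Sample concentration is
`(reading − b)/a × dilution`; the amount per animal multiplies by the
homogenization volume and divides by the number of animals (5 larvae or
8 adults per sample). Homogenization volumes differ per assay (400 µL
for most, 100 µL for the citrate synthase preparation), so the volume is
a parameter of `AssaySpec`, not a constant. Readings below the blank are
flagged below-detection and the amount is left missing rather than
clamped or raised as an error — censoring is a property of the
measurement, not a fault.

Glycogen uses the glucose-oxidase difference method: amyloglucosidase-
digested total glucose minus free glucose, floored at 0 with a warning
flag when the difference is negative (a physical impossibility that
arises from read noise).

Citrate synthase activity follows the DTNB closed form

    activity (U/mL) = (ΔA412/min · V_reaction · dil) / (ε · L · V_enz)

with defaults V_reaction = 0.22 mL, V_enz = 0.02 mL, L = 0.63 cm
(96-well plate), ε(TNB²⁻) = 13.6 mM⁻¹cm⁻¹. Linearity in ΔA and dil and
inverse linearity in V_enz are asserted directly from the formula.

## Normalization and metabotype analysis

Two normalizations serve two purposes. **Column z-scores** (sample SD,
missing entries preserved) feed clustering and PCA. **Percent of
maximum**: replicates are averaged to line means first, then each line
mean is expressed as percent of the maximum line mean within its
metabolite × (stage, sex) group, so the best-stocked line sits at 100.
"Percent of max" was chosen over "percent of sum" (the wording is
ambiguous in the emulated design); the basis (the per-group maxima) is
returned so a second panel — a diet arm — can be normalized on the
*same* basis, which diet responses require: with a shared basis the
percent response `(shifted − baseline)/baseline × 100` equals the
underlying multiplicative effect minus one.

Missing (below-detection) values are imputed as half the minimum
observed value of the column before clustering/PCA. Larval glucose is
left-censored in a subset of lines; dropping those rows would discard
whole lines, and half-minimum is the conventional left-censoring
stand-in. K-means uses 50 restarts (best by within-cluster sum of
squares), a required seed, and k = 3 for combined panels (larva /
female / male) or 6 for larva-only prototypes. Labels are renumbered by
first appearance so cluster identities are reproducible. PCA is the
eigendecomposition of the z-scored columns' covariance; each
component's sign is fixed so its largest-magnitude loading is positive.

**Virago calls** (lines whose adult females show a male-like profile)
are made reproducible rather than visual: the male and female reference
clusters are the k-means clusters whose adult members are majority-male
and majority-female; a line is called when its female samples' centroid
in the top-2 PC plane lies closer to the male-cluster centroid than to
the female-cluster one. Degenerate clusterings (no sex majority) raise.

## Correlation analysis

Spearman rank correlations are computed on midranks over
pairwise-complete observations, with per-pair n reported. P-values
follow the AS 89 algorithm for S = Σd²: full enumeration of the
permutation distribution for tie-free n ≤ 9 (the exact regime), and the
AS 89 Edgeworth series otherwise. The series is most accurate in the
upper tail, and S is symmetric about its mean, so the lower tail is
evaluated on the reflected statistic; two-sided p doubles the smaller
tail and caps at 1. Against a full exact computation the series is
within 2×10⁻⁴ at n = 12 and 10⁻⁷ at n = 20 — well inside the 0.005
band the tests assert. Far in the tail (standardized statistic beyond
roughly 3) the series' correction term can overwhelm the leading normal
term and turn negative; there the p-value falls back to the
t approximation, which is well behaved. Tied data use the t approximation
`t = r√((n−2)/(1−r²))`, the field standard. Significance filtering masks
entries with p ≥ α (default 0.05, matching the emulated analysis; no
multiple-testing correction by default, a Benjamini–Hochberg pass being
deliberately out of scope).

The fecundity comparison is a one-way ANOVA followed by two-sided
two-sample t-tests of every candidate line against every control line,
Bonferroni-multiplied by the number of comparisons and capped at 1.

## Shared-allele statistics

Inbred lines are coded ref/alt/missing per biallelic site; heterozygous
or multi-allelic calls are treated as missing. Pairwise sharing for an
allele class is `100 × (#sites both lines carry the class) / (#sites
callable in both)`. The jointly-callable denominator reproduces the
magnitude relationship typical of inbred panels (shared-alt a few
percent, shared-ref near 75%); an allele-union denominator is available
behind a switch. Note ref% + alt% equals the pair's concordance and is
100 only for identical call vectors. The empirical null is the
histogram of all C(n,2) pair values (bin width 0.5 percentage points;
mode = midpoint of the fullest bin, ties to the lower bin). A candidate
group's statistic is the mean of its within-group pairwise values (an
all-members-share variant is also provided). Group-private alleles:
a site is group-unique for a class iff every group member carries a
non-missing call of that class and every other line with a non-missing
call carries the other class. All of these are checked against a
brute-force site-enumeration oracle on small matrices.

## Microbiome processing

Counts are closed to proportions per sample. The retained-taxon rule is
the cumulative-prefix reading of "top 95% most abundant in at least one
sample": within each sample taxa are ranked by decreasing proportion and
the minimal prefix reaching 95% cumulative abundance is that sample's
top set; a taxon is kept globally if it enters any sample's top set.
(The alternative reading — a 95th-percentile rank cut — was rejected as
inconsistent with "most abundant … in at least one sample".) Genus
rollup sums species counts within genus and conserves per-sample totals.
Exclusions drop named samples (e.g. a Wolbachia-infected line) and taxa
(Wolbachia is an endosymbiont, not a gut resident) without
renormalizing. Hierarchical clustering uses Bray–Curtis dissimilarity on
proportions with average linkage — unstated in the source design,
standard for compositional 16S data. The metabolite–microbe correlation
chain is: exclude → top-95% filter → relative abundance → log10(x + 1)
→ Spearman/AS89 → p < 0.05 filter, at species and genus level.

## GWAS post-processing

Significance filtering is strict (`p < threshold`, default 10⁻⁵).
Per-trait counting deduplicates variant ids and splits them into
gene-associated (non-empty gene symbol, case-sensitive) and unclear.
Condition overlap intersects unique variant ids and unique gene symbols
between basal and diet-shift tables. Manhattan preparation lays
chromosomes end to end in the supplied order and emits −log10 p with
threshold lines at 10⁻⁵ and 10⁻⁷. The `naive_association_scan` is a
deliberately simple desk-scale stand-in used to exercise the pipeline
on synthetic genotypes: per site with ≥ 4 minor-allele lines, line means
are regressed on 0/1 dosage (equivalently a pooled-variance t-test). It
claims no equivalence to the external mixed-model association tool,
whose computation is out of scope.

## Synthetic data: what it emulates, and what it does not

All generators draw from one seed; each uses its own derived substream,
so e.g. adding taxa never perturbs the metabolite draws. Amounts are
drawn on log10 scale and exponentiated (positive, right-skewed, like
assay data), then censored below a detection floor (default 0.6
units/animal — placed so a realistic fraction of larval glucose, and
essentially nothing else, is censored).

The metabolite panel has three strata (larvae mixed-sex, adult females,
adult males) with fixed qualitative stage/sex offsets: larvae
lactate-rich (default 20-fold over adults), glycogen/glucose-poor;
females store-rich in TAG/glycogen/glucose. The offsets were calibrated
once to make the three strata cleanly separable after column z-scoring
— z-scoring bounds the achievable standardized stratum contrast per
column (roughly 2 SD), so every metabolite carries some stratum
contrast. Each line belongs to one of k metabotypes; cluster centers
are equal-magnitude sign patterns over the metabolites, orthogonalized
against the stage/sex contrasts and each other, scaled to
`cluster_separation` replicate-SDs (default 3.5; recovery tests use 5,
the separation at which the clustering module is required to reach
adjusted agreement ≥ 0.9). Keeping the default below the recovery
setting keeps line-cohort structure subordinate to the stage/sex
dimorphism, as in the emulated data. A per-line random effect (default
noise_sd/2) is shared across strata, so a virago line's female samples
— drawn from the line's *male* distribution — match its male means
exactly at zero noise.

Genotypes are independent biallelic sites with alt-allele frequency
drawn from Beta(0.41, 2.12) by default. That spectrum was chosen so
E[p²] ≈ 0.065 and E[(1−p)²] ≈ 0.74, i.e. the pairwise shared-alt and
shared-ref modes land at the magnitudes characteristic of inbred-panel
data (~6.5% and ~74%). Group-private alleles are planted exactly;
non-planted sites that are group-private by chance are repaired (one
group member flipped) so the planted truth is exhaustive. Missing calls
are opt-in (default rate 0) because exact planted recovery is the
reference condition; recall degrades measurably as missingness rises,
and a test asserts that monotonicity. No linkage disequilibrium is
simulated — sites are independent by design.

Abundance tables are multinomial draws (default depth 50 000) from
line-specific Dirichlet base compositions dominated by the five core
Acetobacter/Lactobacillus species, with rarer contaminants filling the
taxon count and an optional Wolbachia-infected line whose samples carry
a large endosymbiont fraction. Planted metabolite–taxon rank
correlations use a Gaussian copula: the metabolite's normal scores are
mixed with noise orthogonalized against them in-sample, so the realized
score correlation equals the target by construction (a free draw's
sampling SD, ≈ 1/√n, would exceed the stated ±0.15 tolerance at n = 30);
the linked taxon's within-sample share is a logistic function of its
copula score, keeping the closed proportion monotone in the score. The
copula conditions on the samples a correlation analysis keeps — the
Wolbachia line is excluded there by design. Genus-level targets spread
the share over the genus's member species.

Diet-shift copies multiply each adult LSD baseline cell by a per-(line,
sex, metabolite, diet) lognormal multiplier — glucose/glycogen/TAG
above 1 on average (stronger under HSD; female glycogen and male TAG
accented), glycerol slightly below 1, protein ≈ 1 — pairing shifted
replicates with baseline replicates so the percent response recovers
`(multiplier − 1)×100` exactly at the default zero shift noise.
Explicit multipliers can be injected for deterministic scenarios.

What passing tests show: the pipeline recovers planted structure of the
kinds the real analysis claims to detect, at the planted effect sizes,
under clean statistical assumptions (independent sites, lognormal
noise, exact compositional closure). What they do not show: performance
under linkage disequilibrium, batch effects, uneven sequencing depth,
compositional artifacts beyond multinomial noise, or real assay
nonlinearity — none of which the generators simulate.

## Problem sizes

The default test and acceptance runs use 35 lines × 3 strata × 3
replicates for panels, 1 000–5 000 genotype sites, 30-sample abundance
tables at depth 50 000, and 20-seed recall loops; the exact Spearman
reference distribution is enumerated in full up to n = 10. These sizes
keep every planted effect comfortably detectable while the whole suite
runs in well under a minute.
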