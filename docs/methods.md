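# Methods and design notes

## Coordinate conventions

All coordinates are 0-based half-open internally. BED input is read as
0-based half-open; 1-based inclusive ranges quoted from annotation text
(e.g. the rat 18S, "positions 1 to 1874") are converted at the boundary by
`slice_1based_inclusive`, so position 1..1874 becomes [0, 1874).

## Looped reference

A tandemly repeated unit has no natural linear start: a contig that begins
at the unit's conventional origin discards reads spanning the repeat
junction as split alignments, depressing coverage around whatever sits
near the contig ends. The looped unit rotates the consensus so that
position 0 falls inside the intergenic spacer, by default 2120 bp upstream
of the 47S TSS (the midpoint of the IGS repetitive element nearest the
unit's 3' end). The rotation is `looped(p) = (p − breakpoint) mod L`, a
bijection tested by round-trip over every position. Annotated regions are
remapped through the same rotation; a region split by the rotation is
carried as **two explicit intervals** rather than wrapped coordinates, so
downstream interval arithmetic (depth means, CpG containment) stays
ordinary. How the original bookkeeping handled straddling regions is not
documented anywhere we know of; the two-interval representation is this
package's choice, and all consumers aggregate split intervals jointly
(sum of counts over both pieces divided by total length), which the tests
verify equals the unsplit computation.

Pseudocopies — partial rDNA-like sequences scattered in the assembly —
are hard-masked to `N` so reads from true arrays cannot land on them;
masking never changes contig lengths. Pseudocopy coordinates are taken as
input (BED), not re-derived by self-alignment. For the rat, the consensus
covers only 18S..28S, so no IGS breakpoint exists; the masked assembly
instead receives the bare 18S (1874 bp) as an extra contig.

## Exome filter

The absolute CN estimator needs a single-copy depth denominator. Exons
shorter than 300 bp (unstable depth) and exons on sex chromosomes
(ploidy differs by sex) are removed, then mutually similar sequences are
deduplicated. Similarity is shared-k-mer Jaccard (default k = 31,
threshold 0.5) — a deliberate, dependency-free stand-in for an ungapped
BLAST screen; at k = 31 random 500-mers share essentially no k-mers while
near-duplicates share most, so the decision is insensitive to the exact
threshold. Of a similar pair the **shorter** member is dropped (ties by
keeping the lexicographically smaller identifier) and the removal log
names the retained partner, making the filter auditable and idempotent.

## Copy-number estimators

* **WGBS absolute**: `CN = 2 × d̄(18S) / d̄(exome)`, with `d̄` the
  arithmetic per-base mean of unique-read depth over the interval
  (pileup semantics). "Unique" means primary, non-secondary,
  non-supplementary alignments, plus `NH == 1` when the tag is present;
  plain depth-table input is assumed pre-filtered. The factor 2 anchors
  the single-copy exome at diploid ploidy. Zero exome depth is an
  explicit error, never infinity. All retained exons enter the
  denominator; no coverage trimming or GC correction is applied.
* **RRBS relative**: rDNA-aligned reads divided by total alignments.
  RRBS exome coverage is too patchy for a depth denominator, so this is a
  *relative* quantity — kept in its own units and compared across methods
  only by rank (Spearman), never by value.
* **ddPCR**: `reference_ploidy × FAM / VIC` per well; wells with mean
  copies-per-partition Lambda ≥ 1.6 are excluded because high template
  loading violates the Poisson assumptions of digital quantification.

Cross-validation reports Spearman (headline, scale-free) and Pearson on
the sample-id intersection and refuses fewer than 3 shared samples.

## Down-sampling robustness

Reads are shuffled once under the given seed and dealt round-robin into
10 subsamples (exhaustive, disjoint, sizes within 1); a fraction-f
estimate merges `round(10f)` randomly chosen subsamples. Operating on
labelled read records rather than FASTQ reproduces equal-split semantics
at desk scale; everything is deterministic given the seed. The synthetic
sample behind this check uses a 2 Mb exome denominator: at much smaller
denominators the hypergeometric noise of the subsample ratio itself —
not the estimator — dominates the deviation, which would make the check
uninformative about estimation stability.

## Methylation aggregation

Bismark-style coverage input (1-based, destranded, percent plus counts)
is converted to 0-based counts; the percent column is discarded after a
consistency check. The default regional mean is **coverage-weighted**
(Σmethylated / Σreads over retained CpGs), which is exactly invariant to
splitting a region into subintervals; an unweighted per-CpG mean is
available by flag. On the rDNA contig only CpGs with ≥ 50 reads are used
(the multicopy locus is deep enough to afford it; per-CpG coverage there
is combined-strand); feature classes genome-wide use all CpGs. The rDNA
summary window runs from 1000 bp upstream of the TSS to the end of the
transcribed unit; genome promoters are ±1 kb of the TSS — two separate
configuration values on purpose. A region in which no CpG survives the
filter yields an explicit empty summary (`mean_methylation = None`),
never 0. Feature-class coverage is the mean of (M+U) over contained CpGs.

**Active copy number** is `CN × (1 − m̄)`: methylated copies are treated
as silenced and discounted. The exact adjustment formula behind published
"methylation-adjusted" copy numbers is not printed anywhere; this linear
discount is the package's explicit choice and is recorded in the output
(`formula` field). It is monotone in both arguments and bounded by
[0, CN], both tested.

## Sample QC

Exclusion rules are qualitative in origin ("extremely high or low",
"poor"); the numeric defaults here are package choices, echoed into
output provenance: read counts beyond median ± 3 robust (normal-
consistent) MADs; mapping efficiency below 0.6; non-CpG methylation
(bisulfite-conversion proxy) above 0.02; and, for RRBS only, total CpG
methylation beyond mean ± 3 SD (aberrant digestion or size selection).
Robust statistics are used for read counts because library sizes are
heavy-tailed; the classical mean/SD is kept for the RRBS rule, matching
the 3-SD convention used for comparable screens. Cohort-relative rules
need n ≥ 3 and are order-independent; with a zero MAD/SD the relative
rule flags nothing (degenerate cohort).

## Rank statistics

Exact branches enumerate the full null — all n! rank permutations for
Spearman at n ≤ 8, all C(N, n1) group assignments for Mann–Whitney at
combined N ≤ 12, all 2^n sign patterns for Wilcoxon at ≤ 12 informative
pairs — and count outcomes at least as far from the null centre as
observed (|r|, |U − n1n2/2|, |W⁺ − n(n+1)/4| respectively), with average
ranks for ties. Above the crossovers, scipy's tie-corrected
approximations are used (normal with continuity correction for
Mann–Whitney, normal for Wilcoxon with zeros dropped, the t-based
approximation for Spearman). The crossover sizes are fixed constants and
the branch taken is recorded on every result. Zero paired differences
are dropped; an all-zero comparison is an explicit error, which the
twin analysis reports as "no difference detectable" rather than p = 1.

Age adjustment is OLS residualisation on age plus the cohort mean —
stratification would also be defensible; residualisation is implemented
and labelled. Per-week growth correlations are reported with raw p as
primary and a Holm-adjusted column alongside.

## Exponential plateau fit

`W(t) = YM − (YM − Y0)e^(−kt)` is fitted by least squares,
reparameterised as (Y0, Δ = YM − Y0, k) with positivity bounds on Δ and
k, from a fixed multi-start grid (Y0 at the first observation, YM at
1.1/1.5/2 × max, k ∈ {0.05, 0.2, 0.5, 1}/week); lowest SSE wins, ties
toward smaller k — deterministic without a seed. Time is taken as given,
so cohorts observed from week 8 pass `week − 8`. Duplicate time points
(pooled cohort fits) are allowed; at least 4 distinct times are
required, and a constant series is rejected as non-growth. Noise-free
data are recovered to ~1e−6 (curve_fit tolerances at 1e−14), and
first-order optimality (residual ⊥ gradient) is tested.

## Synthetic-data generator

The generators define the study conditions the tests run under.

* **Cohort** (defaults): n = 63; true CN ~ Uniform(150, 600) per diploid
  genome; per-base depth Poisson with mean `CN/2 × 14` over the (split-
  aware) looped 18S interval and mean 14 over a 20 kb exome stand-in —
  enough bases that the denominator's sampling error is negligible
  relative to the numerator's; per-sample mean methylation Beta
  (mean 0.30, concentration 25) coupled to CN through a Gaussian copula
  targeting Spearman 0.74 (`ρ_z = 2 sin(πρ_s/6)`); 100 CpG sites with
  fixed N(0, 0.04) site effects, Poisson(120) coverage and binomial
  methylated counts; RRBS allocation binomial out of 5×10⁶ alignments
  with rDNA probability 1.25×10⁻⁶ per copy (≈ 5×10⁻⁴ at CN 400); BMI
  `27 + 4(βz(CN) + √(1−β²)ε)` with β = −0.30 in the non-medicated
  stratum and 0 in the 41% medicated stratum; ddPCR FAM/VIC around
  `CN/2` with 5% CV and Gamma(4, 0.2) Lambda, so a few percent of wells
  legitimately trip the 1.6 exclusion.
* **Lean/obese contrast**: 31 + 32 with a CN shift expressed in SD units
  (default 0.8 SD of a N(400, 80) distribution).
* **Twins**: 24 pairs sharing true CN exactly (N(400, 80) per pair);
  observed CN differs only by 2% lognormal measurement noise; BMI
  discordance |N(3, 1)| kg/m² split symmetrically around a shared base.
* **Growth**: 44 animals, weeks 8–19, `W = Y0 + G(1 − e^{−0.35(t−8)})`
  with Y0 ~ N(180, 12) **independent of CN** and the span
  `G = 80 − 18(0.55·z(CN) + √(1−0.55²)ε)`, plus 3% lognormal observation
  noise. Putting the whole CN effect into the gain makes the
  cross-sectional correlation null at week 8 and emergent by week 19.
  The effect size 0.55 was set by an up-front power analysis so the
  designed emergence pattern (|r₁₉| > |r₈| in ≥ 90% of cohorts of 44) is
  a property of the conditions rather than a coin flip; the realised
  correlations (gain ≈ −0.45, week 19 ≈ −0.40) remain in the range
  reported for post-pubertal rat cohorts. The pooled plateau fit over
  all animals' weekly observations yields R² ≈ 0.55 under these
  defaults, the between-animal spread being what it is; the acceptance
  script computes this number rather than asserting it.

What the generators deliberately do **not** model: sequence-level reads
(depth is Poisson per base, reads are labelled records), GC and
mappability bias, strand-specific methylation, instrument error
profiles, cell-composition effects, or real pseudocopy structure beyond
a planted toy copy. Passing tests therefore demonstrate that the
estimators recover the quantities they claim under the stated noise
models — not that those noise models exhaust real-library artefacts.

Determinism: every generator takes a seed and produces byte-identical
output files for identical (config, seed); an infeasible copula target
(|ρ| ≥ 1) fails explicitly.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen to keep
sampling error far from the asserted tolerances: full cohorts of 50–63
samples for single-cohort checks; 200 replicate cohorts for power/
calibration rates (with a 2 kb exome stand-in inside the replicate loop,
where the depth term's precision is ~0.5% and irrelevant to the rank
statistics under test); a 10⁴-draw law-of-large-numbers check for the
copula; and one ~330k-read sample for the down-sampling analysis.

## Known limitations

* The RRBS estimator is never calibrated to absolute copies; only ranks
  are meaningful, and the package refuses to compare the two scales
  except through correlation.
* The exact concordance of the QC defaults with any published cohort's
  excluded-sample list cannot be asserted without those cohorts' report
  files.
* The k-mer similarity filter is not a local aligner: two exons sharing
  a short high-identity stretch inside otherwise divergent sequence can
  fall below the Jaccard threshold where an alignment screen would flag
  them.
* `region_methylation` assigns CpGs by position containment only;
  overlapping features double-count CpGs into each containing class,
  which matches feature-class (not partition) semantics.
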