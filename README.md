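# rdnacn

Quantification of ribosomal DNA (rDNA) copy number and methylation from
bisulfite-sequencing-derived inputs, with the downstream cohort analyses
that link copy number to body-mass phenotypes.

## The problem

The 47S rDNA unit — encoding the 18S, 5.8S and 28S rRNAs — is tandemly
repeated in hundreds of copies per diploid genome, yet it is absent from
standard genome assemblies and excluded from array-based population
studies. Estimating how many copies an individual carries, and how many of
those copies are epigenetically silenced, requires dedicated reference
engineering and depth-ratio arithmetic. This package implements that
pipeline for researchers analysing WGBS/RRBS cohorts:

* **Reference engineering** (`rdnacn.reference`): a *looped* rDNA unit
  rotated so the artificial contig junction falls in the intergenic
  spacer, 2120 bp upstream of the TSS (reads spanning the natural unit
  boundary then align contiguously); hard-masking of rDNA pseudocopies in
  the assembly; a deduplicated single-copy exome to serve as depth
  denominator; the rat 18S-only variant.
* **Copy-number estimation** (`rdnacn.cn`): absolute CN from WGBS as
  `CN = 2 × d̄(18S) / d̄(exome)` where `d̄` is mean per-base unique-read
  depth; relative CN from RRBS as rDNA-aligned reads over total
  alignments; ddPCR CN as `2 × FAM/VIC` with Lambda ≥ 1.6 wells excluded;
  cross-validation between methods and a 10-subsample down-sampling
  robustness check.
* **Methylation aggregation** (`rdnacn.methylation`): bismark-style
  coverage files aggregated over the rDNA promoter (−1000 bp) plus
  transcribed unit with a ≥ 50-read CpG filter, per-feature-class
  methylation and coverage genome-wide, and the methylation-adjusted
  "active" copy number `CN × (1 − m̄)`.
* **Sample QC** (`rdnacn.qc`): exclusion on read-count outliers,
  mapping efficiency, bisulfite conversion, and (RRBS) total-methylation
  outliers, with auditable thresholds.
* **Association statistics** (`rdnacn.stats`): Spearman correlations,
  Mann–Whitney group tests and Wilcoxon matched-pairs tests (exact
  enumeration at small n, tie-corrected approximations otherwise), OLS age
  adjustment, medication-stratified correlations, twin-pair analysis, and
  the exponential-plateau growth model
  `W(t) = YM − (YM − Y0)·e^(−kt)` with per-week CN correlations.
* **Synthetic data** (`rdnacn.simulate`): ground-truthed generators for
  every stage — Poisson depth, copula-coupled CN/methylation, multinomial
  RRBS allocation, BMI with configurable CN slope, shared-CN twin pairs,
  plateau growth with a CN effect on gain only — so every estimator is
  tested against known truth.

## Worked example

Simulate a 63-sample cohort at 14× depth (true CN uniform on [150, 600],
CN–methylation coupling 0.74) and run the full estimation path:

```python
from scipy.stats import spearmanr
from rdnacn.simulate import SimulationConfig, simulate_cohort
from rdnacn.pipeline import estimate_cohort

sim = simulate_cohort(SimulationConfig(n_samples=63), seed=1)
df = estimate_cohort(sim)
print(df[["sample_id", "cn_true", "cn_wgbs", "cn_rrbs",
          "meth_hat", "active_cn"]].head(3).round(4))
r = spearmanr(df.cn_wgbs, df.meth_hat)
print(f"Spearman(CN, methylation) = {r.statistic:.4f} (p = {r.pvalue:.2e})")
```

```
  sample_id   cn_true   cn_wgbs  cn_rrbs  meth_hat  active_cn
0      S000  435.8276  436.1272   0.0006    0.2426   330.3306
1      S001  507.4588  508.6942   0.0006    0.3714   319.7579
2      S002  433.2593  432.0474   0.0005    0.2850   308.9069
Spearman(CN, methylation) = 0.7321 (p = 9.27e-12)
```

`cn_wgbs` recovers the latent `cn_true` to well under 1% at this depth;
`cn_rrbs` is a unitless fraction comparable only by rank; `meth_hat` is
mean methylation across the promoter + transcribed unit; `active_cn`
discounts the methylated (presumed silenced) copies. The realised
CN–methylation correlation sits at the configured coupling strength.

A CLI mirrors the library: `rdnacn build-ref`, `rdnacn estimate-cn
wgbs|rrbs|ddpcr`, `rdnacn downsample-check`, `rdnacn methylation`,
`rdnacn qc`, `rdnacn associate` and `rdnacn simulate` (see `--help`).

## Layout

```
src/rdnacn/
  reference.py    looped unit, masking, exome filter
  cn.py           depth extraction and the three CN estimators
  methylation.py  CpG aggregation, coverage filter, active CN
  qc.py           sample exclusion rules
  stats.py        cohort association statistics
  simulate.py     ground-truthed generators
  pipeline.py     cohort-level convenience wrapper
  cli.py          command-line interface
docs/methods.md   model and design notes
tests/            pytest suite (unit, property and acceptance tests)
```
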