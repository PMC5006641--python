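# regionburden

Regional rare-variant burden scanning and companion statistics for studies
that prioritise non-coding candidate driver mutations from targeted cohort
sequencing — built around the analysis design used to identify a recurrently
mutated distal repressor of *SOX2* in high-grade serous ovarian cancer
(HGSOC) and its fallopian-tube precursor lesions.

## What it does

Given per-sample variant calls over a target region (e.g. the 2 Mb flanking a
gene of interest), a reference-panel allele-frequency table, and a control
cohort, the package answers: *do rare variants in the case cohort cluster
anywhere in the region more than chance allows?* — plus the discovery and
validation steps around that question:

- **Ancestor ("root") variant discovery** (`root_filter`): variants present
  in ≥ 90% of microdissected tumor islets and absent from matched normal —
  mutations inferred to predate clonal divergence.
- **Rare-variant filter** (`scan.filter_rare_variants`): single-nucleotide
  substitutions carried by fewer than five samples, absent from the panel,
  and flagged `pass` or `allele_bias`.
- **Sliding-window burden scan** (`scan.RegionalBurdenScan`): 40 kb windows
  every 100 bp scored with the ratio statistic

  *T(w) = observed rare variants in w / expected common-SNP calls in w*,

  where the expectation is the mean over Monte-Carlo cohorts drawn from
  panel minor-allele frequencies under Hardy–Weinberg equilibrium (sites
  independent, no LD): at a site with MAF *p*, each of the 33 simulated
  individuals is a non-reference carrier with probability 1 − (1 − *p*)².
  Two nulls calibrate *T*: an **order-statistic p-value** (the rank of the
  observed statistic among the same statistic recomputed on 100 resampled
  33-individual control subsets, reported "< 1/N" at zero exceedances) and a
  **Poisson hotspot tail** P(X ≥ obs) with X ~ Poisson(λ), λ = global
  rate × window size.
- **Regulatory-domain gene-set enrichment** (`great.GreatEnrichment`):
  GREAT-style domains (basal = TSS − 5 kb to TSS + 1 kb, strand-aware,
  extended up to 1 Mb per side stopping at the nearest neighboring basal
  domain); enrichment = fraction of foreground variants mapping to a set's
  genes over the same background fraction, with a permutation null (10,000
  foreground-sized background subsets, strict exceedance) and
  Benjamini–Hochberg q-values; a hit needs q < 0.01 and > 10 supporting
  genes.
- **Biomarker statistics** (`biomarker`): nuclear-intensity (0/1+/2+/3+)
  aggregation, one-way ANOVA + Tukey HSD on percent-3+, logistic (binomial
  GLM) discrimination with ROC/AUC, the two-group normal-approximation
  sample size n = (z₁₋α/₂ + z_pow)²(σ₁² + σ₂²)/Δ², and droplet-digital-PCR
  QC (wells under 7,000 droplets excluded) with pooled mutant allele
  fractions.
- **Synthetic data** (`synthetic`): generators for every input — HWE cohort
  genotypes, rare singleton variants with optional regional enrichment,
  islet call sets sharing a root clone, gene annotations with gene sets, and
  IHC score tables — so the whole pipeline is exercisable without controlled-
  access data.

## Worked example

Scan a synthetic 2 Mb region in which one 40 kb window carries a 5-fold
rare-variant enrichment:

```python
from regionburden import (
    GenomicInterval, PopulationModel, RegionalBurdenScan, WindowScanConfig,
    sample_size_two_groups,
)
from regionburden.synthetic import random_common_sites, simulate_rare_variant_cohort

region = GenomicInterval("chr3", 1_000_001, 3_000_000)            # 2 Mb
hotspot = GenomicInterval("chr3", 1_800_001, 1_840_000)           # 40 kb, 5-fold
model = PopulationModel(
    region=region,
    common_sites=random_common_sites(region, 2000, seed=7),
    enrichment_windows=[(hotspot, 5.0)],
)
cases = simulate_rare_variant_cohort(model, 33, seed=7)
controls = simulate_rare_variant_cohort(
    PopulationModel(region=region, common_sites=model.common_sites), 100, seed=8
)
config = WindowScanConfig(n_sim=200, n_control_subsets=100)
scan = RegionalBurdenScan(cases, region, model.panel(), controls, config=config)
results = scan.fit(seed=7)
print(results.summary())
print("n per group:", sample_size_two_groups(3, 4, 14, 10, power=0.90, alpha_two_sided=0.05))
```

Output:

```
Regional rare-variant burden scan
=================================
region:            chr3:1000001-3000000 (2,000,000 bp)
windows:           19,601 x 40,000 bp (step 100 bp)
rare variants:     732 distinct (global rate 366.00 per Mb)
expectation:       mean of 200 HWE cohort simulations (cohort size 33, carriers)
order-statistic:   100 control subsets

top windows by ratio statistic:
  start     end  observed  expected  ratio  poisson_p order_p_label
1800801 1840800        76     619.7 0.1226  1.094e-29        < 0.01
1799901 1839900        76     623.4 0.1219  1.094e-29        < 0.01
1800001 1840000        76     623.4 0.1219  1.094e-29        < 0.01
1801301 1841300        75     617.1 0.1215  5.695e-29        < 0.01
1801401 1841400        75     617.1 0.1215  5.695e-29        < 0.01

note: p-values are reported per window without multiple-testing correction across overlapping windows.

n per group: 10
```

The injected hotspot is the top-ranked window: it holds 76 rare variants
against ~620 expected common-SNP calls, its ratio exceeds all 100
control-subset statistics (order p < 0.01), and the Poisson tail under a
uniform-rate null is vanishingly small. The power line reproduces the
ten-cases-per-group validation design for the benign (3 ± 4) vs HGSOC
(14 ± 10) percent-3+ staining contrast.

A command-line interface mirrors the library
(`regionburden simulate|root-filter|window-scan|go-enrich|ihc-stats|power|ddpcr|run`);
`regionburden run --outdir out` executes the full synthetic pipeline from a
YAML config with one global seed.

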