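# Methods

This note documents the statistical models the package implements, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions that matter
when reproducing results.

## Coordinate and data conventions

All coordinates are 1-based inclusive in memory, matching how regions are
printed in the genomics literature; BED files are converted at the file
boundary (`start+1` on read, `start-1` on write) and the two conversions are
inverse. Variant identity is `(chrom, pos, ref, alt)`; zygosity is ignored
everywhere except genotype simulation, because sparse tumor-islet calls make
zygosity unreliable. Variant tables are long-format carrier tables: one row
per (variant, carrying sample). Quality flags follow the caller vocabulary
`pass` / `allele_bias`; any other flag is preserved verbatim but fails the
rare-variant quality gate.

## Ancestor (root) variant discovery

A variant is called ancestral when its islet presence fraction —
carriers / total islets, computed over all islets regardless of per-site
coverage — is at least the threshold (default 0.90, inclusive, so 27 of 30
islets passes) and, when a matched normal is supplied, the variant is absent
from it. The comparison subtracts 1e-12 before testing `>=` so that exact
fractions such as 27/30 are not lost to binary rounding. Raising the
threshold can only shrink the returned set (tested property).

## Rare-variant filter

Rare = single-nucleotide substitution, carried by **fewer than**
`max_samples` (default 5; a variant in exactly five samples is excluded)
distinct samples of the input table, absent from the reference panel, and
flagged `pass` or `allele_bias`. Recurrence is counted over the input table
before the flag gate; the order is not dictated by the underlying analysis
description, and with per-site flags the difference is rarely material.

## Sliding-window burden scan

Windows of `window_size` (default 40 kb) advance by `step` (default 100 bp)
from the region start; the count is `floor((L - w)/s) + 1` (19,601 windows
over 2 Mb). Per window the scan reports:

- **observed**: distinct rare case variants in the window (variants, not
  carrier events).
- **expected**: the mean over `n_sim` (default 1000) Monte-Carlo cohorts of
  `cohort_size` (default 33) individuals of the number of non-reference
  genotype calls at panel sites with MAF > 5%, drawn under Hardy–Weinberg
  equilibrium with sites independent (no linkage disequilibrium). At MAF
  *p* an individual is a carrier with probability q = 1 − (1 − p)², so the
  closed-form limit is Σ_sites cohort_size · q — used as the test oracle.
  The per-window standard deviation over simulations is also reported.
  A config switch (`count_mode="sites"`) counts segregating sites (windows
  with ≥ 1 carrier per site) instead of carrier calls, since either reading
  of "counted the heterozygotes or non-reference homozygotes" is defensible;
  carrier counting is the default.
- **ratio**: observed / expected. Zero observed gives 0; zero expected with
  positive observed gives a +inf sentinel with a warning — such windows are
  reported but excluded from ranking, since the statistic is undefined
  there.
- **order-statistic p**: for each of `n_control_subsets` (default 100)
  subsets of `cohort_size` control individuals — sampled without replacement
  within a subset, independently across subsets — the same rare-variant
  filter (recurrence re-counted within the subset) and ratio statistic are
  recomputed; p = #{control statistic ≥ observed} / N. Ties count against
  significance, and zero exceedances are reported as "< 1/N" rather than 0,
  because N resamples cannot distinguish p-values below 1/N. Note the
  estimator is the plain empirical fraction (not (b+1)/(N+1)); with the
  ≥-tie convention it is conservative in practice on discrete window counts
  (tested by one-sided KS against uniform on null data).
- **Poisson tail**: under a uniform-occurrence null with the global rate
  estimated from the region itself (total distinct variants / region
  length), the window count is Poisson with λ = rate × window size and
  p = P(X ≥ observed). P(X ≥ 0) = 1 by convention.

No multiple-testing correction is applied across the overlapping windows —
the scan is a localisation device, not a genome-wide test — and the summary
output says so explicitly.

### Behavior of the ratio argmax under point enrichment

With overlapping 100 bp steps the count profile near a uniformly enriched
40 kb window is a flat plateau: sliding off the enrichment loses enriched
variants at per-bp rate fold·ρ and gains background at rate ρ, a random walk
with downward drift, so windows a few steps away tie or exceed the aligned
window with appreciable probability (≈ 2/fold for a one-count exceedance,
independent of the absolute rate). On top of that the denominator varies by
~10–15% between windows with the discrete panel-site layout. Consequently
the argmax-ratio window reliably **overlaps** the enriched window but is not
pinned to its exact start; localisation is at the scale of the window, not
the step. The test suite asserts overlap, which is the property the
statistic actually has.

## Regulatory domains and gene-set enrichment

Each gene's basal domain is TSS − 5 kb to TSS + 1 kb (strand-aware: upstream
is 5 kb). The extended domain grows from each basal edge until it reaches
another gene's basal domain or 1 Mb, whichever comes first; extensions may
overlap each other (only basal domains stop them), so a variant between two
genes typically maps to both. Assignment is multi-gene (every extended
domain containing the variant); a single-nearest-TSS mode is available
(`mode="nearest"`) because mapping "to the nearest TSS" is the other
defensible reading, and the two modes differ exactly where domains overlap.
Variants in no domain are reported unassigned and still count in the
fraction denominators.

Enrichment of a gene set = (fraction of foreground variants mapping to ≥ 1
set gene) / (same fraction of background variants); background fraction 0
yields an undefined (NaN) sentinel. The permutation null draws
foreground-sized background subsets without replacement (default 10,000) and
counts **strict** exceedances, so ties favor the null. Because the subset's
mapped-variant count is exactly hypergeometric, draws use the hypergeometric
sampler, and when the number of distinct subsets is at most `n_perm` the
exact tail is used — identical to exhaustive enumeration (tested against
itertools enumeration on a 5-variant background). q-values are
Benjamini–Hochberg across gene sets; a hit requires q < 0.01 **and** more
than ten distinct set genes supported by foreground variants. Variants, not
genes, are the permutation unit.

## Biomarker statistics

- Per-case intensity-bin percentages are 100 · count/total, so they sum to
  exactly 100.
- Group comparison: one-way ANOVA then Tukey HSD via the studentized-range
  distribution; with two groups F equals the squared pooled-variance t
  statistic (tested to 1e-9). Degenerate all-equal data is rejected.
- Discrimination: maximum-likelihood logistic regression of the binary label
  on percent-3+ (other bins deliberately not in the default design matrix —
  the readout is strong staining; they can be added by the caller). Complete
  separation is flagged; the ROC and AUC are computed from the raw scores
  and remain defined. The trapezoidal AUC equals the Mann–Whitney rank AUC
  (tested to 1e-12, ties included).
- Two-group sample size: n = (z₁₋α/₂ + z_pow)² (σ₁² + σ₂²) / Δ² with
  unpooled variances, rounded to the **nearest** integer. At the staining
  parameters (3 ± 4 vs 14 ± 10, 90% power, α = 0.05 two-sided) the formula
  gives 10.07 → 10 per group; ceiling would give 11 and would not match the
  ten-case validation design this formula encodes.
- ddPCR: wells with fewer than 7,000 total droplets fail QC (6,999 is
  excluded, 7,000 included) and are dropped; the per-sample mutant allele
  fraction pools mutant/(mutant + wildtype) over passing wells; no passing
  wells yields NaN.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analyses assume, at
the study's stated conditions:

- **Common SNPs**: `n` sites placed uniformly with MAF ~ U(0.05, 0.5];
  genotypes are Binomial(2, p) per individual (HWE). No LD — the expectation
  model itself ignores linkage, so the generator matches the model by
  construction; real panels have LD, which widens the null spread of window
  counts relative to the simulated one.
- **Rare variants**: independent singleton carrier events per individual at
  `rare_site_rate` per bp (default 1.05e-5), multiplied by `fold` inside
  enrichment windows; positions avoid panel sites. The default rate gives a
  per-sample median of ≈ 21 rare variants over 2 Mb, the reported per-sample
  scale; the large per-sample spread seen in real cohorts (a few
  hypermutated samples) is **not** modeled — each sample shares one rate, so
  cohort totals are tighter than real data.
- **Islets**: `root_variants` (default 750) founding-clone mutations each
  carried by a Bernoulli(0.97) subset of 30 islets (dropout emulates missed
  calls in tens-of-cells samples), germline variants shared with the
  matched normal, and per-islet private mutations. With 97% presence a few
  percent of roots fall below the 90% rule, so recovery is slightly below
  the founding count — as it would be with real dropout.
- **IHC scores**: percent-3+ is a normal draw censored (clipped) to
  [0, 100]; the remaining mass is split randomly across the 0/1+/2+ bins.
  Clipping, not truncation, is deliberate: an image-analysis pipeline
  reports 0% strong nuclei for any case whose latent score is at or below
  zero, so the benign group carries a realistic point mass at 0 — and the
  rank AUC of clipped binormal samples stays within MC error of the
  binormal closed form Φ(Δ/√(σ₁²+σ₂²)) = Φ(11/√116) ≈ 0.846, whereas
  truncated-normal sampling shifts it to ≈ 0.89 by inflating the benign
  mean.

Passing tests on these generators show the machinery is correct under its
own assumptions (no LD, homogeneous rates, independent nuclei); they do not
show robustness to LD structure, coverage-dependent callability, or
between-sample rate heterogeneity, none of which are modeled.

## Numerical and design choices

- One global seed; every stage derives an independent child generator via
  `numpy.random.SeedSequence.spawn`, so runs are bit-identical per seed and
  stages stay independent.
- Window counting uses sorted-position binary search; expectations are
  accumulated in simulation chunks to bound memory.
- Acceptance-scale problem sizes: the Poisson type-I check uses 2,000
  non-overlapping 40 kb windows (an 80 Mb null region) so the binomial SE of
  the rejection fraction (~0.005) is small against the [0.03, 0.07] band;
  signal-recovery checks use 100 seeded runs on a 2 Mb region with a panel
  density of ~1 common SNP per kb; the AUC check uses 30,000 cases per group
  (SE < 0.003).
- The discrete Poisson test at nominal 0.05 has achieved size ≈ 0.03–0.05
  for window means λ ≈ 10–20 (it oscillates with λ and is conservative);
  at the default rare-variant rate λ ≈ 14 per 40 kb window and the achieved
  size is ≈ 0.045.

## Known limitations

- No LD-aware simulation, no coverage/callability correction, no gene-level
  burden tests; indels and structural variants are out of scope (SNVs only).
- The order-statistic p-value's resolution is 1/N; reporting "< 1/N" is a
  floor, not an estimate.
- VCF output stores the quality flag and somatic status at site level
  (FILTER / INFO); tables whose rows disagree within one variant round-trip
  losslessly only through TSV.
- The enrichment "hit" rule (q < 0.01, > 10 supporting genes) is a
  convention of the analysis design, not a calibrated error rate.
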