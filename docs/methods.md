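# Methods

## Study design being modeled

The pipeline targets a pooled-array design: four tumor stages (Dukes A–D),
each represented by one pooled tumor-vs-normal comparison of six patients.
Two-color aCGH and mRNA arrays are run in technical triplicate; single-color
microRNA arrays in duplicate. Pooling is modeled as a single latent profile
per stage — the pool averages patient heterogeneity before hybridization —
with an optional extra variance term (`extra_pool_sd`, default 0) rather
than individual patient profiles.

Coordinates are 0-based half-open throughout; BED convention on disk. Sex
chromosomes are excluded by default so genome-wide denominators match
autosome-only reporting.

## aCGH arm

**Normalization.** Each replicate is median-centred (`median_normalize`);
technical replicates are averaged per probe, ignoring missing values.

**Segmentation.** Circular binary segmentation, recursive: the arc (i, j]
maximizing the mean-difference statistic between probes inside and outside
the arc is accepted as a split when its permutation p-value is below
`alpha` (default 0.01; permutations default 10,000, reducible in config).
The statistic is scaled by the overall sample SD of the segment's values
rather than a split-wise pooled SD; since the SD is invariant under
permutation, the test reduces to the maximum bridge increment
|U[j] − U[i]|·√(n/k(n−k)), and the range bound max|ΔU| ≤ max U − min U lets
whole arc widths be skipped per permutation — clearly significant splits
cost O(n) per permutation instead of O(n²). The arc statistic equals its
complement's, so the linear scan covers all circular splits. An accepted
interior arc splits the vector into three pieces; recursion stops when no
split is accepted. No undo/pruning pass is applied. Minimum arc width is 2
probes. Permutation seeds derive deterministically from `random_state`.

**Base-pair boundaries.** Segment bounds run midpoint-to-midpoint between
flanking probes; at chromosome ends they run from the first probe position
to the last position + 1. Gained/lost kb are measured on those bounds.

**Calling.** The gain/loss cutoff is the sample SD (ddof = 1) of the pooled
median-normalized probe values across all arrays and stages. Calls use
strict inequalities; a segment mean exactly at ±cutoff is neutral
(conservative tie-break). The 20th/80th percentiles of segment means are
available as a diagnostic (`segment_mean_percentiles`) but are not
enforced. Note that when real alterations are present the pooled SD exceeds
the pure-noise SD (with the default planted design, ≈ 0.14 vs noise 0.1);
the cutoff is derived from the data at hand by construction.

**Summaries.** Per stage: gained/lost kb per chromosome, percent of genome
altered (rounded to integer, halves away from zero), and the chromosome
alteration-event count (#chromosomes with any gain + #with any loss).

## Minimal common regions

`compute_mcr` is the support-constant decomposition: per chromosome and
sign, the genome is partitioned into maximal intervals over which the set
of stages carrying a same-sign alteration is constant. This is the
computable core of the published MCR construction; gap-joining and
amplitude-ranking heuristics are deliberately omitted (a max-join-gap hook
defaults to 0 — i.e. off). Gains and losses never merge. Recurrence
coverage at k is the fraction of aberrant bases in regions supported by ≥ k
stages.

## Expression arm

**mRNA.** The two-color within-array design reduces tumor-vs-normal to a
one-sample test on per-replicate M-values. Each replicate is lowess-
normalized against its A-values (span 0.3, 3 robustness iterations —
chosen, not prescribed) before testing.

**microRNA.** Tumor and normal single-channel duplicates are quantile-
normalized jointly (ties averaged), then paired into M-values
(tumor − normal per replicate).

**Moderated t.** logFC is the replicate mean; s²_g the replicate variance
with d_g = n−1 df. The variance prior (d₀, s₀²) is fitted by closed-form
moment matching on log s²_g (digamma/trigamma, Newton inversion of the
trigamma). When the observed spread of log-variances does not exceed
chi-square sampling noise, d₀ = ∞ and s₀² is the mean sample variance.
Zero-variance features are excluded from the fit and assigned s₀².
The posterior variance is the usual precision-weighted blend, the t
statistic is referred to Student t with d₀ + d_g df, capped at the pooled
residual df (the prior is estimated from the same data and cannot carry
more information than that). Both conventions were validated against an
independent reference implementation on a shared fixture.

With duplicate arrays (d_g = 1), the prior-df estimate is noisy per
dataset: log χ²₁ variances are heavy-tailed, so d₀ can be badly
underestimated on a single realization even at a few hundred features, and
single-dataset p-value uniformity wobbles. Calibration is therefore
assessed on average over seeds (type-I error at nominal 0.05), which is
stable; triplicate designs (d_g = 2) at 10⁴ features pass a per-dataset KS
uniformity check directly.

**Calls and summaries.** BH q-values; up/down calls require |logFC| above
the cutoff (1.0 mRNA, 0.5 microRNA — log₂ scale) *and* q < 0.05, strict
inequalities. The stage trend test regresses per-feature stage means on
equally spaced stage codes 1–4 (the coding is an assumption), with residual
df 2 per feature, moderated by the same machinery; a feature with zero
slope and zero residual variance reports p = 1. The direction-frequency
test is the 1-df chi-square of the up/down split against 50:50,
(n_up − n_down)²/(n_up + n_down).

## Interaction scan

For each stage, two-sided Fisher exact tests (point-probability rule, as in
scipy) on (genes in/out of region) × (DE / non-DE), at three scopes:
pooled aberrant genome, per-chromosome pooled aberrant bases, and each
aberrant segment. The background excludes region genes. Gene-to-region
mapping defaults to any-overlap (a midpoint rule is available); a gene
covered by several aberrant segments takes its call from the
highest-|mean| covering segment. Segment-scope p-values are reported
unadjusted by default (p < 0.05 significant; a BH option exists but is
off), matching the source analysis convention.

An "interaction gene" must be direction-concordant (gain & up or loss &
down) *and* lie in a segment whose scope test is significant — the
strictest reading of the published filter chain, fixed here as a design
choice. Stage-set logic uses unions: the late-discriminating set is
(C ∪ D) − (A ∪ B); the all-stage intersection is reported separately (the
"carcinogenesis" candidate set), as are early-only and D-only sets. A
microRNA "interacts" in a stage when it is DE there and its locus lies in
an aberrant segment of that stage.

## Synthetic-data generator

The generator's defaults are the assumed study conditions, not tuning
knobs: probe noise SD 0.1 log₂; planted segment amplitude ±0.3; nested
progressive planting (every early segment persists later; gains only in
stage A; altered bases grow A ≤ B ≤ C ≤ D, ≈ 3/7/14/19% of the default
10 × 100 Mb genome); dosage coupling coefficient 4.0 (SD 0.25) applied to
80% of genes under planted segments, so a coupled gene's expected |logFC|
is ≈ 1.2 — above the mRNA cutoff; 5% background DE at effect 1.5 in all
stages; 15% of microRNAs DE at effect 0.8, signs concordant with any
covering planted segment. Nuisance structure exercised by each
normalization step: per-replicate channel offsets (SD 0.05) removed by
median normalization; an intensity-dependent quadratic term (coefficient
0.02) removed by lowess; per-array affine distortions (scale SD 0.05,
offset SD 0.3) removed by quantile normalization. A tumor-purity dilution
knob exists but defaults to off (1.0). Everything is deterministic given
the config seed (independent named substreams per array type).

What the generator does **not** emulate: spatial array artifacts, dye bias
beyond offset/curvature, probe-specific affinities, biological pathway
correlation between genes, patient-level survival structure, and real
genome annotation. Passing recovery tests therefore demonstrate the
statistical machinery under the assumed noise model, not performance on
real arrays.

## Problem sizes and numerical choices

The default synthetic genome is 10 chromosomes × 100 Mb with 2,000 CGH
probes per chromosome, 200 genes per chromosome and 200 microRNAs; the
recovery suites run 20 seeds at this scale with permutations reduced to
1,000 (500 for the end-to-end suite at 800 probes/chromosome, 120
genes/chromosome), sizes chosen to keep full runs in the minutes range on
one core. Reported percentages round half away from zero to integers; raw
fractions are also emitted. Ties at the call cutoff are neutral;
quantile-normalization ties are averaged; BH q-values are clipped at 1.

## Known limitations

* The MCR decomposition omits the original construction's gap-joining and
  amplitude ranking, so absolute MCR counts are not comparable to published
  totals (which also depend on undeposited arrays).
* The CBS variant has no undo/pruning step and uses a global-SD statistic;
  on data with strong within-segment variance changes it may oversegment.
* With duplicate arrays the variance prior is noisy (see above); exact
  per-dataset calibration at d_g = 1 is not guaranteed.
* Strict per-seed nesting of early interacting microRNAs inside late sets
  is an expectation-level pattern: a truly DE microRNA can miss a
  late-stage call by sampling noise, so the property is checked in
  aggregate across seeds.
* The interaction filter chain ("significant scope AND concordance") is one
  reading of an under-specified published procedure; alternates (chromosome-
  scope significance, adjusted scans) are exposed as options but untested
  against published gene identities, which are not reproducible without the
  original arrays.
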