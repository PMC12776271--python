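# Methods

This note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic data do and do not establish.

## Differential count testing

Counts are modelled per feature as NB(*m*, *α*) with Var(*K*) = *m* + *αm*².
Size factors are DESeq-style median-of-ratios over features with a nonzero
geometric mean, rescaled to geometric mean 1 (a pure convention; only ratios
matter downstream). When no feature is expressed in every sample the
estimator falls back to library-size ratios with a warning.

Dispersion is method-of-moments, *α̂* = max(0, (s² − m̄)/m̄²), computed on
normalised counts pooled **within condition** (Bessel-corrected variance)
and averaged across the two conditions. Constant features give exactly 0. A
multiplicative small-sample inflation was evaluated and rejected: it made
the Wald test visibly conservative at the sample sizes this package targets,
while the plain moment estimator keeps the null p < 0.05 rate near nominal.
Inside the Wald variance the dispersion is floored at 1e-8 so a zero
estimate never produces a degenerate variance.

The test statistic is built per block (cell line): the log2 ratio of
normalised condition means, with a 0.5 pseudo-count inside the ratio to keep
fold changes finite, and a delta-method variance
Var(log2 m̄) = Σ_j(m/s_j + αm²)/n² / ((m̄+0.5)² ln²2). Blocks are combined by
inverse-variance weighting — the contrast analogue of the additive
`~ cell_line + condition` design; a block missing one condition is dropped
with a warning. Two-sided normal p-values are BH-corrected across features
and features are classed up/down/ns at |log2FC| > 1, adjusted p < 0.05.
Zero-mean features are reported with log2FC 0 and p 1 rather than dropped,
keeping result tables rectangular. Shrinkage of effect sizes, outlier
replacement and variance-stabilising transforms are deliberately out of
scope; at the effect sizes and replication this package simulates they are
not what decides the calls.

## PWM scanning

A PFM column with counts *c_b* becomes probabilities
(*c_b* + 0.8·*bg_b*)/(Σc + 0.8) — the 0.8 pseudocount is a common default
and is configurable, as the convention varies between databases — and
log-odds log2(p/bg) with a uniform background unless supplied. N bases
contribute 0 (background). The *match fraction* rescales a window's summed
log-odds between the minimum and maximum attainable sums, so the 70 %
threshold is invariant to per-column shifts of the log-odds and comparable
across motifs. Scanning covers both strands of a 400 bp window centred on
the peak summit (truncated with a warning at chromosome ends); the offset
reported is motif midpoint minus summit. `best_central` keeps, per
peak×motif, the hit minimising |offset|, breaking ties by higher score and
then the + strand — a deterministic total order.

Set-level enrichment uses 500 bp windows and peak-level hit indicators
(a peak either contains a match or not); the default background is a seeded
mononucleotide shuffle of the foreground sequences, which corrects for base
composition without requiring a genome-wide null — a deliberate,
documented simplification of binned composition-corrected enrichment
modelling. log2 enrichment uses ε = 1e-3 on both fractions; p-values are
two-sided Fisher exact tests on the 2×2 peak-hit table, BH-corrected across
motifs.

Motif families come from average-linkage clustering of
1 − max-Pearson similarity, where the similarity is the best Pearson
correlation of flattened aligned probability columns over all ungapped
offsets (minimum overlap 4 columns) and both orientations. The family label
is the member with the highest mean within-family similarity — a
data-driven replacement for curated name-based family regexes.

## Footprinting

Each fragment contributes two insertion events at start + 4 and end − 5
(the Tn5 dyad convention); profiles are site × 200 bp matrices centred on
motif midpoints. The raw footprint score per site is
log2((flank + 0.1)/(centre + 0.1)) with 30 bp flanks abutting the motif
span; deeper protection ⇒ higher score. Motif-level raw scores (means over
sites) are min-max normalised across the motif panel within each condition,
which puts the conventional 0.2 delta threshold on a meaningful [0, 1]
scale for an unbounded log-ratio statistic; a consequence is that the delta
is only interpretable when the panel spans a range of footprint depths, so
panels should include both protected and unprotected motifs. P-values come
from permuting per-site raw scores between condition labels (two-sided,
add-one corrected) rather than from a parametric background model — exact
at the site counts involved and assumption-free. Motifs with fewer than 20
sites in either condition are skipped with a warning. No sequence-bias
correction is applied: the synthetic fragments are bias-free, and this is
the main caveat when pointing the module at real ATAC data.

## Network construction

Peaks are assigned to genes by summit: a summit inside a half-open
[TSS − 3 kb, TSS + 3 kb) promoter window assigns to that gene (nearest TSS
if several), otherwise to the nearest TSS within 100 kb as a distal
assignment. A candidate edge TF→target exists when a peak assigned to the
target carries a hit for the TF's motif. The edge confidence is a
transparent surrogate for a trained regulatory-potential model: the
geometric mean of (i) the best hit's match fraction, (ii) the linking
peak's accessibility quantile rank within the condition's mean normalised
ATAC signal, and (iii) |Pearson r| between TF and target expression. All
three components live on [0, 1], so the conventional 0.5 score cutoff
applies; both the score cutoff and the |r| > 0.3 filter are enforced
simultaneously. Two deliberate choices:

- Correlation is computed across all of the condition's samples with
  **within-block centring** of log2 normalised expression. Pooling cell
  lines without centring lets block baseline offsets masquerade as
  co-expression and materially inflates false edges; centring is the
  correlation analogue of the additive design used for testing.
- TF self-edges are excluded: a gene's correlation with itself is 1 by
  construction and carries no evidence.

Degree centrality is out-degree/(N − 1) with N the node count of that
network (regulatory influence, not regulation received); TFs absent from a
network get degree 0 so Δdegree is always defined, and replicate networks
are averaged when given. The TF–TF projection weights pairs by shared
target counts; network overlap reports the Jaccard fraction of (TF, target)
keys plus both per-network shared fractions. The TF summary joins
connectivity, expression and footprint modalities per TF, grouping by
expression status (up → Activated, down → Repressed, ns → Unchanged) and
carrying missing values rather than dropping TFs absent from a modality.

## Cistrome stratification

Overlap is ≥ 1 bp with no reciprocal-fraction requirement — the published
shared-peak percentages this package reproduces are consistent with plain
any-overlap counting. Shared counts are intrinsically two-sided, so both
sides and the merged-union count are always reported. Context annotation is
decided by the summit with promoter > intragenic > distal priority; gene
bodies span [min(TSS, TES), max(TSS, TES) + 1). DAR counts per group use
any-overlap against the group's peaks; DEG counts deduplicate genes (a gene
linked by two peaks counts once). The redistribution statistic is the
fraction of one factor's condition-lost peaks overlapped by the other
factor's condition-gained peaks, with the promoter-proximal share of that
subset.

## The synthetic generator

The generator emulates the study design the analysis assumes: two
conditions (CON/IND) × two cell-line blocks, NB counts, planted effects,
and condition-specific TF binding. Key defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `nb_dispersion` | 0.05 | NB α typical of bulk RNA-seq between biological replicates |
| `nb_mean_log_range` | (3, 9) | log2 baseline means, ~8–512 counts |
| `block_log2_sd` | 0.5 | per-feature × cell-line baseline offset (additive design, no interaction) |
| `depth_log2_halfwidth` | 0.5 | per-sample depth factors, so size-factor estimation is non-trivial |
| `de_lfc` / `dar_lfc` | 2.0 | planted |log2FC|, alternating signs |
| `footprint_protection` | 0.8 | fractional Tn5 depletion over bound motifs |
| `coexpr_log2_sd` | 0.8 | SD of the shared per-sample latent factor linking a TF to its active targets (gives r ≈ 0.8 after NB noise) |
| `bound_peak_boost` | 2.0 | accessibility factor for motif-carrying peaks (static) and again in the bound condition |
| panel width / sharpness | 18 / 91 % | high-information motifs so the 70 % match rule has desk-scale specificity (~0.03 chance hits per window) |

Truth assignment is deterministic: the first ⌈fraction·n⌉ features after a
seeded shuffle, so recovery assertions are exact, and ⌈rewire_fraction·n⌉
TFs are bound (and regulate) in exactly one condition, alternating
IND-only/CON-only. Planted motif instances are the PWM consensus written
into the genome at recorded offsets; never-bound decoy motifs
(`n_unbound_tfs`) can be added to give footprint panels dynamic range.
Fragments place two insertion sites per fragment sampled from the per-base
density (uniform within the peak, × (1 − protection) over bound spans in
the bound condition), with ends positioned so the +4/−5 shift recovers the
sampled sites exactly. Everything is reproducible bit-for-bit from the
config seed, with independent sub-streams per stage.

Problem sizes used by the test suite and the acceptance script are chosen
for statistical adequacy at desk scale: differential testing is exercised
at 1000–2000 features with 6–10 samples per condition; network inference
uses 16 samples per condition because a Pearson |r| > 0.3 edge filter is
uninformative at very small n (the null sd of r at n = 6 is ≈ 0.45, at
n = 16 ≈ 0.26); footprint panels use ≥ 40 sites per motif. The rewired-TF
ranking scenario uses a 10-TF panel with 10 % rewired so that "top decile"
is a meaningful rank set.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: read-level artefacts (duplicates, mappability,
GC bias), Tn5 sequence bias, overdispersion heterogeneity across features,
peak-calling uncertainty, indirect TF–target regulation, TF cooperativity
and motif co-occurrence, and block × condition interactions. Recovery rates
here are upper bounds for data with those complications.

## Numerical conventions and degenerate inputs

All intervals are 0-based half-open; TSS/TES are inclusive base positions.
Ties in best-central scanning resolve by |offset|, then score, then strand.
Zero-variance expression gives correlation 0 (never NaN). Empty networks
degrade to zero degrees, and empty overlaps to NaN, with warnings. Min-max
normalisation of a constant panel returns 0.5 for all members. Permutation
p-values use the add-one estimator, bounded below by 1/(n_perm + 1).
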