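# Methods

This note records the models, parameter choices and numerical conventions
behind `oodyn`, and what the synthetic-data generator does and does not
emulate.

## Quantification and spike-in calibration

TPM is computed over *all* matrix rows, spike-ins included. This is
deliberate: the spike-ins are added in a fixed absolute amount per sample,
so they only carry absolute information if they share the per-million
denominator with the endogenous genes. The calibration factor
`k_s = median(spike TPM mass) / spike TPM mass of s` uses the cohort-median
sample as the anchor rather than a designated reference sample, which makes
it robust to a single degenerate oocyte. The factor is computed on the
current calibrated values, making recalibration a no-op (unit correction).
Calibration rescales whole columns, so within-sample gene ratios are
untouched; dosage summaries then sum calibrated values over endogenous rows
only.

A consequence worth stating: a *global* dosage change (every transcript
scaled equally) is invisible to relative, per-gene differential expression
— size-factor normalisation removes it by construction. Detecting it is
exactly what the spike-in calibration is for; the two analyses are
complementary, not redundant. Differential testing therefore runs on raw
counts with internal size factors, while dosage, binning, PCA and the decay
taxonomy run on calibrated values.

Group comparison of per-sample dosage totals uses the unequal-variance
(Welch) two-sample t form. At n ≈ 3–5 per group the equal-variance
assumption buys nothing and can mislead; Welch is the safer default.

Expression-distribution bins default to (0, 2, 10, ∞): the 2 matches the
analysis floor used by the decay taxonomy and the 10 the conventional
"highly expressed" cutoff; both are configurable.

## Differential expression

The NB/Wald test is implemented from first principles rather than calling
an existing differential-expression package, so its behaviour is fully
specified by this note:

- **Size factors**: median-of-ratios against per-gene geometric means,
  restricted to genes observed in every sample; if no such gene exists,
  library sizes normalised to geometric mean 1.
- **Dispersion**: method-of-moments `α̂ = max(0, (s² − μ̄)/μ̄²)` on scaled
  counts, variance pooled within genotypes (group means centred out,
  denominator n − 2), then shrunk with weight 0.5 toward a fitted trend
  `α(μ) = a₀ + a₁/μ`, floored at 1e-8. The shrinkage stabilises the very
  noisy per-gene moment estimates at n = 3 without assuming a shared
  dispersion.
- **Wald statistic**: the group-mean variance under NB
  (`Var(mean) = q·Σ(1/s_i)/n² + αq²/n`) is propagated to
  `log2((q_mut+½)/(q_ctrl+½))` by the delta method; p values are two-sided
  normal. The ½ pseudocount inside the ratio keeps zero-count genes finite
  and shrinks their fold changes toward 0, which is the desired behaviour
  at n ≤ 3. Genes with zero counts in both groups get p = 1.
- **Calling**: BH step-up adjustment (own implementation,
  `padj_(i) = min_{j≥i} m·p_(j)/j` capped at 1; NaNs excluded from m and
  propagated), then strict thresholds: up iff `log2FC > 1` and
  `padj < 0.05`. A gene sitting exactly on either boundary is not called.

Measured behaviour under the generator's conditions (seed-fixed in the test
suite): empirical type-I error at nominal 0.05 is ≈ 0.06–0.07 with
dispersion 0.1 at n = 3 + 3; power at |log2FC| = 2 in a 10%-DE background
is ≈ 0.93–0.95; false-discovery proportion at the calling thresholds stays
below 0.1.

## Decay taxonomy

Per-gene stage summaries use the **median** over replicate samples of
`log2(calibrated TPM + 1)` — robust at n ≤ 5, and the +1 keeps zeros
finite. The expression filter keeps genes whose control stage-summary TPM
exceeds 2 (strict) at ≥ 1 stage. Transition status is **inclusive** at the
threshold: |Δ| exactly equal to `fc_log2` (default 1) counts as changed, so
"2-fold" means at-least-2-fold; the same convention is used by the quadrant
analysis so that its four quadrants exactly partition the eligible DEGs.
Clusters are defined on control trajectories only; mutant genes inherit the
control cluster.

Per-cluster decay impairment is the median over member genes of
(mutant Δ − control Δ) summed over the cluster's degrading transition(s),
with a one-sided Wilcoxon signed-rank test (positive statistic = decay
impaired). The symmetric statistic on elevating transitions
(control − mutant, positive = elevation impaired) quantifies ZGA failure in
cluster VI.

## Gene-set overlaps

Overlap percentages are reported both in full precision and display-rounded
(half away from zero) to integer percent, matching how such fractions are
usually printed. The enrichment p is the upper-tail hypergeometric
probability via `scipy.stats.hypergeom`; the test suite checks it against
direct PMF summation with exact binomial coefficients to 1e-10. The
universe defaults to the set of genes actually tested at that stage and is
configurable, since overlap enrichment is only meaningful relative to an
explicit universe.

## Interactome calling

Enrichment over the empty-vector background uses the signed positive
direction only — bait pulldown enrichment is one-sided even when the
threshold is quoted as an absolute value — and is strict (> 10-fold).
Reduced binding is inclusive (Mut/WT ≤ 2/3, i.e. ≥ 30% reduction) and gated
on wild-type interactor status, so background proteins can never be
"reduced". Zero intensities are offset by a small pseudo-intensity (default
0.01) rather than imputed; this keeps the rule monotone in the data.
Replicates, when present, are collapsed by the geometric mean of positive
observations before calling.

## Synthetic-data generator

The generator emulates the statistical structure of a control/mutant
GV–MII–D3 single-cell design:

- **Trajectories**: genes are laid out on the nine clusters with signed
  log2 steps of magnitude `cluster_step_log2` (default 2, i.e. 4-fold) per
  transition. The baseline distribution (`baseline_log2_mean` 5,
  `baseline_log2_sd` 1.5) anchors each gene's day-3 control level; the GV
  level is the anchor minus the net signed step. Transcripts destined for
  degradation therefore start high (stockpiled maternal mRNA) and
  ZGA transcripts start low, which reproduces the declining control total
  dosage across GV → MII → D3.
- **Mutant effects**: endogenous GV rates scaled by
  `mutant_gv_dosage_factor` (default 0.6, a 40% storage deficit); each
  degradation step retains only `mutant_decay_attenuation` (default 0.3) of
  its log2 magnitude; each day-3 elevation step realises only
  `mutant_zga_attenuation` (default 0.3). Setting all three to neutral
  makes the mutant rate matrix identical to control.
- **Spike-ins**: 92 spike species with nominal amounts log-uniform over
  four decades, identical absolute rates in every sample, scaled to 5% of a
  control GV library's read mass. Spike lengths are fixed at 1 kb; gene
  effective lengths are log-uniform in [500, 5000] b so TPM differs from
  raw proportions.
- **Counts**: a per-library depth is drawn log-normal (mean 2e6, CV 0.2 —
  typical of low-input libraries), allocated across transcripts in
  proportion to rate × length, and counts drawn gene-wise as
  gamma-Poisson (NB) with dispersion `nb_dispersion` (default 0.1). All
  sampling flows through one seeded generator; a seed fixes the experiment
  byte for byte.
- **Truth**: per-gene cluster, the full stage × genotype rate matrix,
  ZGA (= cluster VI) and M-decay (= clusters I ∪ III) memberships, and
  per-sample absolute endogenous dosage.

What it does **not** emulate: batch or technical covariates, gene–gene
correlation, gene-specific mutant effects at GV (the GV deficit is purely
global, so per-gene GV DE counts are near zero by design — real data shows
both global and gene-specific changes), transcript-level multi-isoform
structure, and dropout beyond what NB sampling at the configured depth
produces. Passing tests therefore demonstrate that the analysis recovers
the planted global structures under realistic noise, not that it handles
every artefact of real low-input libraries.

## Problem sizes and determinism

The default simulated experiment is 9 × 200 genes + 92 spikes × 18–30
samples; calibration simulations use 2000-gene two-group designs. These
sizes give Monte-Carlo-stable statistics (cluster recovery varies by ~2
points across seeds, the dosage-ratio estimate by ~±0.04) while keeping the
whole test suite and the acceptance script in the seconds range. All
stochastic tests fix seeds; `scripts/acceptance.py` derives every
sub-simulation seed from its `--seed` argument via `SeedSequence`.

## Known limitations

- The Wald test with moment dispersions is mildly anti-conservative at
  n = 3 (empirical type-I ≈ 0.065 at nominal 0.05); no fold-change
  shrinkage or independent filtering is applied.
- The decay taxonomy is threshold-based by design (no smooth kinetic fits
  or half-life estimation); genes near a boundary flip clusters under
  resampling.
- Interactome replicate handling assumes intensities are comparable across
  conditions after geometric-mean averaging; no normalisation across
  pulldowns is attempted.
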