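# Methods notes

This note documents the models, defaults and numerical choices behind
`myoph`, and what the synthetic phantoms do and do not emulate.

## Tissue acidity maps (`tissue_acidity`)

**Procedure.** Background mean and SD are sample statistics (SD with
denominator n−1) over an explicit tissue-free mask. Channels are
background-subtracted and resampled bilinearly; `resize_factor` > 1
*downscales* linear dimensions — whole-section tiled scans are large, and
downscaling also pools signal — while values < 1 upscale. A pixel enters the
ratio map only if its background-subtracted value exceeds `threshold_k`
(default 2) background SDs on *both* channels; this is identical to
requiring the raw value to exceed mean + k·SD. Kept ratios are divided by
their median, so the map's median is exactly 1. Excluded pixels carry NaN,
not zero, so histograms are unbiased.

**Histogram decomposition.** A hand-written EM fit of a k-component
univariate Gaussian mixture (default k = 3, unconstrained variances)
decomposes the defined ratio values. Initial means are quantile-stratified
(first restart at the central quantiles, subsequent restarts at one random
quantile per stratum), sharpened by a few k-means passes; 10 restarts by
default, the highest final log-likelihood wins, ties to the earliest
restart. The log-likelihood is asserted non-decreasing across EM iterations;
component SDs are floored at 1e-6 of the data SD to avoid collapse.
Components are reported sorted by mean. Skewness is the bias-uncorrected
Fisher–Pearson statistic m₃/m₂^(3/2). Non-convergence is reported through a
flag, never an exception. Freedman–Diaconis binning is used for display
histograms only; the fit always uses raw values.

## Dye calibration (`ph_calibration`)

**Model.** A 4-parameter logistic in pH (single protonation site with a
Hill slope, default 1, fixable): R(pH) = R_min + (R_max − R_min)/(1 +
10^(h·(pKa − pH))). R_min is the acid asymptote and may be larger or smaller
than R_max, so the same equation and the same closed-form inverse cover dyes
whose ratio rises (H34580 440/490) or falls (cSNARF1 580/640) with pH.

**Fitting.** Bounded nonlinear least squares initialised from order
statistics of the data (asymptotes from the observed extremes oriented by
the level means, pKa from the pH nearest the ratio midpoint) — deterministic
and invariant to row order. At least 4 distinct pH levels are required (3
with the Hill slope fixed). A series whose ratio spread is negligible, or
whose fitted dynamic range falls below 0.05 ratio units, is rejected as
pH-insensitive (the behaviour of SYTO-family dyes).

**Inversion.** Ratios must lie strictly between the asymptotes; values
outside by up to 1% of the dynamic range (configurable) are clamped, values
further out are undefined (NaN) and propagate as per-cell quality flags.

## Monolayer quantification (`nucleo_cyto`)

**Segmentation.** Otsu threshold → hole filling → distance-transform
watershed (markers from `peak_local_max`, minimum separation derived from
the configured area window) → size filter, relabelled 1..n. The algorithm is
deterministic and pluggable; no training data is needed.

**Annuli.** The perinuclear width is one shared integer per field:
round(mean equivalent radius), where the equivalent radius is that of the
circle with the region's area. The annulus is every background pixel within
that width of a nucleus; contested pixels go to the nucleus with the nearest
centroid (deterministic and order-independent). Annuli are disjoint from all
nuclei and from each other.

**Per-cell pH.** Region ratios are ratio-of-means (mean numerator / mean
denominator), which is less biased than mean-of-pixel-ratios at low SNR;
a flag can switch behaviour in future versions if pixelwise ratios are
needed. pHn inverts the H34580 ratio over nuclear pixels, pHc the cSNARF1
ratio over the annulus; ΔpHnc = pHn − pHc is recomputed and asserted on
every record. No nuclear-mask erosion is applied by default. Cells with
out-of-range ratios are flagged and excluded from summaries by default.

**Hierarchy.** Two levels (cell < isolation): cells are averaged within
isolation, isolations are weighted equally, and SEM is the SD of isolation
means over √n_isolations. With one isolation the SEM is undefined (NaN).
Coupling slopes are OLS of condition-mean pHc (and pHn) on pHe; at least 3
distinct levels are required.

**Noise propagation.** For the uniformity control, the expected ΔpHnc
scatter is computed first-order: a region ratio-of-means with additive
channel noise SD s, denominator level B and n pixels has SD ≈
(s/(B√n))·√(1+R²); dividing by |dR/dpH| of the titration curve converts to
pH units, and the nuclear and cytoplasmic terms add in quadrature.

## Synthetic data (`synthetic_data`)

All generators take an explicit integer seed; identical spec + seed gives
byte-identical output. Noise is additive Gaussian per emission channel,
chosen over Poisson for analytic tractability (region-mean noise then has
the closed form above).

**Tissue phantom.** An elliptical tissue disk with an inner-wall band
(fractional elliptical radii 0.45–0.75 by default) at niche pHe 6.4 against
background pHe 7.4. pHLIP signal = gain × density × f(pHe) with f a
decreasing logistic centred at the insertion pK (default 6.6, slope 1/pH) —
the insertion curve of the probe in myocardium is not established, so the
pK is an explicit, configurable parameter; only monotone decrease matters
to the pipeline. Hoechst tracks density only. The tissue-free surround is
returned as the background mask.

**Monolayer phantom.** Disk nuclei (radius 8 ± 1 px) are rejection-sampled
with enough clearance that annuli stay disjoint; each (pHe level, isolation)
is one 640×640 field. Ground truth follows an explicit affine coupling
model, by default

    pHc = 4.9 + 0.3·pHe            (cytoplasm tracks pHe at 0.3)
    ΔpHnc = 0.82 − 0.1·pHe         (so pHn = 5.72 + 0.2·pHe)

giving a positive nuclear-cytoplasmic gradient of 0.08–0.20 pH units that
widens in acid. Cell-level jitter (SD 0.03 pH) and isolation-level offsets
(SD 0.02 pH, shared across levels — the same biological isolation is split
across media) make the hierarchical aggregation non-trivial. Dye ratios are
painted from the configured calibration curves (defaults are synthetic
placeholders, not measured dye constants) at denominator intensity 120 with
channel noise SD 2.

**Omics tables.** True DEGs (default 3% down + 3% up of 2000 genes) get
p ~ Beta(1, 2000) and signed fold-changes of mean magnitude 1.5; nulls get
p ~ U(0,1). Matched proteins are sampled from the true DEGs and share the
gene's direction with the configured concordance probability. Union peaks
carry per-condition Bernoulli presence flags rejection-sampled to guarantee
presence in ≥ 1 condition. TSSs sit on a jittered grid on a separate
chromosome from background peaks, so the fraction of genes with a promoter
peak is a clean Bernoulli draw of the configured probability.

**What the phantoms do not emulate** — optics (PSF, bleaching, 3-D),
Poisson photon statistics, realistic cardiomyocyte morphology, touching
nuclei at high density, fibroblast contamination, or the internal
statistics of DESeq2/DEP (whose output tables are this pipeline's inputs).
Passing tests therefore demonstrate correctness of the computations under
a known forward model, not robustness to every pathology of real data.

## Omics statistics (`omics_concordance`)

BH adjustment delegates to statsmodels' step-up implementation; tests check
it against a literal transcription of the definition. Classification is
strictly `padj < alpha` with direction from sign(log2FC); significant
features with exactly zero fold-change are excluded with a warning (note
that at alpha = 1 a feature whose adjusted p is exactly 1 is excluded by the
strict inequality). The concordance table counts only features significant
in both layers; the odds ratio is ad/bc, reported infinite when bc = 0 and
ad > 0. The Fisher test is the exact two-sided enumeration: hypergeometric
probabilities over the margin-fixed support, summing those ≤ the observed
table's probability with relative slack 1e-12 for floating-point ties.

Percentages mirror how printed figures are derived: rounded to the nearest
integer, ties away from zero; unrounded values are retained alongside.
Intervals are 0-based half-open throughout; TSS positions are 1-based in
input TSVs and converted on read. The promoter window is TSS ± 2000 bp
(configurable), start clipped at zero, and by default peaks present in any
condition count (a flag restricts to one condition). The spike-in factor is
(dm6_input/rn6_input)/(dm6_ip/rn6_ip), which equalises exogenous-genome
recovery of IP relative to input across samples and is invariant to
sequencing depth.

## Problem sizes

The slope-recovery experiment uses 5 pHe levels × 500 cells × 5 isolations
(2500 cells), matching the order of magnitude of a real monolayer
experiment (hundreds of cells per level over 5 isolations) and completing
in well under a minute; across seeds the recovered slopes scatter by about
±0.002 around the generative values. The mixture-recovery check uses 10⁴
samples; the exhaustive Fisher sweep covers every 2×2 table with total ≤ 40.
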