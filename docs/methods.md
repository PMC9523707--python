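# Methods

`gcxfp` implements the combined untargeted + targeted (UT) fingerprinting
workflow used to profile volatilomes by comprehensive two-dimensional gas
chromatography with time-of-flight mass spectrometry (GC×GC-TOF MS), together
with a seeded synthetic-data generator that emulates the study design of a
maize-silage inoculation experiment (two herbage dry-matter levels, an
uninoculated control and two lactic-acid-bacteria treatments, plus pooled
quality controls).  This note records the models, the defaults and why they
were chosen, and what the synthetic data can and cannot demonstrate.

## Data model

A run is a cube `counts[modulation, point, m/z]`.  The modulation period
`P_M = 3.5 s` slices the first-dimension separation; within each period the
detector acquires 100 spectra/s (350 points/period) over a unit-mass m/z grid
35–350 (316 channels).  First-dimension retention time is
`¹t_R = modulation × P_M / 60` minutes; second-dimension time is
`²t_R = point / 100` seconds, with no peak wrap-around across the period
boundary.  The TIC raster is the channel sum of the cube.  Detector units are
arbitrary non-negative counts; no baseline drift is modelled (flat baseline at
the noise median).

## Synthetic studies

The generator is first-class, tested code: every downstream stage is
validated closed-loop against structure it plants.

* **Peaks.** Each compound is a separable 2D Gaussian (σ₁ = 2.5 modulations,
  σ₂ = 0.06 s) whose integrated volume is `base × fold-change ×
  LogNormal(0, 0.12)`.  The 0.12 multiplicative SD matches the ~12.5% mean
  response %RSD typical of HS-SPME repeatability; base volumes are drawn
  log-uniformly from 2·10⁶–2·10⁷ counts so every panel analyte clears the
  S/N ≥ 100 gate in all classes.
* **Spectra.** Reference spectra are deterministic stick spectra (8–20
  channels, base peak scaled to 999) derived from a hash of the CAS number:
  reproducible without any external spectral database, and near-orthogonal
  across the library (the maximum cross-pair DMF over all 268 entries is
  < 300).  Cube points of a peak are spectrally proportional to the
  compound's reference spectrum.
* **Retention jitter.** Total relative SDs default to 0.79% (¹t_R) and 4.09%
  (²t_R), the repeatability scales of the emulated method.  Jitter is split
  into a shared per-run multiplicative drift (90% of the variance) and an
  independent per-peak residual (10%).  Run-to-run drift in
  temperature-programmed GC is predominantly systematic — that is precisely
  why template realignment works — whereas a purely independent per-peak
  jitter of the same magnitude would exceed any fixed search window for a
  mid-run peak ~13% of the time and make the all-but-one reliability rule
  unattainable by construction.
* **Design.** Default: herbage_low 3, herbage_high 3, con 6, lbuc 6, lpar 6,
  qc 6 biological replicates plus one analytical duplicate of the first
  replicate of each non-QC class — 35 runs.  QC expectations are the mean of
  configurable parent classes (default: the control class), mirroring pooled
  QC mixtures.  Run order is a seeded permutation.
* **Panel.** A documented 40-analyte subset of the packaged library spanning
  all ten chemical classes, selected so all members (plus internal standards
  and planted unknowns) elute before 30 min and are mutually separated by at
  least 4.5 combined peak widths — co-elution deconvolution is explicitly
  out of scope.  The planted class effects mirror the reported silage
  signatures: a 46-fold propionic-acid and 45-fold isoamyl-propionate
  increase in the Lpar class, 9-fold 1-propanol, elevated propionate esters,
  and depleted C6 lipoxygenase aldehydes in all fermented classes.
* **Unknowns.** Three non-library compounds present everywhere (they become
  reliable template peaks without identity) and one Lpar-only compound (it
  fails the all-but-one rule and surfaces as a peak-region feature).
* **Internal standards.** Two per run at fixed positions and equal nominal
  volume (10⁷ counts), subject to the same response noise; their synthetic
  retention positions are chosen inside the default window away from all
  panel analytes.

What the simulation does *not* emulate: chromatographic tailing, column
bleed, co-elution requiring spectral deconvolution, wrap-around, detector
saturation, or real NIST spectra.  Passing closed-loop tests therefore shows
the pipeline's logic is correct under its stated assumptions, not that it
would match commercial software output on real instrument files.

## Peak detection

Noise is estimated as 1.4826 × the median absolute deviation of the lower
half of the raster values around the raster median — peaks occupy only the
upper tail, so the estimate is immune even to very large peaks.  Local maxima
are found on a lightly smoothed raster (Gaussian, 1 modulation × 3 points;
ties broken toward the lower index) and must exceed S/N 100 above the flat
baseline.  Footprints come from a watershed on the smoothed raster, truncated
at 5% of each apex height; because a separable Gaussian truncated at fraction
*f* of its apex retains exactly 1 − *f* of its integral, measured volumes are
divided by 0.95, making planted integrals recoverable to well within 5%.
Apex spectra are taken literally from the single largest cube point of the
footprint, after subtracting a per-channel background (median over a strided
subsample of cube points) and zeroing channels below 3 channel-noise SDs —
without this cleaning, the baseline offset on all 316 channels caps weak
peaks' match factors near 700.

## Spectral similarity

DMF is `round(999 · cos²)` of Stein–Scott-weighted spectra
(intensity^0.5 · m/z^1, configurable) over the union of channels; RMF is the
same statistic restricted to the reference's channels.  Disjoint supports
score 0.  An unoptimized double-loop oracle is kept in the test suite and
must agree integer-for-integer.

## Retention indices and targeting

Linear (van den Dool & Kratz) interpolation over a C9–C25 ladder; a missing
alkane is bridged with the proportionally larger index span.  The default
ladder is derived from the packaged library itself: the library's own
n-alkane rows anchor C9–C16, C10 is the median solution over compounds
bracketed by C9/C11, and C17–C25 come from local regressions of time on
experimental index.  The resulting calibration reproduces the library's
experimental indices with median |error| ≈ 0.5 and maximum < 5 units, which
is what makes closed-loop identity assignment meaningful.  Targeting demands
index agreement within ±10 units (±15 available as the alternative preset)
plus DMF ≥ 900 and RMF ≥ 950; the best DMF wins, with ties broken by index
deviation and then library order.

## Alignment and the UT feature table

Template matching is greedy in descending DMF inside a ±0.30 min / ±0.20 s
search window (≈3× the mid-run retention SDs) with DMF and RMF ≥ 750; each
peak is consumed at most once.  The template seeds from the medoid run
(maximum total matched DMF in a pilot all-vs-all pass), iterates
match → fit → re-match twice, updates expected coordinates to matched means,
and retains entries matched in all but one run.  The retention transform is
degree-2 in ¹t_R and degree-1 in ²t_R, least-squares with one 3×MAD
reweighting pass (robust to ≲10% mismatches).  Aligned TIC rasters (bilinear
resampling through the per-run transform) average into the composite
chromatogram; watershed regions of the composite not covered by a template
apex become untargeted peak-region features.  Responses are matched 2D peak
volumes (template entries) or region-integrated volumes (regions); unmatched
cells are imputed 0 *and flagged*, so statistics can exclude them.
`%normalized response = 100 × volume / mean(IS volumes in the run)`; a run
matching neither internal standard is a hard error.

## Visual comparison

Class composites are per-point means.  The fuzzy-ratio difference image maps
`d = analyzed − reference` to hue (green positive, red negative), saturation
`|d| / (|d| + ε)` (so near-equal points render white; ε defaults to 3× the
composite noise SD because no quantitative "nearly equal" band is otherwise
defined), and brightness falling with log-scaled magnitude (linear scaling
available).  The rendering is exactly antisymmetric under argument swap and
invariant to adding a constant to both rasters.

## Chemometrics

Per-feature Fisher ratios are one-way ANOVA F statistics over the (non-QC)
classes; the sieve keeps features with F above a single configurable
threshold, default 3.84 = F_crit(4, 8) at α = 0.05 (the emulated analysis
quotes both 3.84 and "F > 4"; one knob covers both, and the α printed as 0.5
alongside 3.84 in the source material is taken as the obvious typo for 0.05).
PCA mean-centers and autoscales features before a full SVD; constant rows
are dropped with a warning.  Correlation clustering uses Pearson r with
1 − r average-linkage, two-sided t-transform P-values, Z-scored rows for
heatmaps, and flags pairs with r ≥ 0.900 and P < 0.05.  Response ratios are
class-mean fold-changes with explicit ∞ (zero denominator) and NaN (both
zero) flags.  The two-way ANOVA implements the balanced fixed-effects
decomposition `Y_ijk = μ + α_i + β_j + (αβ)_ij + ε_ijk` exactly
(SS_total = SS_D + SS_L + SS_D×L + SS_error on balanced data, checked
against statsmodels in the tests) with Bonferroni pairwise pooled-variance
t-tests producing compact letter displays.  Missing-flagged cells enter all
statistics as 0 by default (absence below S/N is a true zero response).

## Problem sizes and numerical choices

The default study (35 runs × 514 modulations × 350 points × 316 channels,
float32) processes end-to-end in about a minute; tests and the
reproduction script use a 30-minute retention window, which covers the whole
40-analyte panel while keeping cubes ~230 MB each (held one at a time —
`simulate_study` is a generator).  Run containers are single-file zips with
stored members and fixed timestamps, so identical seeds give byte-identical
artifacts and reproducible manifests.  Degenerate inputs are handled
explicitly: all-zero rasters return zero noise with a warning, zero
within-class variance yields an infinite Fisher ratio, zero pooled variance
an undefined t, and empty ANOVA cells are errors.

## Known limitations

* The identification loop is only as good as the synthetic spectra: real
  spectral similarity between congeners (e.g. homologous esters) is far
  higher than between hash-derived spectra, so real-data false-assignment
  rates would be worse than the closed-loop ones.
* The degree-2/degree-1 retention transform cannot absorb non-smooth drift;
  the all-but-one rule then silently drops affected peaks rather than
  flagging them.
* Peak regions are delineated on the composite only; a feature present in a
  single run below composite S/N is lost.
* The printed library table carries its source's internal inconsistencies
  (row totals, one CAS shared by two isomers); they are preserved verbatim
  and surfaced as warnings rather than silently repaired.
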