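# Methods

This note documents the models, estimators and numerical choices behind
`mtllps`, what the synthetic data does and does not emulate, and the known
limitations.

## 1. Measurement model

The assay confines two fluorescently tagged RNA-binding proteins on the
microtubule network and asks whether they mix or demix along the filaments.
The raw measurement is a pair of intensity vectors I_RBP1(s), I_RBP2(s)
sampled along each filament path at uniform arc step s (default: one pixel,
30 nm), each value being the arithmetic mean of bilinear samples across a
perpendicular band of physical width 120 nm (4 samples at 1-px spacing for
30 nm pixels). Arithmetic band averaging matches the "line thickness"
semantics of standard line-profile tools. Positions are generated with
`linspace(0, L, round(L/step)+1)`, which includes both endpoints; this makes
path reversal an exact symmetry of the sampling at the cost of the actual
step differing from the requested one by at most one part in the sample
count.

Channels are assumed registered; no deconvolution or chromatic correction is
attempted. Background is removed per channel with a rolling-ball estimate
(default radius 50 px); the radius is an implementation default, chosen large
against the filament width (~6 px FWHM after PSF) and small against
cell-scale intensity variation.

## 2. Ratio normalization

The per-position ratio is guarded against empty stretches with per-channel
epsilons, r = (I1 + ε1)/(I2 + ε2), ε_k = ε_frac · mean(I_k), ε_frac = 0.01 by
default. The normalized ratio is

    n_i = r_i / gmean(r),

with the geometric mean (and the channel means) taken over the *pooled*
profiles of a cell, so every filament of a cell shares one normalization and
sparse compartments barely shift the baseline.

The geometric mean — rather than the arithmetic mean — is deliberate: with
per-channel epsilons and geometric normalization, swapping the channels maps
n to exactly 1/n, so RBP1- and RBP2-dominant detections are mirror images
with identical boundaries and enrichments, and multiplying either channel by
a constant leaves n unchanged. Neither exactness holds under arithmetic-mean
normalization. For ratios scattered multiplicatively around a baseline the
two means differ by O(CV²) ≈ 0.2% at the noise levels considered, so this
choice does not change what is detected, only makes the symmetries exact.

## 3. Compartment detection

A compartment is a maximal contiguous run of samples with

    n_i > 1 + θ          (RBP1-dominant), or
    n_i < 1 / (1 + θ)    (RBP2-dominant),

with θ = 0.20 and strict inequalities (a deviation of exactly 20% does not
trigger). The downward condition is multiplicative so that the swap symmetry
is exact. Runs shorter than `min_run_samples` (default 5 samples ≈ 0.15 µm)
are discarded as single-pixel noise. Each compartment extends half a step
beyond its first and last sample, so L = (run length) × step; its
enrichment is 100·(max of the dominant-over-other smoothed ratio within the
run − 1), and the argmax position is recorded for attribution.

**Smoothing.** Before thresholding, n is smoothed with a *geometric* moving
average (uniform window in log space, edge-replicated; default window
5 samples = 0.15 µm). Log-domain smoothing preserves the n → 1/n swap
symmetry exactly, which an arithmetic moving average would break. The window
default comes from an error analysis of the max-statistic: at 3% per-channel
multiplicative noise the ratio CV is ≈ 4.2%, and the maximum over a ~100-
sample run of raw ratios is biased upward by ≈ 2.5 standard deviations —
more than 10 percentage points of spurious enrichment, which would dominate
the estimate for weakly enriched compartments. A 5-sample geometric window
reduces the max bias to ~2 points while blurring boundaries by at most
±2 samples (60 nm), well below the PSF scale. Set `smoothing_window=1` for
raw-sample detection.

**Detected vs planted values.** Because the mean ratio includes the
compartments themselves, a planted fold f is measured as slightly less than
(f − 1)·100%: the bias factor is the compartment's share of the pooled
network length (e.g. ~2% for 30 µm of compartments on 1 mm of network).
Against flanking-baseline normalization this bias would vanish; mean-ratio
normalization is the default because it needs no baseline segmentation and
matches pooled-vector processing of whole-network recordings.

## 4. Attribution: enrichment vs exclusion

A ratio increase can mean the dominant protein accumulated or the coexisting
protein left. At the argmax position the signed log deviations of both
channels from their pooled means are summed:

    D = log[I_dom/mean(I_dom)] + log[I_other/mean(I_other)]

D > 0 → `enrichment_of_dominant`; D ≤ 0 → `exclusion_of_other`. The naive
*difference* of log deviations is not usable here: it equals the log of the
mean-normalized ratio, which is positive at the argmax of every detected
compartment by construction, and the discriminating quantity is the sum.
D is symmetric in the two channels, so channel swap preserves attributions.

Limitation: D inherits common-mode intensity variation (local filament
brightness, bundling, crossings) because both deviations are measured
against global means. For strongly enriched or depleted compartments the
planted signal dominates and attribution is reliable (it is exact on
noiseless single-mechanism plants); for weak compartments (folds ≲ 1.5) on
images with strong brightness structure the attribution becomes noisy. This
is a property of the statistic, not of the implementation.

## 5. Colocalization score

Both channels are high-pass filtered in the Fourier domain before
correlating: H(f) = 1 − exp(−f²/2σ_f²) with σ_f set so that H = 1/2 at the
cutoff frequency 1/(2 µm). The Gaussian-edged rolloff avoids the spatial
ringing of a brick-wall filter; the DC term is removed exactly, so
cell-scale gradients and diffuse background do not contribute. The measured
response is ≥ 99.99% at a 0.5 µm period and ≤ 5% at 8 µm. Filtered values
may be negative and are kept (only correlations are computed). Spearman ρ
(average ranks for ties) and Pearson r are computed over all ROI pixels;
a channel that is constant after filtering yields NaN, not 0. The expression
covariate is the mean unfiltered first-channel intensity over the ROI.
An optional on-structure mask can restrict the correlation to traced
filament pixels; the default uses all ROI pixels.

## 6. Synthetic scenes

The simulator emulates: a 2D filament network (straight chords or bounded-
curvature random walks, 0.15 µm steps, ≤ 0.3 rad/step) rendered as 1-px
lines (microtubules are sub-resolution at this pixel size), planted
multiplicative fold changes on arc intervals, Gaussian PSF blur (default
σ = 80 nm ≈ 0.21 λ/NA for 525 nm emission at NA 1.4), constant background
with optional linear gradient, and Poisson shot noise followed by Gaussian
read noise (sd 2) — a standard CCD model; acquisition noise and bit depth
are conventions here, not measured properties. Default signal levels
(2000 photons per on-filament pixel before blur, 30 nm pixels) put the
post-blur on-profile noise near the few-percent level used throughout the
validation suite. A 1D generator bypasses imaging entirely (exact boxcar
folds, i.i.d. lognormal multiplicative noise with unit mean) for isolating
the detection stage.

Not emulated: time-lapse dynamics (droplet fusion, transport), 3D stacks,
stress-granule morphology, filament bundling, depth-dependent blur and
spatially varying background beyond a linear gradient. Passing tests
therefore demonstrate correctness of the *measurement chain* under
controlled conditions, not robustness to every real-microscopy artifact.

Colocalization scenes place a fraction `co_fraction` of the second channel's
filaments on the first channel's paths and the rest on an independent
network, recording the fraction as ground truth; the resolution of the
fraction is 1/n_paths.

## 7. Validation conditions and problem sizes

The standard experiments (in `mtllps.benchmarks`, reported by
`scripts/acceptance.py`) use: a 1 mm same-protein network at 3% per-channel
noise (≈ 33,000 samples); a 4 × 4 fold {1.3, 1.5, 2, 3} × length
{0.5, 1, 2, 4} µm recovery grid, one planted compartment per 60 µm profile;
1,000 random 300-sample profiles for the brute-force-scan equivalence; 200
random profiles for the swap/scale exactness checks; 512² px colocalization
scenes and a 320² px independence null (> 10⁵ pixels); and the four packaged
scenario presets (8 × 12 µm networks). These sizes give Monte-Carlo errors
comfortably below every asserted tolerance while keeping the whole suite in
the seconds range.

## 8. Tracing

Automatic tracing (a convenience; user-supplied polylines are first-class)
runs a Sato tubeness filter at the expected filament scale (σ = 2 px),
Otsu-thresholds the ridge response, skeletonizes, removes junction pixels so
branches are analyzed independently (how crossings should be merged is
genuinely ambiguous; independent branches is the conservative choice), and
vectorizes each remaining chain. Branches shorter than 1 µm are dropped.
On noiseless non-crossing networks the traced length recovers ≥ 95% of the
planted length, with sub-pixel RMS deviation from the true centerline; tips
erode by a few pixels (PSF + skeletonization), which is the main recall
loss.

## 9. Quality control and reporting

A cell enters group statistics only if its analyzed network length exceeds
0.5 mm (stored as a QC flag, not a hard error — short cells are analyzed but
flagged, and the pipeline emits an explicit warning). Group contrasts use a
two-tailed two-sample t-test on per-cell mean enrichment, reported with t,
df and p; degenerate-variance groups are reported as such rather than
raising. Every artifact written by the pipeline carries the tool version and
a hash of the full configuration.
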