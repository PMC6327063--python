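# Methods

This note documents the models, parameter choices and numerical decisions
behind each pipeline, what the synthetic generators do and do not emulate,
and the known limitations.

## Speckle flowmetry

The temporal speckle contrast k = σ/μ is computed per pixel across frames
(the red-laser stack is a time series per pixel); spatial-window and hybrid
estimators are deliberately out of scope.  σ is the population standard
deviation (÷N): contrast is a property of the intensity ensemble, which also
makes the two-point example {1, 3} → k = 0.5 exact.

The integration law k²(τ, T) = (τ/2T){2 − (τ/T)[1 − e^(−2T/τ)]} assumes an
exponentially decorrelating, fully developed speckle field (unit β).  It is
evaluated with `expm1` so both asymptotes are accurate to machine precision,
and inverted by bisection on log(τ/T) over [10⁻⁴, 10⁴]; contrasts outside
that bracket are clamped to the bracket edge and flagged invalid rather than
dropped, so order statistics over a map stay meaningful.  Invalid pixels
(μ ≤ 0, k = 0, k ≥ 1) propagate as a boolean validity mask, never as NaN
poisoning.

**Finite-sample bias.** The ratio estimator σ̂²/μ̂² is biased low by
O(1/N_eff) when frames are correlated (τ comparable to or larger than the
frame interval): at τ/T = 5 with 1000 frames the median recovered τ is ~15%
low.  `speckle_contrast(..., bias_correction="jackknife")` applies a
delete-a-block jackknife (10 contiguous blocks, preserving the correlation
structure) to k² per pixel, which removes most of that bias (residual error
≲ 9% across τ/T ∈ [0.2, 5] at 1000 frames).  The plain estimator remains
the default because it is the field-standard definition; the jackknife is
recommended whenever τ itself is the quantity of interest.

Time-resolved flow for the response pipeline uses a sliding window
(default 15 frames ≈ 1 s at 15 fps) of temporal contrast feeding 1/k²,
timestamped at window centres.  The window trades temporal resolution
against estimator variance and is exposed as a parameter.

## Fractional responses

IOS frames are inverted to a proportional absorption index using the
per-frame maximum as white reference.  The reference choice cancels in
r(t) = (x − x̄_B)/x̄_B, which is the only quantity carried downstream; the
index itself has no absolute units.  Illumination correction divides by a
large-mean-filter estimate of the illumination field (normalised to unit
mean so intensities keep their scale); division was chosen over subtraction
because vignetting and LED inhomogeneity are multiplicative.  The kernel
should be a fraction (~1/6) of the field of view — at the instrument's
640 px FoV that is the 100 px (stimulus runs) or 200 px (anesthesia runs)
mean filter; scaled-down test fields scale the kernel accordingly.

Epoch averaging interpolates each epoch separately onto a 10 ms grid (time
zero at epoch start, stimulus at 3 s) and averages across trials; this keeps
memory bounded for long runs and makes manual trial exclusion a simple index
set (no automatic artifact rejection is attempted).  The averaged response
then receives a centred 1 s moving average — which restricts the useful
range to [1 s, epoch end] — and a 3×3 median; the laser-derived contrasts
(CBF, dHb) additionally get a 20×20 mean because of their lower SNR.

The 1 s moving average attenuates a response whose width is comparable to
the window: for the synthetic gamma-variate hemodynamic kernel the peak
reads ~12% low, and a sharp calcium transient's apparent peak shifts late by
a few hundred ms.  Tests therefore score the pipeline against the
box-convolved kernel (the exact expectation), not against the unsmoothed
amplitude; users comparing absolute peak amplitudes across conditions are
unaffected because the attenuation is common.

dHb sign convention: functional hyperemia raises red reflectance, i.e.
lowers the dHb absorption index, so activation appears as a negative dHb
response.

## GLM activation mapping

The design matrix is [1, a(t), g(t)] per pixel, solved by one `lstsq` over
all pixels; residual orthogonality to the design is the validity check.
The hot-spot is the largest 8-connected component above the 0.95 quantile of
the calcium MIP (the threshold is a parameter; the notion of "peak activity
region" is inherently heuristic).  The background regressor defaults to the
whole valid field of view; a cortex mask can be supplied, and should exclude
non-hemodynamic reference regions when present.  Raw positive c₁ values are
mapped with no per-pixel significance testing or multiple-comparison
correction — the activation map is a coefficient map, not a statistical
parametric map.  dHb is refused by the CLI by default because of its low
SNR (an override flag exists).  Activation masks for Dice scoring binarize
a map at half its maximum; Dice compares against the generator's territory
masks.

## Vascular maps

Arrival-time mapping follows the fixed chain: 50 ms resample → per-frame
background subtraction (50 px) → zero-phase 2 Hz low-pass → one global
threshold → first crossing per pixel → 5×5 median → vessel mask.  The
threshold is 50% of the robust (99th-percentile) plateau intensity; the
fraction is exposed because "single intensity threshold" admits a family of
choices, and the fractional definition makes arrival ordering invariant to
positive affine intensity rescaling.  Pixels that never cross are invalid.
The background subtraction is a grayscale morphological opening with a flat
disk (sequence-decomposed footprints for speed): intensity-scale invariant,
properly specified by a single radius, and property-tested (constants → 0,
impulses retained, exact-disk agreement) rather than matched bit-for-bit to
any particular tool's rolling-ball variant.  Opening is border-affected
within one radius of the frame edge.

Microvascular connectivity: 1 s block means → band limit to 0.01–0.1 Hz →
global-signal regression on the FoV mean → seed Pearson correlation.  The
band limit is realised as a projection onto in-band DCT-II components
rather than an IIR filter: on a 300-sample block series a forward-backward
Butterworth with a 0.01 Hz corner drags edge transients across a third of
the record and leaks strong Nyquist-frequency content (e.g. block-aliased
~0.5 Hz physiology) into the band; the DCT projection implements the band
limit exactly on finite support and is zero-phase by construction.  A
conventional Butterworth path is retained as an option.  The global signal
is the mean over the whole valid FoV; stacks are assumed co-registered
(longitudinal registration is out of scope).

## RBC enhancement and velocimetry

Enhancement chain per frame: intensity inversion (aggregates become
bright) → background subtraction → 1st–99th percentile contrast stretch →
Gaussian-smoothed Hessian at scale σ_H (default 2 px, matched to aggregate
radius) → eigenvalues.  At a bright blob's centre both 2-D eigenvalues are
negative, so they are negated before the pixel-wise max combination —
otherwise the max would select the blob's edge ring; this is the 2-D
reading of a convention stated for 3-D eigenvalue ordering.  Otsu
thresholding of the combined response yields the mask; the percentile
stretch makes the chain invariant to positive affine rescaling.

Velocimetry is single-pass block matching: per block, the integer
displacement within ±search_px maximising zero-normalised cross-correlation,
refined by a parabolic fit of the peak (sub-pixel), averaged over frame
pairs.  Blocks are invalid when the correlation peak is below 0.3, when the
block lacks texture (SD below 1% of the frame SD — near-empty blocks
correlate spuriously), or when the full search window would leave the frame
(a clipped search cannot distinguish "no match" from "match outside").
No iterative or window-deforming refinement is attempted.

## EEG band power

Decimation by 40 low-passes at 0.8× the new Nyquist (8th-order zero-phase
Butterworth) before taking every 40th sample.  Band edges default to the
standard convention — delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30,
gamma 30–100 Hz — and are overridable; filters are zero-phase 4th-order
Butterworth band-passes, with a 60 Hz notch (Q = 30) ahead of the gamma
filter only.  Power is the variance per non-overlapping 60 s epoch,
median-filtered (3 samples) across epochs; the total is the sum of the five
bands and fractions are computed after smoothing, so they sum to one per
epoch exactly.  Zero-phase filtering has edge transients at the record
boundaries; first/last epochs of short records should be interpreted with
care.

## Synthetic data

The generators define the study conditions; their defaults are the
acquisition paradigm the pipelines target (10 s epochs, stimulus at 3 s,
60 epochs with two interleaved tones, ~15 fps with 5% timestamp jitter,
~1 s hyperemic delay, 0.01–0.1 Hz global fluctuation).  All randomness is
seeded and every generator returns a truth object sufficient to score its
downstream stage.

* **Speckle**: per-pixel independent complex Gaussian AR(1) field with step
  correlation e^(−Δt/τ), intensity integrated over 16 substeps per
  exposure.  Temporal decorrelation only — no spatial speckle grain, no
  static scatterer fraction (β = 1), no photon noise.
* **Sessions**: calcium transient = fast-rise (50 ms) exponential-decay
  (0.5 s); hemodynamic response = gamma-variate (shape 3) peaking 1 s after
  the delay (~2 s post-onset); response amplitudes 5% (Ca) / 2% (HbT)
  fractional, single-frame noise SD 2% of baseline (single-epoch peak
  SNR ≈ 1), global fluctuation 3× the response amplitude in the
  strong-global condition.  IOS channels are emitted as reflectance with
  50% baseline parenchymal absorption and a 3 px non-hemodynamic bright rim
  (bone/agarose) that anchors the per-frame white reference: the inverted
  absorption index of the interior then carries exactly the programmed
  fractional response plus the global term, and the rim is excluded from
  the cortex mask.  No optics (PSF), motion, or hemoglobin spectroscopy is
  modelled.
* **Bolus**: logistic wash-in per vessel pixel (scale = width/4, so
  "width" spans the 12–88% rise); the phantom's arrival midpoints increase
  along each vessel (the tracer front propagates down the vessel), jointly
  spanning 0.5–3 s, with SNR 10 at 200 ms width.
* **Connectivity**: each territory carries an independent unit-variance
  band-limited (0.01–0.1 Hz) source; all pixels share a global series;
  plus white noise.  300 s at 5 fps by default.
* **EEG**: per-band unit-variance band-limited noise scaled by per-minute
  amplitude envelopes, plus an optional 60 Hz line sinusoid.

Passing tests on these phantoms demonstrates correct implementation of the
stated models and recovery of programmed parameters under realistic noise;
they do not certify performance on real data with motion, optical blur,
spatially structured noise or non-exponential speckle statistics.

## Problem sizes

Tests and the acceptance script run on 64×64 (sessions, phantoms) to 48×48
(connectivity) fields with full-length epoch structure (60 × 10 s sessions,
1000-frame speckle stacks, 300 s connectivity runs, 2–3 min EEG records) —
the instrument's native 640×640 FoV is supported by the same code paths and
configurable in every generator.

## Known limitations

* No motion correction or longitudinal registration.
* No HbO/HbR spectroscopic unmixing — HbT and dHb are proportional indices.
* The speckle model assumes β = 1 and pure temporal decorrelation.
* Velocimetry is single-pass; large displacements need a larger search
  radius rather than pyramid refinement.
* Vessel segmentation is a global Otsu threshold, not a tubularity filter;
  it expects bright-vessel polarity input (a flag handles the inverse).
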