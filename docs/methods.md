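# Methods

## The detection model

`roakit` detects Ca²⁺ events in two-photon fluorescence movies pixel by
pixel.  The gray value of pixel *i* at frame *t*, F_i(t), is modeled as
approximately Gaussian with a linear mean–variance relation

    Var_i(t) = a·E_i(t) + b,

the signature of PMT-amplified photon counting (*a* is the effective gain,
*b* the signal-independent amplifier/read variance).  Raw high-frame-rate
data are strongly non-Gaussian — zero-inflated with a heavy right tail — but
spatiotemporal averaging brings them close to normality, and the square-root
transform X_i(t) = √Z_i(t) of the smoothed series Z_i(t) stabilizes the
variance: by the delta method Var(X) ≈ a/4 + b/(4E), essentially independent
of the signal level once E is moderately large.  All statistics below live
in these sqrt units.

Per pixel we estimate:

* **baseline** μ̂_i = Mode(X_i) — the signal sits at baseline most of the
  time, so the most frequent value is a transient-robust location estimate;
* **noise SD** σ̂_i from the median squared successive difference,
  σ̂_i² = Median([X_i(t+1) − X_i(t)]²)/c with c = 2·m₁ ≈ 0.909873 (m₁ the
  median of χ² with 1 df).  Differencing cancels slow drift; the median
  ignores the sparse large differences that transients produce.

A pixel is active at frame t when the detection-path value exceeds

    τ_i = μ̂_i + κ·σ̂,          κ = 4 by default,

with σ̂ = Median(σ̂_i) the global median noise SD (a per-pixel σ̂_i option
exists behind `DetectionConfig(per_pixel_sigma=True)`; the global median is
the default because per-pixel noise estimates are themselves noisy and a
common scale keeps the threshold interpretation uniform across the FOV).
Active x-y-t voxels are connected into events with a 26-neighborhood by
default (transients drift sub-pixel between frames; stricter connectivity
fragments them), filtered by minimum footprint (4 px) and duration
(2 frames), and summarized into an event table, density/frequency traces and
an events·min⁻¹·µm⁻² rate.

## SNR-targeted smoothing

Movie quality is summarized as SNR = Median(μ̂_i)/Median(σ̂_i).  Below an SNR
of about 9 the number of detected events correlates with image quality
rather than biology, so the pipeline smooths until SNR ≥ 9 (configurable):
the spatial Gaussian sigma is raised through {0, 0.5, 1, 1.5, 2} px first
(SNR is insensitive to finer steps); if sigma = 2 px is not enough, the
temporal window is searched over 1–30 frames by bisection for the minimal
sufficient window, assuming SNR is non-decreasing in the window length.  If
even (2 px, 30 frames) misses the target, that maximal configuration is
returned flagged `attained=False` — a valid result, not an error.  During
the search the SNR is evaluated on at most the trailing 1,000 merged frames
to bound cost on long recordings.

Two temporal operators are deliberate: parameter **estimation** uses
non-overlapping frame binning (successive binned samples stay independent,
which the successive-difference estimator requires), while **detection**
uses a centered moving average of the same width, which preserves the frame
count.  Both are n-frame means, so the noise SD estimated on the binned path
transfers to the detection path.  The spatial Gaussian is applied on both
paths with the same sigma; whether the detection path should also receive
the spatial filter is genuinely underdetermined, and applying the one
configuration consistently to both paths keeps τ_i and F* on the same scale.

## Numerical choices

* **Mode of a continuous series.** Histogram with per-pixel bin width
  max(0.2·σ̂_i, range/1024), edges anchored at integer multiples of the
  width.  The winning bin is found on [1,2,1]/4-smoothed counts with ties
  toward the lowest bin (the baseline is the low state), then refined to
  the center of mass of the contiguous plateau of bins holding ≥ 75% of the
  peak count.  Plain argmax is unstable here: adjacent 0.2σ bins of a
  Gaussian differ by only ~8% in expectation, so the argmax flips by ±2
  bins under resampling; the plateau center of mass is sub-bin accurate
  (error < 0.6 bins) and moves < 0.5 bins under 5% transient
  contamination.  Constant pixels return their constant.
* **Dead pixels.** σ̂_i = 0 (dead or saturated) pixels are excluded from the
  global medians and receive τ_i = +∞; their count is logged.
* **Chunking.** Binarization is chunked in time with an (n//2)-frame halo
  and window bounds computed in absolute frame coordinates, so chunked and
  whole-movie runs are bit-identical; estimation chunks align to bin
  boundaries for the same reason.  The moving-average window shrinks
  symmetrically at the movie ends.
* **Degenerate inputs.** Empty frame intervals, temporal windows longer
  than the movie, negative sqrt inputs and zero F₀ raise typed errors;
  an all-ignored FOV is rejected.
* **ROI ΔF/F₀.** F₀ is the 20th percentile of the ROI's raw trace —
  robust to sparse transients, configurable.
* **Transitions.** A state transition is timestamped at the first sample of
  the new state; windows are [t−pre, t+post) on a grid at the finest median
  sampling interval of the targets, with truncated windows flagged and
  missing values carried as NaN/None sentinels.

## The synthetic generator

`SynthParams` emulates ~30 Hz two-photon movies.  Noise is realized as
a·Poisson(E/a) + Normal(0, √b), clipped at zero and quantized to the
integer dtype: the mean is exactly E, the variance exactly a·E + b, and the
raw histogram reproduces the zero-inflated, right-skewed shape of dark PMT
data.  Events are discs (radius from a bounded power law, exponent 2,
2–6 px by default) with a trapezoidal time course (linear 2-frame rise and
decay around a plateau; durations from a bounded power law, 5–40 frames),
planted at a Poisson rate of 30 events/min with amplitude expressed in
multiples of the local baseline SD √(a·E + b) — by the delta method this
equals the amplitude in sqrt-domain noise SDs.  Default baseline E = 60,
a = 2, b = 5 give a raw sqrt-domain SNR of ≈ 10.7, i.e. a recording that
needs no smoothing; test scenarios lower the baseline or correlate the
noise to exercise the search branches.

Ground-truth voxel sets follow the FWHM convention: an event's scored
frames are those at ≥ half the plateau amplitude.  The sub-half-max ramp
tails (1/3 of amplitude) sit below any sensible threshold — for a 6σ event
they are 2σ excursions against a 4σ threshold — so counting them as truth
would score the profile shape rather than the detector.  Scoring
(`match_events`) is greedy one-to-one matching by descending voxel IoU with
a 0.3 floor, optionally restricted to the analyzed (non-ignored) region.

What the generator does **not** emulate: indicator kinetics (no
exponential decay tails), motion artifacts, neuropil contamination,
spatially varying gain, photobleaching, or overlapping/propagating events.
Passing tests therefore demonstrate the statistical calibration of the
detector under the stated noise law, not performance on real recordings
with those additional nuisances.

## Problem sizes

The test suite uses movies up to 64×64×900 px (event recovery),
32×32×10⁴ px (≈10⁷ voxels, false-positive calibration) and 256 pixels ×
10⁴ frames (estimator consistency); the reproduction script additionally
runs the smoothing search on a 256×256×3,000 noise movie.  These sizes keep
the statistical bounds meaningful (e.g. the 1−Φ(4) ≈ 3.2×10⁻⁵ tail needs
≥10⁷ voxels for a factor-3 check) while a full run of suite plus script
completes in a few minutes on one CPU.

## Known limitations

* The mode-based baseline assumes the pixel spends most of the recording at
  baseline; pixels active more than ~40% of the time bias μ̂_i upward.
* The MSSD estimator assumes noise that is white after smoothing; strong
  frame-to-frame correlation (e.g. from resonant-scanner artifacts)
  inflates or deflates σ̂_i depending on its sign.
* SNR monotonicity in the temporal window is assumed by the bisection; the
  search logs (and tolerates) local violations from sampling noise but can
  then return a near-minimal rather than minimal window.
* Events are reported as whole connected components; splitting, merging and
  propagation analysis are out of scope.
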