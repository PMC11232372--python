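# Methods

This note documents the models, conventions and numerical choices behind
`slicetox`, in the order the pipeline runs them, plus what the synthetic
generator does and does not emulate.

## The injury model

Slice preparation kills cells preferentially near the cut surface. The
package treats the depth distribution of each injured population (PI⁺
cells, GCaMP-filled neurons, colocalized puncta) as an exponential density
truncated to the imaged range:

p(z) ∝ exp(−z/τ), 0 ≤ z ≤ z_max (default 300 µm),

and the diffuse neuropil GCaMP intensity as an exponential of the same
form. The decay constant τ (µm) is the quantity of interest throughout:
small τ means injury confined to the surface; incubation-time effects and
pharmacological interventions appear as changes in τ and in total counts.

## Synthetic acquisitions

`slicetox.synthetic` renders what the analysis assumes, nothing more:

- **Somata** are isotropic 3-D Gaussian blobs, σ = radius/2, truncated at
  3σ. The Gaussian is smooth and analytically integrable, which makes
  in-mask intensity checks exact; it is not a PSF model.
- **Depths** are inverse-CDF draws from the truncated exponential (PI⁺ and
  GCaMP-filled each with their own τ; healthy somata uniform, since they
  are not part of the injury gradient). The file also ships a
  truncated-exponential maximum-likelihood estimator (score-equation
  bisection) used as an independent cross-check of the depth law.
- **Neuropil** is a spatially flat, depth-exponential green background.
  The red channel has no background of its own; it receives
  `bleedthrough × green` (default 0.5) before noise, and nothing leaks
  from red into green.
- **Noise** is additive Gaussian read noise (default SD 4 intensity units
  against soma peaks of 60–180). The detection stage thresholds on the
  background SD, not on photon statistics, so Poisson noise would add
  realism without touching any code path under test.
- **Placement** is rejection sampling with a global planar minimum center
  separation (max(3·radius + 2 µm, 12 µm)) across *all* classes and a 3σ
  border margin. This deliberately over-separates cells: touching somata
  would exercise watershed-style splitting, which the detection stage (by
  design, below) does not do, and cross-class neighbors inside the match
  radius would create spurious colocalization pairs. Separability is what
  lets tests assert exact counts.
- **Colocalized cells** are the first ⌊frac_coloc·n_filled⌋ filled cells,
  rendered in both channels at the same position; their depths follow the
  filled-population τ.
- **Movies** place non-overlapping circular ROIs; non-filled ROIs share
  synchronous events at Poisson times, each a Gaussian bump (width
  `event_sigma` s, amplitude `event_amp_dff`) on a constant baseline;
  filled ROIs sit at a constant high fluorescence with no events.

Not emulated: optical PSF, scattering, depth-dependent laser-power
compensation (a flat `depth_attenuation` knob exists to stress-test
detection, off by default since acquisition-side power ramping compensates
it in practice), photobleaching, motion, overlapping somata, asynchronous
or cell-specific transients. Passing tests therefore demonstrate the
correctness of the measurement machinery on data obeying the stated model,
not robustness to these real-data effects.

### Condition presets

`fig1` is the baseline acute-slice condition (τ_PI = 41 µm,
τ_filled = 65 µm, τ_neuropil = 131 µm, 50 % bleed-through).
`fig3-late` emulates prolonged (3–5 h) incubation: larger τ and more
cells. `fig6-mdl` emulates calpain inhibition during incubation: fewer
PI⁺ cells and steeper decay. These encode parameter regimes, not drug
chemistry. The preset soma radius is 3.5 µm (≈ 7 µm diameter, small
neonatal somata): with the Gaussian blob model this places detected
particle footprints (~50–90 µm² depending on threshold) inside both
published size windows. Movie presets `superficial` and `deep` differ in
event rate and amplitude (2 vs 5 events/min, 0.6 vs 1.2 ΔF/F₀) with equal
event width, encoding the depth ordering of seizure-associated transients.

## Preprocessing

- **8-bit conversion** maps [min, max] linearly to 0–255 with half-up
  rounding; a constant stack maps to zero. For dual-channel data the
  default is a *joint* scale (shared min/max across channels): per-channel
  scaling would make the red/green intensity ratio depend on each
  channel's own dynamic range and corrupt the ratiometric filter. A
  per-channel option exists for single-channel work.
- **Background estimation** is median / 1.4826·MAD over the whole image —
  robust on sparse-signal images, and it recovers the true noise SD
  (within ~10 % on pure-noise frames), which the 5×SD threshold needs. A
  user-designated signal-free rectangle is available as an alternative.
  Subtraction clips at zero.
- **Order**: planes are median-smoothed (disk radius 2, reflected edges),
  grouped into MIPs of five planes (final partial group kept, so depth
  coverage is conserved), then each MIP is background-subtracted; the
  per-MIP background SD feeds thresholding. A MIP's depth stamp for
  binning is its span midpoint.

## Detection

Mask = background-subtracted MIP strictly greater than k·SD (k = 5).
Components are 8-connected; area is pixel count × pixel_size²; perimeter
uses the Crofton approximation and circularity 4πA/P² is clipped at 1
(discretization can push small particles above 1). Size and circularity
bounds are inclusive; the size filters are areas in µm² (a 10-µm-diameter
soma, ~78 µm², sits inside both windows). There is no watershed splitting
of touching cells — the generator guarantees separation instead.

A soma whose z-extent straddles a MIP-group boundary appears in two
adjacent MIPs; a deduplication pass (same channel, ≤ 10 µm in-plane,
adjacent MIP) keeps the brightest instance, so one cell yields one
detection with its best-focus depth.

Channel intensity means (mean_green, mean_red) are measured within the
particle mask on the preprocessed (subtracted, smoothed) MIPs of both
channels.

## Ratiometric bleed-through elimination

The ratio is the normalized excess r = (R − G)/G on background-subtracted
in-mask means: negative iff green exceeds red, which is exactly the
bleed-through signature (a plain quotient R/G could never reach the
negative threshold −0.4). With G at the noise floor (≤ 10⁻⁶) and R above
it, r = +∞ (unambiguously red, kept, excluded from fitting); dead in both
channels is flagged undefined. An (R − G)/(R + G) convention is available.

The threshold is mean − 1 SD of a Gaussian fitted (Freedman–Diaconis
histogram, least squares, sample-moments fallback with a warning) to the
ratios of a curated true-positive set; the default pipeline threshold is
the fixed value −0.4 rather than a per-run refit, because a clean dataset
rarely yields the ≥ 20 finite ratios the fit requires (true PI⁺ cells have
r = +∞ there). Elimination uses strict `<`, so a detection at exactly the
boundary survives.

## Colocalization

Pairs must lie within 10 µm in-plane and at most 1 MIP apart (a punctum
split across a section boundary must still match); both knobs are config.
Matching extracts mutually nearest admissible pairs iteratively in
ascending (distance, red_id, green_id) order — equivalent to global greedy
selection, deterministic under ties, one-to-one. A brute-force
enumeration oracle (refusing instances above 10⁴ candidate pairs) proves
equivalence on random instances in the test suite.

## Depth profiles and exponential fits

Bins are half-open [lo, hi), default 0–300 µm in 30-µm steps;
out-of-range detections are dropped with a logged count. Count profiles
normalize to the slice total, intensity profiles to the slice maximum.
The fit is nonlinear least squares of y = A·exp(−z/τ) at bin midpoints
(A₀ = first bin value, τ₀ = 50 µm, τ bounded to (1, 10⁴) µm); no additive
offset term, matching the single-exponential convention. `converged` is
false when the optimizer fails or τ pins at a bound (e.g. a flat profile).
For equal-width bins the binned masses of an exponential are themselves
geometric, so the midpoint-abscissa fit recovers τ without binning bias.

Cumulative summaries (fraction of cells above a depth; depth containing a
given fraction) interpolate linearly inside bins and are exact inverses of
each other. They are computed from the empirical cumulative, not from the
fit — for a τ = 41 µm exponential the two disagree slightly, and the
empirical version makes no model assumption.

Median neuropil intensity per depth step pools all non-soma pixels of the
planes (or MIPs) in each 30-µm bin; pooling planes keeps the median free
of the upward bias a max-projection would inject into a noisy background.

## Ca²⁺ transients

- Neuropil subtraction: soma disc mean minus concentric annulus mean per
  frame; the annulus (gap 1.2 µm, outer radius 2× soma radius) excludes
  every soma in the field; ROIs with an empty annulus are dropped with a
  warning.
- F₀ is the mean over the frames whose trace value lies in the lowest
  quartile (an explicit time window is available); ΔF/F₀ is undefined
  (flagged) when F₀ ≤ 0.
- Events are `scipy.signal.find_peaks` maxima above
  baseline + max(k·1.4826·MAD, min_amp), k = 3, with ≥ 2 s separation.
  The absolute floor min_amp = 0.05 ΔF/F₀ exists because on a quiescent
  low-noise trace the MAD threshold collapses toward zero and shot-noise
  ripple would be called activity; physiological transients are an order
  of magnitude above it. Amplitude is peak − baseline; AUC integrates
  (ΔF/F₀ − baseline) trapezoidally between the baseline crossings
  flanking the peak; FWHM interpolates the half-amplitude crossings
  linearly, so a noiseless Gaussian event of width σ measures
  2.3548σ within one frame interval.
- GCaMP-filled classification: an ROI is filled iff it fired zero events
  AND its median raw fluorescence exceeds the 90th percentile of the
  median fluorescence of the ROIs that did fire. Using the active ROIs as
  the brightness reference (rather than all ROIs) keeps the threshold
  below the filled cluster regardless of how many ROIs are filled; a
  bright but active ROI is never flagged.
- Grid statistics: 4×4 equal tiles with half-open bounds (a centroid on a
  shared corner counts once); per tile the non-soma median intensity and
  PI⁺ centroid count; zero-PI tiles are flagged excluded before
  correlation; Spearman (average ranks) and Pearson coefficients come
  from scipy with t-approximation p values.

## Problem sizes and determinism

Every stochastic stage takes a seed (or a numpy Generator); identical
config + seed reproduces stacks, movies, truth tables and reports
bit-identically. The reproduction script uses 10⁴ depth samples for the
cell-count decay constants, 5×10³ for colocalized puncta, 284 draws for
the ratio-distribution recovery (the size of the curated set it mirrors),
and a 256×256 px field for the neuropil-intensity decay — the
median-vs-depth statistic does not depend on field area, only on plane
count.

## Known limitations

- Detection is per-MIP (2-D); no volumetric segmentation, no splitting of
  touching cells.
- The single-coefficient bleed-through model cannot represent a full
  spectral unmixing matrix.
- τ fits carry no bootstrap confidence intervals; cross-slice inference
  (mixed models, ANOVAs) is out of scope.
- The filled-ROI classifier needs at least five ROIs and at least one
  active ROI to anchor its brightness reference; in an all-silent field
  it falls back to the whole-field percentile and flags nothing when all
  ROIs are alike.
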