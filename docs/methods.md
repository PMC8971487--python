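# Methods

## Signal model and preprocessing

A recording is a stack `F(t, y, x)` of fluorescence intensities at frame
rate `f_s` (Hz) and pixel size `p` (µm).  For ANEPPS-family voltage dyes
at long emission wavelengths, depolarisation *reduces* fluorescence;
`apply_polarity` therefore replaces each pixel trace by its own maximum
minus the trace, so that depolarisation is a positive deflection.  The
per-pixel (rather than global) reference means resting-brightness
gradients across the tissue do not distort relative amplitudes.  Movies
labelled `upright` (calcium indicators, pre-corrected data) pass through
unchanged, and the operation is idempotent once upright.

**Spatial filtering.**  Every frame is convolved with a sampled Gaussian
kernel (default 3×3, σ = 1.5 px) normalised to sum 1.  At image borders
and mask edges, weights over unavailable pixels are dropped and the
remainder renormalised ("renormalised truncation").  This was chosen over
zero-padding or reflection because masked-out pixels (bath, lumen) carry
no signal and must not bleed into tissue pixels; it also preserves
spatially constant frames exactly.  Out-of-mask pixels are returned
untouched.

**Baseline correction.**  Slow drift (photobleaching, perfusion
artefacts) is removed by subtracting the grey-scale morphological opening
of each pixel trace — a moving minimum followed by a moving maximum with
a flat structuring element.  The element spans
`round(kernel_ms · f_s/1000)` samples, forced odd (rounding upward) so
the opening is centred; defaults are 200 ms for guinea-pig and 100 ms for
mouse recordings.  The opening removes only features *narrower* than the
element, so the kernel must exceed the action-potential footprint
(upstroke + full repolarisation): that is exactly why the species
defaults differ — guinea-pig APDs (~110 ms) need the longer kernel.
Analyses that sweep APD80 up to 110 ms on 1 kHz profiles scale the kernel
to `max(default, beat duration + 50 ms)`.  A flat trace corrects to
identically zero, and the correction is invariant to adding a constant.

**Tissue segmentation.**  `amplitude_fraction` (default) includes a pixel
when its max−min amplitude reaches 0.3× the 95th percentile of all pixel
amplitudes.  Amplitudes are measured after a short (≤ 9-sample) temporal
boxcar: without smoothing, the max−min range of pure noise at SNR 10
crosses the threshold; smoothing along *time* rather than space was
chosen because spatial smoothing bleeds signal across the tissue
boundary and creates a false-positive ring one kernel wide.  The
measurement pipeline itself applies no temporal filtering anywhere.  An
Otsu threshold on the time-averaged image is available for
brightness-based segmentation.  Only the largest 4-connected component is
kept; holes are not filled (an atrial preparation's lumen must stay
excluded).  The 0.3 default fraction recovers ≥ 99 % of truly active
pixels with ≤ 1 % false inclusions at SNR ≥ 10 on simulator fixtures.

## Beat detection, PCL grouping, ensemble averaging

Beats are detected on the global signal (frame-wise mean over in-mask
pixels) as local maxima with topographic prominence ≥ 0.4× the signal
amplitude, separated by ≥ 40 ms; spacing conflicts resolve in favour of
the more prominent peak.

Cycle lengths are scanned in order; a new pacing-cycle-length (PCL) group
starts whenever an interval deviates from the running median of the
current group by > 5 ms — half the 10 ms step of the ramp protocols, so
adjacent stages never merge, while single ectopic intervals isolate into
their own groups.  A group's nominal PCL is the median member interval
rounded to 1 ms.  When the global signal is supplied, cycle lengths are
measured between interpolated 50 %-upstroke crossings rather than raw
peak frames: the peak of a broad optical plateau (slow waves summed over
the field) wanders ±1–2 frames under noise, whereas the upstroke
midpoint — the package's timing reference throughout — is steep and
stable.  This is what makes PCL recovery exact at the deposit's
frame rates.

Ensemble averaging aligns the last 10 beats of a group on the global
signal's upstroke midpoint (interpolated, snapped to the nearest frame)
and averages frame-wise.  The midpoint was preferred to the peak as the
alignment point because it is sub-sample interpolable and robust to
plateau noise.  Default windows span 20 % of the PCL before to 90 % after
the alignment point, clamped to the recording; a group's final beat is
excluded when its window would overlap the next group's first beat.
Residual noise falls as 1/√n of the averaged beats.

## Morphology

All measures operate on upstroke-positive single-beat windows.

- **Baseline** is the 5th percentile of the samples before the
  maximum-upstroke-velocity instant.  A pre-upstroke estimate is needed
  because windows may clip the previous beat's repolarisation tail.  A
  percentile rather than the strict minimum matters under noise: the
  minimum of an N-sample noisy segment biases low like σ√(2 ln N), which
  inflates amplitudes and delays the APD crossing by up to ~3 ms at
  SNR 10 for long, shallow repolarisations; the percentile is a
  consistent floor estimate independent of window length and identical
  on clean traces.
- **Activation time**: `midpoint` returns the first upward crossing of
  50 % of (peak − baseline) before the peak, linearly interpolated;
  `max_dvdt` returns the maximum first difference before the peak,
  earliest frame on ties (ties are compared with a relative tolerance so
  numerically equal plateau slopes resolve deterministically), not
  interpolated — finite differences live on the frame grid.  The
  midpoint is the default because max-ΔF/Δt is sampling-rate limited and
  collapses fast-activating tissue into apparent simultaneity.
- **APD at level L** runs from the max-upstroke-velocity instant to the
  first downward crossing of `baseline + (1 − L/100)·amplitude` after
  the peak, crossing interpolated.  Activation maps are re-zeroed to the
  earliest defined pixel.
- **Heterogeneity** is `(P95 − P5)/P50` over defined pixels (linear
  interpolation between order statistics) — dimensionless and
  scale-invariant.
- **ΔAPD80** measures APD on every single beat of a group and reports
  the mean over consecutive pairs of `|APD_i − APD_{i−1}|` (a
  last-pair-only option exists).  Pixels where any single-beat APD is
  unmeasurable are undefined rather than silently averaged.  The
  single-beat noise floor is (sample noise)/(repolarisation slope) plus
  ~0.5 frames of max-ΔF/Δt jitter: ≈ 1–1.3 ms at SNR 20 after spatial
  filtering, halving by SNR 40.  Programmed alternation of 10 ms is
  recovered within 2 frames at SNR ≥ 10.

## Conduction velocity

For each defined pixel, activation times in a centred window (default
5×5) are least-squares fitted with `T(x,y) = a + bx + cy` (default) or
the full second-order polynomial; the gradient at the centre is `(b, c)`
ms/pixel.  A plane is the default for 5×5 windows — 25 points against 3
parameters is well-conditioned — while the quadratic option suits larger
windows or curved fronts.  Pixels with fewer than 12 defined neighbours
or rank-deficient (collinear) fits are undefined.  Velocity is
`v = g/|g|²` scaled to cm/s (`speed = 0.1·p/|g|` for `p` in µm and `|g|`
in ms/pixel); it points from early to late activation, in image
coordinates (x = columns, y = rows increasing downward).  Speeds outside
1–200 cm/s are excluded as artefactual — near-zero gradients from
simultaneous activation (epicardial breakthrough) would otherwise yield
unbounded speeds; the caps are configurable and logged.  Reported CV is
the arithmetic mean speed over an ROI; restricting the ROI to near the
pacing site avoids the far-field apparent-speed inflation that
transmural breakthrough produces.

## Rhythm analyses

**Dominant frequency**: the mean-subtracted trace is multiplied by a Hann
window of its own length, zero-padded to `ceil(f_s/0.05 Hz)` samples, and
the magnitude-squared spectrum computed; DF is the argmax of power within
0.5–50 Hz, exact ties resolving to the lowest frequency and an all-zero
spectrum reporting NaN.  The padded grid spacing is ≤ 0.05 Hz at every
supported frame rate.

**Optical wave similarity**: single-beat windows (upstroke−20 ms to
+90 % of the PCL, truncated to equal length) are amplitude-normalised to
[0, 1]; with cosine similarity `s(i,j)`, OWS is the weighted sum over
beats of each beat's mean similarity to all others, clipped to [0, 1].
Weights default to uniform — the weighting scheme of the index's
original formulation is not fully specified by the available
description, so the weight vector is an injectable parameter and the
uniform default is recorded in every run log.  Flat beats are dropped;
fewer than two usable beats yields NaN.

## Synthetic data

The generator is kinematic: no reaction–diffusion model, no spiral
waves.  An optical-AP template — raised-cosine upstroke over `U` ms
(unique max-slope instant at `U/2`, which is also the 50 % midpoint) and
a linear repolarisation whose slope places the 0.2-amplitude crossing
exactly `APD80` after the max-slope instant — propagates as a planar or
radial front at constant speed.  Linear (not exponential) repolarisation
keeps the APD80 ground truth closed-form; an exponential tail exists for
realism without the exactness guarantee.  Stimuli follow an explicit
`(PCL, n_beats)` schedule; the generator refuses schedules where
activation spread plus beat duration exceeds the PCL (beats would
overlap within a pixel).  Alternans adds ±Δ/2 to APD80 on even/odd
beats.  Noise is i.i.d. Gaussian per sample (amplitudes are arbitrary
units, so SNR = 1/noise_sd is the controlled quantity; Poisson shot
noise is not modelled), drift is a global sinusoid, polarity is applied
last, and everything is bit-reproducible from the seed.  Ground truth
(activation map, per-beat APD80, speed field, DF) is computed from the
parameters alone — noise never touches it.

Epicardial breakthrough is modelled phenomenologically as apparent-delay
compression growing with distance from the pacing site
(`delay → (L/b)·ln(1 + b·delay/L)`), inflating far-field apparent speed
by `1 + b·d/L` — enough to reproduce the whole-surface-vs-local ROI
discrepancy, but not a transmural propagation model.

The irregular-movie generator gives each spatial domain an independent
beat train at its own frequency, with multiplicative jitter applied to
inter-beat intervals, per-beat amplitudes and per-beat APDs — a stand-in
for fibrillatory irregularity sufficient to exercise DF mapping and OWS
degradation, not a model of VF dynamics.

**What passing tests show.**  Synthetic fixtures have ideal optics: no
motion, no photon shot noise, no spatial heterogeneity of AP shape, no
fibre-direction anisotropy, and wavefronts of exactly known geometry.
Recovery results therefore demonstrate correctness of the measurement
chain, not performance bounds on experimental data, where signal quality
and manual ROI choices dominate.

## Validation grid and problem sizes

The standard recovery grid crosses the three acquisition profiles
(51×51 @ 1 kHz/156 µm, 45×45 @ 0.987 kHz/71.4 µm, 64×64 @ 0.5 kHz/320 µm)
with speeds {20, 50, 100} cm/s, APD80 {40, 80, 110} ms and SNR
{∞, 20, 10} — 81 trials of 12 beats each, sized to run in a few minutes
on one CPU.  Per trial the PCL is the smallest frame-aligned value
accommodating activation spread + beat duration + 40 ms (slow waves on
the large guinea-pig field need up to ~450 ms), which also makes the
"exact PCL recovery" check well-defined at the non-integer 0.987 kHz
rate.  Acceptance thresholds: exact PCL, APD80 map error ≤ 2 frames,
ROI-mean CV error ≤ 2 %, direction error ≤ 3°, DF within one 0.05 Hz
bin, programmed ΔAPD80 within 2 frames.

## Known limitations

- No motion correction; recordings are assumed mechanically uncoupled.
- No calcium-specific measures: calcium movies are handled as generic
  upright-polarity movies.
- No phase mapping, rotor tracking, or restitution-curve fitting.
- The deposited containers' internal variable names and dimension order
  are not standardised; the loader picks the largest 3-D numeric
  variable and assumes (row, col, frame) order, with explicit overrides
  for both.
- Heterogeneity is undefined (raises) for maps with a zero median or
  fewer than 20 defined pixels.
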