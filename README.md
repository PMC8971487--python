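# cardiomap

Analysis of cardiac optical-mapping fluorescence movies from isolated
whole hearts and atria, for electrophysiology labs working with
voltage-sensitive-dye recordings (mouse and guinea-pig preparations at
0.5–1 kHz, tens of micrometres per pixel).

Optical mapping images the transmembrane potential of a beating heart as a
movie: each pixel carries an optical action potential (OAP).  From a 3-D
stack `F(t, y, x)` the package measures, per pixel and per pacing cycle
length (PCL):

- **Activation time** — the depolarisation midpoint (interpolated 50%
  upstroke crossing) or the instant of maximum upstroke velocity
  (max ΔF/Δt).
- **APD80** — action potential duration from maximum upstroke velocity to
  80 % repolarisation, the interval to the downward crossing of
  `baseline + 0.2 · amplitude`.
- **Conduction velocity (CV)** — the multi-vector method: a local
  polynomial surface `T(x, y)` is least-squares fitted to activation times
  in a 5×5 window and the velocity is `v = ∇T/|∇T|²` (pixel/ms), scaled by
  the pixel size to cm/s.
- **Heterogeneity** — `(P95 − P5)/P50` of a map's defined pixels.
- **Alternans (ΔAPD80)** — mean absolute APD80 difference between
  consecutive single (non-averaged) beats.
- **Optical wave similarity (OWS)** — mean pairwise cosine similarity of
  amplitude-normalised single-beat OAPs, 1 for perfectly repeating
  signals, → 0 in fibrillation.
- **Dominant frequency (DF)** — frequency of peak Hann-windowed spectral
  power in 0.5–50 Hz, zero-padded to a 0.05 Hz grid.

Upstream of the measurements: polarity correction (voltage dyes darken on
depolarisation), 3×3 Gaussian spatial filtering (σ = 1.5) with
renormalised truncation at tissue borders, morphological top-hat baseline
correction along time (200 ms kernel for guinea-pig recordings, 100 ms for
mouse), amplitude-based tissue segmentation, automated beat detection and
PCL-group identification, and ensemble averaging of the last 10 beats per
PCL.

A kinematic simulator (`cardiomap.simulate`) renders movies with exact
ground truth — programmed PCL schedule, APD80, conduction speed and
direction, alternans magnitude, noise, drift, dye polarity, and an
epicardial-breakthrough distortion term — so every stage of the pipeline
is testable without the multi-gigabyte experimental recordings.

## Worked example

`examples/01_simulate_and_measure_apd.py` simulates a mouse-whole-heart
style recording (51×51 pixels, 1 kHz, 156 µm/pixel, 12 beats at 110 ms
PCL, APD80 = 45 ms, planar wave at 50 cm/s, SNR 20) and measures it back:

```
movie: 1338 frames of (51, 51), 1000 Hz, 156 um/pixel
detected 12 beats; nominal PCL 110 ms (programmed 110)
ensemble of 10 beats -> APD80 map: mean 45.92 ms, sd 0.40 ms (programmed 45)
```

The PCL comes back exactly; the APD80 map mean is within one frame (1 ms)
of the programmed value — the small positive offset is the discrete
max-upstroke-velocity start point — and the 0.4 ms spatial sd is the
residual noise after ensemble averaging and spatial filtering.  The other
examples cover conduction velocity and direction recovery
(`02`, errors 0.00 % / 0.00° on a clean 30° planar wave), alternans and
OWS (`03`: programmed 10 ms alternation → measured 10.00 ms), DF mapping
of paced versus two-domain irregular movies (`04`: 8.00 / 14.00 Hz), and
the batch pipeline over a MAT ramp recording (`05`).

Deposited recordings are analysed the same way from the shell:

```sh
cardiomap analyze experiment_folder/ --profile guinea_pig --out results/
cardiomap simulate --spec spec.txt --out synthetic/
```

`--profile` selects the acquisition metadata (frame rate, pixel size,
top-hat default) for the three dataset types; per-dataset settings files
of `key = value` lines are applied with `--config`.

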