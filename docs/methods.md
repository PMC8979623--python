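# Methods

## Scope and model

`pvzkit` computes composite pulmonary vascular impedance (PVZ) from
asynchronous screen captures of PA pressure and pulsed-wave Doppler
velocity, each carrying its own ECG strip. "Composite" means the
pressure and flow sides of the ratio come from different acquisitions:
the two beats are reconciled by ECG gating and paired strictly by
harmonic index, not by absolute frequency. This is the central modelling
commitment of the method — harmonic k of a 62 bpm pressure beat is
divided by harmonic k of a 65 bpm flow beat — and it is what makes the
heart-rate comparison between captures a first-class output (a warning
above the configured mismatch tolerance, 10% by default; never a hard
failure, since asynchrony is inherent to the acquisition).

Flow is obtained from the Doppler envelope as Q(t) = V(t) · CSA with a
circular cross-section CSA = πd²/4 from the echo diameter at the
pulmonic valve. This assumes a flat velocity profile and a constant
diameter over the cycle; no Womersley correction is attempted.

## Digitization

- **Traces** (pressure, ECG): per pixel column, the intensity-weighted
  centroid row of pixels at or above the detection threshold
  (default 0.5 on normalized intensity, per-region overridable). The
  centroid gives sub-pixel resolution and is unbiased for symmetric
  anti-aliased strokes.
- **Doppler envelope**: per column, the outermost super-threshold pixel
  away from the zero-velocity baseline — the maximum-velocity edge, not
  the modal velocity. This is a deliberate choice the display itself
  cannot disambiguate; users tracing modal-velocity conventions should
  expect systematically higher velocities from this tracer. A running
  median over 5 columns suppresses isolated speckle columns; near the
  region edges the window shrinks symmetrically (5→3→1) because an
  asymmetric median biases steep segments by up to a column of slope.
- **Gaps** (cursor/annotation occlusions): interior missing columns are
  linearly interpolated between detected neighbors; missing leading and
  trailing columns are trimmed, never extrapolated. More than 50%
  missing columns is a detection failure.
- **Calibration**: two anchors per axis define invertible affine maps
  (pixel column → s, pixel row → unit). Rows grow downward; the signed
  y slope absorbs the orientation. No OCR of on-screen scales is
  attempted — anchors are explicit, reviewable config.
- **Resampling**: linear interpolation onto a uniform 1000 Hz grid.
  Linear interpolation adds no overshoot, which keeps systolic and
  diastolic extrema honest; the pixel-column sampling of clinical sweeps
  is far below the Nyquist limit of the content that survives a raster
  display, so no pre-filter is applied.

## Beat processing

R peaks gate everything, because the ECG is the only clock the two
captures share. The detector subtracts the median, thresholds local
maxima at 0.6 × a robust maximum of the detrended signal, and accepts
candidates tallest-first under a 0.3 s refractory period (rhythms to
200 bpm). The robust maximum is the 99.5th amplitude percentile: the QRS
complex occupies roughly 2% of samples at physiologic heart rates, so a
lower percentile would sit at baseline level and admit false peaks,
while the true maximum would be fragile to single-pixel glitches. The
relative threshold makes detection invariant to amplitude scaling; a
config flag inverts negative-polarity leads.

Beats run R-to-R; partial cycles at the record edges are discarded. All
beats start included; exclusion is an explicit per-capture index list in
the session config (mirroring investigator-driven beat selection in
cardiac-output practice — no automatic ectopy rejection). Included beats
are linearly time-normalized to the mean R-R interval before point-wise
averaging into the ARB; normalization preserves systolic/diastolic phase
alignment across beats of unequal length, where truncation to the
shortest beat would smear end-diastole.

## Spectrum and parameters

The ARB spans exactly one cardiac cycle, so its FFT bins *are* the
harmonics: amplitude 0 is the beat mean and, for k ≥ 1, amplitudes carry
the one-sided 2/L normalization so |a_k| is the physical cosine
amplitude. The normalization cancels in the P/Q ratio but fixes the
reported |P(k)|, |Q(k)| columns of the spectra export. Defaults:
10 harmonics computed; reliability flag at harmonic 3 (fluid-filled
catheter bandwidth), carried as metadata and plot shading, never
truncating output.

- modulus[0] = mean P / mean Q = TPR. Mean PA pressure is taken from the
  re-digitized trace itself, not from a monitor-reported mean.
- phase = pressure phase − flow phase, degrees, wrapped to (−180, 180];
  negative low-harmonic phase means flow leads pressure.
- Zc averages moduli over harmonics 2–4; Zs sums moduli at 1 and 2. Both
  index sets are config-overridable (`--zc-range`, `--zs-indices`).
  Averaging is over moduli, not complex values.
- A flow harmonic below 1e-12 × |Q(1)| is treated as numerically zero
  and reported as a degenerate-flow error rather than an unbounded
  modulus; the cutoff separates structurally zero harmonics of symmetric
  synthetic flows from float noise.
- Unit conversions: ×1333.22 to dyn·s·cm⁻⁵, ×1000/60 to Wood units.

## Synthetic fixtures

The ground-truth chain is a three-element Windkessel
Z(f) = Rc + Rp/(1 + i·2πf·Rp·C) — the simplest model with a non-flat
modulus and phase per harmonic — driven by a half-sine ejection pulse
(default ejection window 35% of the cycle, a value that also keeps the
pulse's spectral zeros away from harmonics 1–4). Pressure is synthesized
per harmonic in the frequency domain, so the pressure/flow pair is exact
with respect to the analytic impedance; no ODE integrator error enters
the oracle. Each beat occupies a whole number of samples and the record
ends on a beat boundary: with jitter off the record is strictly periodic
on the sample grid, and the core pipeline recovers Z(f_k) to float
precision — the basis of the 1% noiseless recovery check. Each beat's
sampled flow is rescaled so its discrete integral (sum × dt) equals the
stroke volume exactly.

The ECG is a train of unit Gaussian R spikes (20 ms FWHM) over a slow
wander of amplitude ≤ 0.1. The renderer draws anti-aliased polylines for
traces, a filled band with multiplicative texture for the Doppler
spectrogram, dim gridlines, optional background noise, and writes the
exact per-column pixel path, calibration anchors and R times alongside
the image. Speckle dropout (default 10% in "noisy" fixtures) lives
*inside* the band; the outermost envelope pixel is part of the envelope
and a one-pixel zero-line clutter row keeps diastolic (zero-velocity)
columns detectable, as baseline clutter does on real spectrograms.
Off-band bright salt exists as a separate knob, default zero — an
outermost-pixel tracer has no defense against dense off-band outliers,
and real spectrograms put their noise in and near the band. The region
supplied to detection excludes the outermost image column on each side,
where only a single polyline segment lands and the centroid is biased on
steep slopes.

What the fixtures do **not** emulate: fuzzy/faded envelope edges,
respiratory modulation, arrhythmia beyond Gaussian R-R jitter, text
annotations and cursors (gap handling is tested synthetically instead),
compression artifacts of real screenshots. Passing the synthetic suite
therefore demonstrates the pipeline's correctness and noise behaviour,
not robustness to every clinical display.

Default physiologic ranges for randomized fixtures: HR 50–110 bpm,
SV 40–100 mL, Rc 0.02–0.08, Rp 0.2–1.2 mmHg·s/mL, C 1–6 mL/mmHg, PA
diameter 1.8–2.8 cm; rendering at 200 px/s sweep with a 480 px-high
frame. Fixture captures default to 6 s (four to ten beats), which keeps
the rendered images small while giving the ARB several beats to average;
the acceptance study uses 20 randomized sessions.

## Determinism and numerical notes

Every stochastic operation takes an explicit seed; the analysis pipeline
itself contains no randomness, so identical configs and images produce
byte-identical exports. Phase wrapping maps to the half-open interval
(−180, 180] (−180 is reported as +180). Beat indices, pixel coordinates
and harmonic indices are all 0-based; rectangles are half-open. A
harmonic decomposition requires L ≥ 2N+1 samples for N harmonics, so a
two-sample beat admits no spectrum at all and is rejected.

## Known limitations

- One capture pair per stage; averaging spectra or parameters across
  multiple accepted captures of the same stage is a documented extension
  point, not implemented.
- No wave-separation analysis, pulse-wave velocity, or wedge-pressure
  PVR; TPR (not PVR) is the steady-state output.
- The envelope tracer follows the maximum-velocity edge; studies
  calibrated to modal velocity will read systematically lower flows.
- Relative phase error at higher harmonics is ill-conditioned when the
  analytic phase is small (|φ| ≈ 10–15° by harmonic 4 for physiologic
  Windkessel parameters); under noise, modulus is the robust quantity
  and the one bounded by the recovery checks.
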