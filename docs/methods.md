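# Methods

`grfest` implements a complete pipeline for estimating vertical (GRF_v) and
anteroposterior (GRF_ap) ground reaction forces during treadmill running
from a consumer-style wearable stack — a 16-channel force-sensitive-resistor
(FSR) pressure insole, a shoe-mounted IMU, and an instrumented treadmill as
the gold standard — together with a synthetic-data generator that stands in
for a human dataset.  This note records the models, the parameters that
matter, and the design decisions taken where the problem was genuinely open.

## The estimation model

One independent sequence-to-sequence regressor is trained per force
component.  The input for one foot contact is a 400 × 26 matrix: 16 FSR
channels, the centre-of-pressure coordinates (CoP_x, CoP_y), three
accelerometer axes, and five discrete descriptors (ground contact time,
mass, speed, gradient, insole length) broadcast along the time axis.  The
architecture, applied at every timestep:

    input dropout
      → bidirectional LSTM (hidden size H per direction → 2H concatenated)
      → linear(2H → L2) → activation → dropout
      → linear(L2 → L3) → activation → dropout
      → linear(L3 → 1)

Training minimises the batch RMSE between the estimated and measured force
trace with Adam.  The network, backpropagation through time, and Adam are
implemented directly on NumPy arrays; gradient correctness is pinned by a
finite-difference test over every parameter tensor and all four activation
choices, and the parameter count by a closed-form test.

Default hyperparameters are the full-scale selections for the GRF_v model
(H = 512, learning rate 5e-4, batch 8, ReLU; `model.GRF_AP_CONFIG` carries
the anteroposterior selections).  Desk-scale work uses
`model.REDUCED_CONFIG` (H = 64, learning rate 2e-3, 10 epochs, batch 32,
dropout 0.1), sized for cohorts of a few hundred contacts.

Targets are trained in bodyweight units (force / (mass·g), g = 9.81 m/s²),
which removes mass-scale variance from the regression target; raw-Newton
training is available via `ModelConfig.target_units`.

Hyperparameter search (`model.tune`) is a random search over the documented
spaces (log-uniform learning rate 1e-5…1e-1; categorical layer sizes
{32…512}; dropout rates 0.1…0.5; epochs 1…15; four activations), scored by
the mean validation RMSE across subject-disjoint group folds.  Random
search was chosen over a sequential model-based optimiser because the
desk-scale trial counts (tens of trials) give model-based search little
room to pay off; the trial log is persisted so the search can be audited.

## Synthetic data generator

The generator emulates the statistical structure the pipeline relies on,
not running biomechanics in full:

- **Cohort.** Mass, easy running speed and insole length are truncated
  normals (defaults: 65.9 ± 10.4 kg on [45, 100]; 11.0 ± 1.5 km/h on
  [7, 16]; 270 ± 15 mm) pooled across sexes from published
  recreational-runner characteristics.  A latent footstrike scalar in
  [0, 1] (0 = extreme rearfoot) is drawn as a tercile mixture with
  rear/mid/fore proportions 0.54/0.30/0.16.
- **GRF waveforms.** GRF_v is an active half-sine peaking at 45% stance
  (≈2.5 BW at easy pace, scaling with (speed/easy)^0.4) plus a Gaussian
  impact transient at 15% stance whose amplitude, up to 0.8 BW, shrinks
  linearly with the footstrike latent.  GRF_ap is a braking-then-propulsion
  sine whose balance shifts with gradient (+0.012 BW per % incline on a
  half-sine carrier), so uphill running is net propulsive.  Both traces are
  tapered to exactly zero at touchdown and toe-off.  Additive white noise
  (default SD 0.05 BW) models measurement error.
- **Insole.** Sensor geometry is a 4 × 4 grid spanning 5–95% of insole
  length and ±25 mm mediolaterally (real coordinates are proprietary; an
  even spread is the only published constraint).  Per sample, force is
  split over sensors with a normalised Gaussian kernel (width 25 mm)
  centred on a travelling centroid that rolls from a footstrike-dependent
  touchdown point toward the forefoot; each sensor responds
  logarithmically, raw = a·ln(1 + b·F) with a = 1, b = 0.01 N⁻¹.  Because
  kernel weights are normalised, inverting the response recovers total
  force exactly (a tested conservation law).  The 16-sensor grid quantizes
  the recoverable CoP to within the kernel width.
- **Logging.** The device logs pressure only during stance, at 50 Hz, as
  consecutive non-overlapping 20 ms moving averages (a trailing remainder
  gives one partial-window sample), timestamped at the window centre.
- **IMU.** The vertical accelerometer axis follows grf_v/(m·g) − 1 (free
  fall = −1 g between contacts) and the AP axis grf_ap/(m·g), plus a smooth
  low-frequency "segment dynamics" wobble (0.1 g) and white noise, resampled
  to 1,138 Hz and clipped at ±30 g.  Gyroscope channels are generated for
  schema realism but unused by the feature set.
- **Sessions.** Stride times are jittered per participant
  (CV drawn in 0.015–0.05); the treadmill force stream is the reference
  clock and records every contact, while the pressure and IMU devices start
  at independent offsets within ±2 s, so they miss leading or trailing
  contacts — exactly the situation the stride-time alignment must solve.

What the generator does **not** emulate: treadmill vibration, FSR drift and
hysteresis, soft-tissue artefacts in the IMU, left/right asymmetry (only
left-foot data is modelled), or truly out-of-distribution running styles.
Passing tests therefore demonstrate pipeline correctness and learnability
under the stated noise model, not real-world accuracy figures.

## Preprocessing and synchronization

- Filtering is zero-phase (forward–backward) Butterworth, order 4, 15 Hz
  for force and 10 Hz for the accelerometer.  Forward–backward squares the
  magnitude response (half-amplitude at the cutoff), and was chosen to
  avoid phase lag corrupting event timing; it is configurable.
- Contact detection: maximal runs strictly above 40 N on the filtered
  vertical force; runs shorter than 80 ms are discarded as noise; intervals
  are half-open [ic, to) with 0-based indices.
- The stance-only 50 Hz pressure log is upsampled back to 1,000 Hz with a
  piecewise-quadratic interpolant (falling back to linear below 3 knots,
  with a warning); no further filtering is applied to pressure.
- CoP is the pressure-weighted average of the sensor coordinates.  At
  zero total pressure the last valid CoP within the contact is carried
  forward (the grid centroid if none exists yet).
- Each device's stride-time vector (same-foot initial-contact differences)
  is aligned to the force stream's by an exhaustive integer-lag Pearson
  scan (±20 contacts, ≥10 overlapping strides); the alignment is accepted
  above r = 0.85, ties break toward the smaller |lag|.  Zero-variance
  windows make the correlation undefined and produce an explicit rejection
  rather than a repair.
- Per contact, force and accelerometer slices are filtered, pressure
  upsampled, CoP computed, and every channel linearly interpolated onto
  400 points (endpoints preserved exactly); ground contact time is recorded
  in seconds beforehand.  The continuous force stream is filtered once for
  event detection and the segmented slices once more, keeping event timing
  and per-contact smoothing consistent.

## Evaluation

- Per-contact metrics: RMSE in BW; rRMSE = 100·RMSE/range(measured);
  Pearson r; vertical peak and trapezoidal-impulse percentage differences;
  anteroposterior braking/propulsive peak differences in BW and N.  All
  signed differences are estimated − measured.
- LOSO: one fold per participant; standardizer and model are refitted on
  the remaining participants each fold (leak-free by construction and by
  test); a failing fold is recorded and the rest continue.
- Bland–Altman: bias, bias ± 1.96·SD limits of agreement, and the
  least-squares slope of difference vs measured magnitude (the
  "regression to the mean" diagnostic).
- PFI: a channel's values across all contacts are replaced by i.i.d.
  standard-normal draws (inputs are z-scored, so this matches the nominal
  channel distribution); the PFI is the ratio of permuted to original
  RMSE, with both the mean (headline) and median over the 100 repetitions
  reported, since either aggregation is defensible.
- The CoP error profile bins per-contact peak errors by the normalized
  anteroposterior CoP position at touchdown; empty bins are omitted.

## Problem sizes and numerical choices

The test suite and acceptance analyses run at desk scale by design:
protocol stages default to 30 s (full protocol: 2–5 min stages, with the
±10% speed structure preserved), the parameter-recovery experiment uses a
10-participant cohort with 24 contacts each (8 per gradient condition) and
the reduced H = 64 model, and synchronization fidelity is measured over 100
sessions of 50 contacts.  Model arithmetic uses float64 by default for
exactness; experiments pass float32, which is numerically indistinguishable
at these scales and measurably faster.  Degenerate inputs are handled
explicitly: zero-variance feature channels standardize to zero (std
fallback 1), a flat measured trace makes rRMSE an explicit error, and
training aborts with a diagnostic on a non-finite loss.

## Known limitations

- The synthetic forward model is smooth and low-dimensional; real FSR and
  IMU data are rougher, so real-data error rates will be higher than the
  recovery bound demonstrated here.
- Footstrike classification is approximated by the touchdown CoP position
  (the commercial system's classifier is proprietary).
- Sub-contact (sample-level) clock alignment and within-session drift are
  out of scope; alignment is at contact resolution.
- Only vertical and anteroposterior components are estimated; mediolateral
  force is not modelled.
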