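# Methods

## Scope

The package is an end-to-end, testable reconstruction of a µECoG motor
decoding workflow: synthetic grid recordings with known ground truth →
high-gamma (HG) PSD features → position–velocity Kalman decoding → CC /
SNR / bit-rate scoring → electrode-density, coverage and
channel-contribution analyses. Real recordings of this kind are not
publicly deposited, so the synthetic generator defines the reference
conditions every quoted number is computed under.

## Synthetic sessions

A session is rendered per channel as

    s_ch(t) = e_ch(t) · c_ch(t) + n_1/f(t) + n_line(t) + n_cm(t)
              + w_bg · b(t) + n_white(t)

* **Carrier** `c_ch`: white noise band-passed to 70–150 Hz (4th-order
  Butterworth, zero phase), unit RMS, independent per channel. µECoG HG is
  modelled as broadband noise whose *amplitude* carries the signal.
* **Envelope** `e_ch(t) = baseline + Σ_axis gain[ch,axis] · |d_axis(t)|`,
  where the drive `d` is the 3-D kinematic position resampled to the
  acquisition rate and normalized per axis to unit RMS (keeps noise
  presets comparable across profiles).
* **Tuning map**: `n_sources` Gaussian bumps at random positions on the
  array plane, each coupled to one axis (cycling X, Y, Z), amplitude
  0.5–1 × the configured range; per-channel gain is the bump sum at the
  site. The default spatial scale is 1.5 mm, giving millimetre-scale
  spatially specific tuning that stride subsampling can resolve or miss.
* **Noise layers**: 1/f background (white noise with spectrum shaped to
  `f^-1` amplitude exponent, configurable), a 50 Hz line sinusoid plus
  harmonics with `1/h` amplitude roll-off shared across channels, a shared
  low-frequency common-mode process (removed by CAR), independent white
  sensor noise, and a **diffuse synchronous HG background**: one shared
  in-band carrier weighted by a broad (8 mm) Gaussian spatial profile.
  The last layer exists because each channel's private carrier is
  independent — without a shared in-band process, regions *without* local
  tuning would be the least correlated, inverting the empirically expected
  relationship that spatially specific, high-contribution regions show
  *lower* inter-electrode HG correlation than diffusely driven ones.
  Because the background's weights vary across the array, CAR attenuates
  but does not remove it.
* **Kinematics**: the `gait` profile is a quasi-periodic oscillation per
  axis (1.4 Hz stride plus a 0.3-weight second harmonic, slow random
  amplitude modulation, amplitudes 0.6/1.0/0.4 with Y largest, riding on a
  positive offset of 1.2× the amplitude — a joint angle does not cross
  zero). The `center_out_reach` profile chains minimum-jerk point-to-point
  moves (0.8 s move, 0.2 s hold) with zero endpoint velocity. Speed is
  the finite-difference derivative.
* **Bad channels**: `round(fraction · n_channels)` channels drawn without
  replacement get impedance above the 1 MΩ screening threshold and their
  signal replaced by high-amplitude white noise.

Everything is deterministic given its seed; the benchmark preset derives
three sub-seeds (tuning, kinematics, session noise) from one master seed.

What the generator does **not** emulate: volume conduction and electrode
impedance spectra, non-stationarity across a session, movement artifacts,
inter-areal propagation delays, or any biophysical cortical model. Passing
tests therefore demonstrate that the *pipeline* recovers the statistical
structure it assumes, not that the assumptions hold in tissue.

## Benchmark preset

16×16 grid at 1250 µm pitch / 850 µm sites, 300 s gait session, 1000 Hz
acquisition (the 70–150 Hz feature band makes this rate lossless for
features; higher rates stay configurable), 12 sources at 1.5 mm scale,
amplitudes 1.5–2.5 over a 0.2 baseline, noise 5 µV 1/f + 5 µV line +
8 µV common-mode + 0.5 µV white + 0.4 µV shared HG background. With these
conditions the held-out (chronological 30%) mean position CC of the Kalman
decoder is 0.89–0.96 across master seeds 1–5.

The preset was calibrated once, against two constraints: features of
well-tuned channels must visibly track the generating envelope, and the
envelope must remain approximately *linear* in position. These trade off
(see "Periodogram ceiling" below); the calibration favours decodability.

## Feature extraction

Fixed order: impedance exclusion → notch → CAR → resample → bin/PSD →
z-score; a pipeline runner asserts the order.

* Notch: one second-order IIR notch (Q = 30) per harmonic (default
  50/100/150/200 Hz), applied forward–backward. Steady-state attenuation
  measured on tones is 71–93 dB; the first/last ~1 s of any finite segment
  carries the zero-phase edge transient, so attenuation is a
  steady-state quantity.
* CAR reference set = impedance-retained channels. For subsampling
  experiments CAR is computed once over the full retained array and
  features are then column-restricted, mirroring the analysis of subsets
  of a single recorded session; feature extraction itself is per-channel
  and commutes with sub-selection.
* Resampling: polyphase with the built-in anti-alias filter.
* PSD: one Hann-windowed periodogram per 100-ms bin (50 samples at
  500 Hz); the feature is the mean PSD over bins with centres in
  [70, 150] Hz inclusive. Welch segmentation is pointless at this bin
  length.
* Z-score: mean/std from the chronological training split only, applied
  to all bins; zero-variance channels are zeroed and flagged rather than
  erroring (a dead channel can pass impedance screening). Stored
  statistics can be re-applied to a new session without re-fitting
  (cross-session recalibration).

### Periodogram ceiling

A 50-sample Hann periodogram averaged over the 9 in-band frequency bins
has roughly k ≈ 4–5 effective χ² degrees of freedom (Hann windowing
correlates adjacent bins). For a noise carrier this caps the per-bin,
per-channel correlation between the feature and the squared envelope at
√(k/(k+1)) ≈ 0.90 *regardless of modulation depth*, and at realistic
modulation depths (envelope linear in position, no rectification) the
attainable value is ≈ 0.7–0.8 before additive noise. Pushing modulation
deeper raises this figure but folds the drive through the |·| coupling,
breaking the linear observation model and costing far more decoding
accuracy than the feature-level correlation gains. The test suite
therefore checks envelope tracking at CC > 0.9 with a sinusoidal carrier
(deterministic periodogram; isolates the demodulation property) and at
CC > 0.45 per top-gain channel on the benchmark preset (noise carrier at
its attainable level). Decoding does not suffer from the ceiling because
the filter averages over many tuned channels.

## Decoder

State `[p, v, 1]` (7-dim; the bias absorbs feature offsets, since
z-scored features have zero mean only on the training segment). `A`'s
position rows encode `p + dt·v` exactly; the velocity block and `W` come
from least squares on successive pairs; `H`, `Q` from least squares of
features on states (generative direction, standard for neural cursor
filters). `Q` gets a ridge of `max(1e-8, 1e-6·mean diag)` so the
innovation covariance stays invertible even on noiseless data.
Initialisation `x₀ = 0` (bias 1), `P₀ = 10·I` (bias variance 0); the
first 10 bins are excluded from CC scoring as burn-in. Once the Kalman
gain converges (relative change ≤ 1e-9) the steady-state gain is reused;
this keeps 256-channel sessions cheap and changes estimates only below
that tolerance. Constant state dimensions raise a singular-fit error
naming the offending dimension.

The optional LSTM decoder (3 stacked layers, 300/100/50, Adam at 1e-3
with L2 weight decay, truncated-BPTT windows of 50 bins, 7:3
chronological split, early stopping with patience 10 and best-weight
restore) requires `torch` and is not used by any analysis here.

## Metrics and tasks

* CC: per-axis Pearson; constant traces flag the axis undefined instead
  of propagating a 0/0.
* Sliding CC: half-open windows (default 30 s / 10 s step), centre
  timestamps; a binned trace's duration is `n·dt`.
* SNR: rectified 10 Hz-low-passed envelope; 100-ms frames classified high
  (mean envelope > median + 2·MAD) or low (< median); SNR =
  20·log₁₀(peak-to-peak of high frames / RMS of low frames). Frame-level
  classification avoids phase-correlated sample selection that biases the
  low-state RMS. Single-state channels return NaN.
* Bit rate: `log2(N)·max(S−F,0)/T`; timed-out trials are failures with
  their full duration charged to `T`.
* Closed loop: 100-ms ticks; commanded velocity
  `(1−α)·decoded + α·g·unit(target−cursor)` with `g` = 1.5 screen-units/s,
  capped near the target so full assistance lands instead of orbiting.
  Success = 200 ms continuous dwell within radius 0.12 before 4 s.
  Center-out targets on a 0.7-radius ring; webgrids on a 15×17 grid (255
  cells). The synthetic user emits velocity toward the target with
  Gaussian angular noise; a random-walk source provides the chance
  baseline. The assistance blend is a documented stand-in for
  flexible-fixturing-style shared control.
* Paired comparison: Shapiro–Wilk on both groups and Levene variance
  homogeneity at α = 0.05 gate a paired t-test; otherwise the Wilcoxon
  signed-rank test (the rank test appropriate for paired samples).
  Identical groups short-circuit to p = 1. Note the signed-rank test
  cannot reach p < 0.05 below 8 pairs.

## Spatial analyses

* Density subsets: strides {8,4,2,1} anchored at the top-left site;
  {1,4,16,64} channels/cm² over the fixed extent. Coverage subsets:
  centred k×k blocks, ties shifted toward the top-left. Subsets smaller
  than the decoder's state dimension (e.g. the 4-channel stride-8 subset)
  are reported undefined rather than fitted.
* Subsampling performance: per subset, column-restrict the features
  (CAR already fixed over the full array), fit/evaluate on the 7:3
  chronological split; repeats regenerate the session noise from distinct
  seeds via a session factory. Variability is reported as the CV
  normalized to its maximum across subsets.
* Contribution, stage 1: kinematics per axis are tertile-binned (Gini
  impurity needs classes; tertiles are parameter-light and configurable)
  and one random forest per axis yields per-channel importances,
  normalized to sum 1 per axis, plus their mean.
* Stage 2: channels enter in descending importance starting from the top
  5; decoding CC is recorded per size; the optimal subset sits at the
  curve's global peak, first (smallest) on ties; an all-undefined curve
  falls back to the starting subset.
* Contribution map: per-channel frequency of optimal-subset membership
  across sessions, scaled to max 1.
* HG correlation: band-pass 70–150 Hz, 2-s bins, per pair the peak of the
  absolute normalized cross-correlation over lags ±100 ms (FFT-based);
  per-channel similarity curves are the bin-wise mean peak against all
  partners, z-scored per channel. Numerically flat segments skip their
  pairs with a reported count.
* High/low-contribution comparison: the contiguous 4×4 block with maximal
  mean contribution (row-major first on ties, logged) versus the adjacent
  non-overlapping block with the lowest mean; reports within-block HG
  correlation, decoding CC over repeated chronological splits
  (60–80% train), and the gated paired test.

## Problem sizes

The test suite runs the full benchmark preset once (16×16, 300 s) for the
end-to-end accuracy check, a 150-s variant with 5 fresh-noise repeats for
the density experiment, and 8×8 / 6×6 sessions of 100–120 s elsewhere;
the acceptance script regenerates the full benchmark for its single
reported quantity. These sizes keep a complete run on one CPU within a
few minutes while leaving every statistical conclusion at its stated
threshold.

## Known limitations

* The generator's linear gain-times-|drive| coupling and noise layers are
  statistical stand-ins; no claim is made about biophysical realism.
* The Kalman observation model is linear in position/velocity; the
  feature's quadratic dependence on the envelope is absorbed only to the
  extent the modulation stays quasi-linear.
* The closed-loop user model bypasses feature synthesis (velocity-level
  stand-in) unless a decoder-backed source is supplied.
* Bit rates from the simulated task depend on the user-model parameters
  and are not comparable to human performance figures.
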