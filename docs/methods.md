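# Methods

## Signal model and assumptions

The recording is modelled as an instantaneous, noiseless-mixing linear
system `X = A S + n`, with `X` the M×N channels-by-samples matrix, `A` a
full-column-rank M×L gain matrix, `S` the L×N source matrix (maternal and
fetal ECG waveforms) and `n` additive sensor noise.  The model assumes the
propagation from each cardiac source to each electrode is memoryless and
stationary over the analysis window, that `L ≤ M < N`, and that channels
are mean-centred.  As in all blind separation, the scale, sign and
permutation of recovered sources are undetermined; every extractor here
returns unit-norm rows and the evaluation stage aligns estimates to truth
(Hungarian assignment on |correlation|, then sign) before any metric is
computed.

## The null-space projector

With denoised data `Xp` (zero-mean rows), the separation operator is

    W = (1/N)·Xpᵀ Cx⁻¹ Xp,   Cx = (1/N)·Xp Xpᵀ,

the orthogonal projector onto the row space of `Xp`.  Numerically W is
built from the economy SVD `Xp = U Σ Vᵀ`: `W = V f Vᵀ` with per-direction
shrinkage `f_i = s_i/(s_i + λ)`, `s_i = σ_i²/N`, and ridge
`λ = 10⁻¹⁰·trace(Cx)/M`.  Directions with `σ_i ≤ 10⁻⁸·σ_max` are
truncated, so rank-deficient data (e.g. a noiseless mixture of L < M
sources) yields a projector of the numerical rank rather than an error;
only identically-zero data raises.  This makes W idempotent and symmetric
to machine precision, which is what the construction's name promises and
what the null-space step needs.

The sources are read out of the null space of `Q = W − I_N`.  Q's singular
values are 1 on the orthogonal complement of the row space and ≈ 0 on the
row space; sorting them strictly descending places the null-space basis in
the last columns of `Vq`, internally ordered by ascending data variance.
Taking the **last L columns** therefore returns the L dominant-variance
directions of the data — the maternal component and the weaker fetal one —
which is the deterministic tie-break this package uses for the otherwise
degenerate null-space basis (`order_by="xp_spectrum"`).  A full SVD of Q
(`order_by="svd_native"`, O(N³)) is kept for small-N cross-checks; a guard
refuses N > 20 000 because W is a dense N×N matrix.

No rotation beyond this variance ordering is applied inside the null
space.  The consequence is analysed under *Limitations*.

## Preprocessing

Each channel passes a cascade of 4th-order Butterworth low-pass (100 Hz),
4th-order Butterworth high-pass (0.5 Hz, baseline wander) and a
second-order IIR notch (50 or 60 Hz by configuration, quality factor 30).
Filters run forward–backward by default so R-peak positions are not
delayed; padding is set to three time constants of the slowest stage
(~6 s at 0.5 Hz) because shorter padding leaves a visible boundary
transient.  A causal single-pass mode is available.

## Peak detection and heart rates

R peaks are found with a Pan–Tompkins pipeline (band-pass, derivative,
squaring, moving-window integration, adaptive dual thresholds with
search-back, refinement to the largest band-passed deflection).  The
classic parameters — 5–15 Hz band, 150 ms integration, 200 ms refractory —
serve the maternal trace; the fetal mode uses 10–25 Hz, 80 ms and 150 ms
to suit the narrower QRS and rates up to ~180 bpm.  Both sets are
configurable; squaring makes detection polarity-blind, which matters
because separated sources carry arbitrary sign.  Heart rates are exact
arithmetic on the indices: `rate_l = 60·fs/(p_{l+1} − p_l)`, averaged over
intervals.

## Control logic and comb filter

Removal of residual maternal beats from the raw fetal trace activates only
when `var(FHR) > maxvar` **and** `mean(FHR) > maxFHR` (defaults 3 and
180 bpm; variance is the sample variance, ddof = 1).  An extra maternal
peak between two fetal peaks halves the local RR interval, which doubles
the local rate — inflating both statistics at once; requiring both
clauses keeps normal rate variability (which easily exceeds `maxvar`
alone) from triggering removal.  An `fhr_stat="any"` mode tests single
intervals instead of the mean.

The comb gain is 1 outside windows of half-width `U` centred at maternal
peaks, and `a_r = 0.46 − 0.46·cos(2πr/(2U+1))` inside, giving exactly zero
gain at each maternal R sample.  The coefficients are implemented in this
valley form deliberately (an `1 − Hamming` `complement` variant is a
switch); overlapping windows combine by pointwise minimum and windows
truncate at record edges.  The default window is 21 samples at 1 kHz
(U = 10), scaled proportionally with fs; recommended total lengths are
20–45 samples at 1 kHz — longer windows start deleting fetal beats that
fall near maternal ones.

## Baselines

* **PCA**: whitening `Cx^{-1/2} Xp` through an eigendecomposition; rows
  are uncorrelated with unit variance, and the L dominant-variance
  components are returned (`select="minor"` available).
* **FastICA**: scikit-learn's fixed-point implementation (log-cosh
  contrast, symmetric decorrelation, 200 iterations, tol 1e-6), seeded for
  determinism.  Inputs whose whitened components all have near-zero excess
  kurtosis are flagged as non-identifiable; components are still returned.
* **PLP**: the cited construction leaves the prediction-error vector and
  iteration space open, so this package implements the linear-predictor
  reading: each extracted waveform `y_m = w_mᵀ Z` (Z whitened) minimises
  its one-step AR(1) prediction error `E_r(n) = y(n) − c·y(n−1)` by
  relative-gradient descent with the coefficient `c` refit every
  iteration, deflation keeping the L predictors orthogonal, and a
  divergence watch (update norm growing for 10 consecutive iterations
  while overshooting the unit sphere) that raises naming `mu_y`.  The most
  temporally predictable source — the slower, smoother maternal ECG — is
  extracted first.  Defaults: `mu_y = 0.01`, 500 iterations, tol 1e-8.

## Evaluation metrics

* **SPI** `= (1/L)·Σ 10·log10(⟨y,y⟩⟨s,s⟩/⟨y,s⟩² − 1)`; more negative is
  better, 0 dB ⇔ squared cosine 0.5.  The algebraic form is the one
  consistent with "more negative = more similar"; exact matches floor at
  −300 dB and orthogonal pairs cap at +300 dB (all dB caps are ±300).
* **BSS-eval**: the estimate is orthogonally decomposed into `s_target`
  (projection on its matched source), `e_interf` (rest of the source
  span), `e_noise` (extra span of the true noise channels) and `e_artif`
  (remainder); SIR/SAR/SDR are the standard energy ratios.  Requires
  simulation truth.
* **qSNR** `= 10·log10(Σ ŝ²/Σ(s − ŝ)²)` after least-squares amplitude
  alignment; the numerator uses the estimate as printed in the source
  formulation (a `conventional` switch uses the truth).
* **SE/ACC/PPV** from TP/FP/FN counts obtained by greedy one-to-one
  nearest peak matching within ±50 ms (the PhysioNet Challenge 2013
  convention; configurable).

## Synthetic data

Each source is a train of Gaussian deflections (P, Q, R, S, T) on a
per-beat axis: amplitudes relative to R (0.15, −0.10, 1, −0.25, 0.35),
widths in ms (35, 9, 13, 9, 60 maternal; ×0.6 fetal), temporal offsets as
fractions of the RR interval so morphology compresses at higher rates.
Beat-to-beat RR jitter is multiplicative Gaussian (default 3 %, truncated
at ±3σ) to emulate quasi-periodicity.  Defaults: maternal 80 bpm, fetal
140 bpm, fs 250 Hz, 10 s.

The fetal source is rescaled by `p = sqrt(pm/pf)·10^(q/20)` so that the
fetal-to-maternal power ratio equals exactly `q` dB — the sign convention
that realises the stated fmSNR (the literal printed exponent `−q/20` would
amplify a weak fetal source and is treated as a typographical slip).

Mixing gains model dipole projections: abdominal rows see both sources
with random magnitude *and sign*, thoracic rows have near-zero fetal gain.
Columns are normalised to unit norm — column scale is unidentifiable
anyway, and unit columns make the source-level power ratio carry to the
mixture, so fmSNR is the single knob controlling fetal prominence.  White
Gaussian noise is added at a stated mixture-to-noise ratio, measured as
total clean power over total noise power (a per-channel option exists).
All randomness flows from one seed through independent sub-streams.

What the generator does **not** emulate: volume-conductor propagation and
electrode-position physics, coloured physiological noise (EMG, electrode
motion, uterine activity), fetal movement or rate accelerations,
waveform-morphology pathology, and maternal reference electrodes with
amplitudes far above the abdominal leads.  Passing the synthetic
benchmarks therefore demonstrates correctness of the algorithms under the
stated mixing model, not clinical performance on real recordings.

## Benchmark problem sizes

The recovery benchmark uses 20 seeded mixtures of 5 channels
(3 abdominal + 2 thoracic), N = 2500 samples at 250 Hz, fmSNR −10 dB,
mixture SNR 12 dB.  The fmSNR sweep covers {−30, −20, −10, 0} dB with
5 seeds per level for all four extractors.  The projector diagnostics run
100 random matrices with M ∈ {2…6}, N ∈ {50…500}.  These sizes keep the
whole suite in the order of seconds while leaving the statistics stable
across seeds.

## Limitations

* **Equal-power degeneracy.**  When the fetal and maternal sources reach
  comparable power (fmSNR → 0 dB) under equal-norm mixing columns, the
  mixture covariance becomes nearly degenerate inside the source plane,
  and *any* second-order criterion — the null-space variance ordering here,
  or PCA — returns an essentially arbitrary rotation of the two sources.
  In the sweep benchmark this shows as a qSNR drop at 0 dB for the
  second-order extractors while FastICA (higher-order statistics) and PLP
  (temporal predictability) keep improving.  Real montages sidestep the
  issue because chest reference electrodes record the maternal ECG at
  several times the abdominal amplitude, which keeps the maternal
  eigen-direction pinned; reproducing that montage, however, raises the
  noise budget implied by a fixed record-level SNR enough to push the weak
  fetal component toward the noise floor, so the generator keeps the
  equal-norm convention and documents the degeneracy instead of hiding it.
* The comb filter zeroes fetal samples that coincide with maternal beats;
  overlapping fetal/maternal R peaks lose fetal information by design.
* The projector is dense N×N; long records must be processed in windows
  (the API enforces this with the N ≤ 20 000 guard).
* The extracted waveforms are linear combinations of the recorded
  channels; in-band sensor noise projected onto the fetal direction is
  irreducible by this family of methods, which bounds the attainable
  waveform correlation at low fmSNR.
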