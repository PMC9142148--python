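# Methods

This note documents the models, the synthetic worlds the package is tested
in, the numerical choices, and the limits of what a green test establishes.

## Causal feature chain

Band power is estimated per channel and band as the variance of the
causally filtered signal over a trailing window, updated every 100 ms
(packet clock). Filters are order-4 Butterworth band-passes applied
forward-only (`scipy.signal.sosfilt`); no filter is named by the underlying
experimental convention, and a causal IIR is the realization an online
system would use. The filter's frequency response is exported
(`features.band_filter_response`) and serves as the oracle for
pass/stop-band tests: a unit sine at a band's geometric center yields a
variance of A²/2 = 0.5 within 5 %, and leakage into non-overlapping bands
stays below 5 %.

Two descriptions of the variance window circulate for this kind of
pipeline ("intervals of 1 s" vs band-specific windows); we use the
band-specific table (θ 1000 ms; α and the three β bands 500 ms; the three
γ/HFA bands 100 ms), evaluated at every packet end. Variance over partial
windows is computed during the first second and the whole first 10 s is
flagged burn-in, because the normalization median is not warm before that.

Normalization: `v_norm = (v − med) / (med + ε)` with `med` the median of
the trailing 10 s **including** the current sample (100 values at 10 Hz)
computed on raw features, then clipped to [−2, 2]. `ε = 1e−12·(1 + |med|)`
guards the zero-median case; its scale is far below any feature of
interest. Warm-up uses the median over whatever history exists. The whole
chain is strictly causal, which the tests verify bit-exactly by truncating
recordings.

Lag concatenation appends the 4 preceding packets (8 bands × 5 lags = 40
features per channel, covering 0 to −400 ms); rows without full lag
history are dropped, never zero-padded.

## Force target

The cleaning recipe referenced in the literature is not restated anywhere
we could implement from, so the package uses a causal substitute: subtract
the trailing-window (15 s) 10th percentile, twice, then half-wave rectify.
A single pass leaves an offset proportional to the drift slope (the
percentile of a trending window estimates the past, not the present); the
offset is nearly constant, so a second identical pass removes it. The
baseline is evaluated every 100 ms on a 10× subsampled window and held —
loss-free at force bandwidths. The first ~2 window lengths (30 s) are a
baseline warm-up.

Movement onsets: threshold crossing at 10 % of the session maximum held
for ≥ 100 ms, 500 ms refractory, then backtracked to the last sample at or
below 2 % of the maximum, which lands near the ramp foot (≤ 50 ms error on
noise-free ramps, ~recall = precision = 1.0 at the generator's default
noise). Peak-force variability uses the sample (n−1) variance, appropriate
for small repetition counts. Z-scoring is session-wide by default — the
convention of the emulated study, which technically lets label *scaling*
(two scalars) span CV folds; `zscore_session(train_index=...)` provides the
strictly leak-free variant.

## Decoders

* **Wiener filter** — normal equation on the lagged feature matrix with
  ridge jitter `1e−8 · tr(XᵀX)/p` for conditioning (perturbs coefficients
  ~1e−8, far below the 1e−6 oracle-equivalence tolerance); pseudo-inverse
  fallback on rank deficiency.
* **Elastic net** — scikit-learn coordinate descent for the objective
  `1/(2n)‖Xw−y‖² + αρ‖w‖₁ + α(1−ρ)/2‖w‖²`, max 1000 iterations; α = 0
  short-circuits to the closed-form least-squares solution.
* **MLP** — `MLPRegressor`: 1–3 hidden layers of 1–10 units, sigmoid/tanh,
  linear output, Adam (β₁ = 0.9, β₂ = 0.999), MSE, batch 100, ≤ 1000
  epochs, early stopping on an internal 80/20 split with patience 10.
  Batch normalization and dropout (0.2) from the emulated architecture
  have no sklearn counterpart and are omitted; at 1–10 units per layer
  their regularizing role is minor. The sampled "input nodes" of the
  original description cannot vary (input width is fixed by the features);
  the first hidden layer is sampled 1–10 instead.
* **GBT** — `GradientBoostingRegressor`, 10 boosting rounds; depth ~
  U{1..100}, learning rate η ~ logU[1e−5, 1], minimum splitting loss γ ~
  U(1, 10). In gradient-boosting frameworks γ thresholds an n-scaled gain;
  sklearn's `min_impurity_decrease` is per-sample-weighted, so γ is mapped
  as `min_impurity_decrease = γ/n`, preserving the property that γ ∈
  [1, 10] is a mild regularizer at realistic n rather than a tree killer.
* **SPoC** — generalized eigenvalue problem `C_z w = λ C w` with
  `C_z = mean_e(z_e C_e)`, `C = mean_e(C_e)`, z-scored epoch targets and a
  `1e−6·tr(C)/C` identity shrinkage. The single filter with the largest
  |λ| is kept. Log-variance features are invariant to the sign of **w**,
  so a "sign convention" cannot act through the filter; the sign of the
  training feature–target covariance is stored on the filter object
  instead. For continuous decoding (`evaluation.spoc_nested_cv`) the
  recording is epoched into non-overlapping 1 s windows on the feature
  clock with the epoch-mean z-scored force as target, and filters are fit
  within each outer training fold only (no leakage).

## Evaluation protocol

Outer 3-fold over **contiguous** time blocks (autocorrelated series make
shuffled folds leak), 2/3 train / 1/3 test. Hyperparameters: 10 rounds of
Bayesian optimization per outer fold — 5 random points, then 5 expected-
improvement points under a Gaussian process with a Matern-5/2 kernel over
the unit-cube-encoded space (256 random candidates per acquisition
maximization; integers and categories encoded to [0, 1]). The inner
objective is the mean validation R² over three contiguous splits, each
80 % train / 20 % validation (the literal "3-fold with 80 % training" is
self-contradictory; this honors both numbers). The MLP skips the inner CV
(single 80/20 split), reproducing the emulated protocol. Non-finite
objective values are scored worst-so-far and the search continues. All
fits are deterministic given (data, seed).

**Chance level.** The generic permutation test is two-sided Monte-Carlo
(`p = (1 + #{|s*| ≥ |s|}) / (1 + n_perm)`) with index shuffling for
exchangeable pairs and circular label shifts (≥ 10 s, beyond the
normalization memory) for time series. For *decoding performance*
specifically, shifting only the final label trace against a fixed
out-of-fold prediction is miscalibrated: the prediction is a function of
the labels it was trained on, and shared slow confounds (force-drift
residue, feature normalization dynamics) survive training and inflate the
two-sided statistic on ~20 % of null simulations.
`evaluation.decoding_permutation_pvalue` therefore re-runs the full
train/predict procedure on each shifted surrogate and compares mean test
R² one-sided — calibrated by construction (measured type-I ≈ 0.05–0.10 at
the criterion's grid; 18/20 null seeds non-significant, planted-signal
fixtures p < 0.01).

Cluster-corrected sample-wise correlation: Spearman across subjects per
time point, cluster-forming threshold from the t-approximation at
p < 0.05, cluster mass = Σ|r|, null = maximum cluster mass over score
permutations, significance at the 95th percentile. Measured type-I error
0.030 over 200 null simulations. The percentage-bend correlation follows
the published robust estimator with bend constant 0.2 (cross-checked
against an independent implementation to 1e−10). FDR is Benjamini–Hochberg
step-up.

## Synthetic worlds and what green tests mean

**Recordings.** Channels are 1/f background (spectrally shaped white
noise) plus unit-variance band-limited oscillators (filtered white noise):
beta at 4× and gamma at 1.5× relative amplitude against an 8× background.
Movement-locked modulation: beta amplitude × (1 − beta_desync·gate) with a
smoothed 1.5 s gate after onset; gamma amplitude × (1 + gamma_coupling ·
force). Contralateral channels get the full planted gains; ipsilateral
gains are divided by `contra_gain` (default 2). Pre-movement beta bursts
(amplitude ×3, 200–400 ms, Poisson `burst_rate` per preparation second)
are injectable and recorded in the ground truth. Force = raised-cosine
ramps (250 ms rise, 1–2 s plateau, peaks U(0.8, 1.2) — movement-to-
movement variability without a stated functional form), a 0.005 Hz drift
sinusoid (amplitude 0.5) and white noise (sd 0.05). Defaults emulate an
intraoperative session: ~1 movement per 8.5 s.

What the generator does **not** emulate: non-stationary impedance drift,
stimulation or movement artifacts, cross-channel correlated noise,
waveform shape, or aperiodic-exponent changes. A green decoding test
establishes that the pipeline recovers planted spectral amplitude coupling
without leakage — not that it handles every pathology of real recordings.

**Null world.** "No decodable signal" means *all* movement-locked neural
modulation off (`gamma_coupling = beta_desync = burst_rate = 0`); zeroing
only the gamma coupling leaves beta desynchronization, which any correct
decoder legitimately decodes.

**Connectomes.** Fibers are quadratic Béziers through a sampled midpoint
(hub ± 1 mm for the hub fraction, default 50 %); sites are placed near
fiber paths — a hub-proximal cluster (40 %) plus on-fiber sites — the way
recording strips overlie tracts. Uniformly scattered sites would leave no
fiber passing the >20 %-of-sites traversal filter at the 5 mm connection
radius. Site performance = `slope_a · (normalized hub connectivity) +
N(0, noise_sd)`, truncated to [0, 1]. Fingerprints are connected-fiber
vertex densities on a 4 mm grid smoothed with an 8 mm FWHM kernel. The
aggregated fiber score is the plain t-weighted sum over significant
connected fibers: normalizing by connected-fiber count (an option,
`normalize_by_count=True`) removes exactly the degree signal that carries
the planted hub relation and drops leave-one-out ρ from ~0.9 to ~0.2, so
the sum is the default. The >20 % traversal rule is applied per fiber on
geometry only (no performance information), so computing it once outside
the CV loop cannot leak.

## Numerical conventions and degenerate inputs

- Bipolar sign: `contact_i − contact_{i+1}` (lower minus upper).
- CAR pool: ECoG channels of the same hemisphere (cross-hemisphere
  averaging is physically implausible for per-hemisphere strips).
- Final partial packet: discarded, as online operation would.
- Burst boundary: strictly `> threshold`; a sample equal to the threshold
  is not in a burst; a single supra-threshold sample is a 100 ms burst.
- Rest periods for burst thresholds: outside (−1 s, +2 s) around any onset
  and outside burn-in.
- Best channel ties: first channel in iteration order.
- Constant R-map voxels (std below `1e−12·(mean+1)`, i.e. round-off) are
  stored as 0 and masked; constant LOOCV predictions report ρ = 0, p = 1.
- Degenerate t-score groups (< 2 sites on either side) are NaN-flagged and
  excluded from FDR.
- Disk format stores samples as little-endian float32; round trips are
  exact to ~1e−6 of the stored amplitude.

## Known limitations

Single-CPU scale: multi-seed statistical arms use 150 s recordings and
reduced permutation counts (200–500); the reference decoding fixture uses
the full 10 minutes. The MLP family approximates the original architecture
(no batch-norm/dropout). SPoC decoding uses 1 s epochs (the epoching of
the emulated study is unstated). BrainVision IO is not provided; the
documented binary+TSV fallback layout is used instead (the standard
readers for that format are not part of this environment).
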