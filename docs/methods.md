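# Methods

`cardioresp` extracts three families of cardiorespiratory features from
paired ECG and respiratory-airflow recordings and compares their
discriminative value for a binary clinical contrast (e.g. type 2
diabetes vs control) under class-imbalance-aware cross-validation.
This note documents the models, the estimator internals, the synthetic
cohort the tests are built on, and the limitations of both.

## Signal model and preprocessing

The substrate is the R-to-R interval (RRI) series, obtained from the
ECG with a Pan–Tompkins-style detector: band-pass 5–15 Hz, derivative,
squaring, 150 ms moving-window integration, adaptive signal/noise
thresholds and a 200 ms refractory period, with each detection refined
to the local band-passed maximum. These constants are the canonical
published values. Respiratory airflow (mL/s) is integrated
trapezoidally into instantaneous lung volume (ILV, mL); a single
least-squares line is subtracted per segment to remove the drift that
any flow offset accumulates. Breath-by-breath re-zeroing was rejected
because it distorts phase in the 0.15–0.4 Hz band, exactly where the
coupling of interest lives.

Analysis uses a single 240 s segment per subject — long enough for ten
cycles of the 0.04 Hz low-frequency (LF) floor, short enough to be
plausibly stationary. The screening stage flags beats whose RRI
deviates more than 20% from an 11-beat local median as suspect (an
ectopy proxy), flags 10 s airflow windows whose variance falls below
10⁻⁴ of the record variance as signal flattening, and accepts the
earliest 240 s window with under 5% suspect beats and no flattening;
otherwise it returns a typed rejection with reasons. The 20% / 5%
thresholds are stipulations; there is no universal standard.

Both the tachogram and the ILV are resampled to a uniform 4 Hz grid by
cubic splines and detrended with a degree-3 polynomial over the
segment, which suppresses <0.04 Hz drift without attenuating the LF
band. Each RRI is stamped at its interval *midpoint* before splining:
stamping at the later beat (a common shortcut) imposes a spurious
half-interval (~0.45 s) phase lag on the tachogram relative to the
respiratory drive, which is material for causal kernel estimation.
4 Hz comfortably covers the 0.04–0.4 Hz analysis range and keeps
system-identification design matrices small; a 240 s segment yields
960 samples.

## Spectral HRV

Welch periodograms with a 256-sample (64 s) Hann window and 50%
overlap give 0.0156 Hz resolution and at least six averages per
segment. HRV features are the trapezoidal band integrals of the
one-sided density over LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz), in
ms², plus their ratio; band membership is half-open `[lo, hi)`. The
LF/HF ratio is reported as missing — never infinity — when HF power is
zero. Absolute powers are reported (normalized units are a config
option).

## Frequency response function (FRF)

The noncausal transfer estimate from ILV to RRI is
H(f) = S_xy(f)/S_xx(f) from Welch cross- and auto-spectra with the
same windowing as the HRV spectra, with magnitude-squared coherence
γ²(f) = |S_xy|²/(S_xx·S_yy). The convention S_xy = E[X*(f)·Y(f)] makes
a pure output delay τ appear as phase −2πfτ. Band features are
unweighted means of |H(f)| over the LF and HF bins (ms/mL). Plain
(unmasked) averaging is the default: in realistic records most LF-band
RRI power is a non-respiratory oscillation, so LF coherence is
genuinely low and a 0.5-coherence mask would leave the LF feature
undefined for most subjects. Coherence masking remains available via
`coherence_min` for users who prefer noise-guarded gains.

## Causal impulse response (IR)

The directional counterpart models
rri[t] = Σⱼ h[j]·ilv[t − d − j] + e[t] with a non-negative transport
delay d, i.e. present and past input only. Restricting the regression
to a causal kernel "opens the loop": it attributes RRI variance to
preceding respiration, separating feedforward vagal drive from
feedback pathways that a symmetric spectral estimate mixes.

The default estimator expands the kernel over orthonormal discrete
Laguerre functions (decay parameter α = 0.85 at 4 Hz, i.e. a ~1.5 s
time constant over a 25 s memory), with the number of functions (2–10)
and the delay (0–3 s in 0.25 s steps, the physiological vagal latency
range) chosen jointly by minimum description length. A plain
ridge-regularized FIR mode (`basis="fir"`, λ by generalized
cross-validation or fixed) is retained; it is exact on white-noise
designs but proved fragile on realistic records, where the
non-respiratory LF oscillation violates GCV's white-residual assumption
and 100 free taps can synthesize spurious sharp resonances. The
Laguerre default was adopted for precisely that reason: few, smooth
degrees of freedom are the field's standard defense.

Because the LF disturbance is strongly autocorrelated, the selected
model is refit once by generalized least squares: an AR(8) model of
the residual whitens both series before a second delay/order search.
AR(8) was the best compromise found between HF fidelity and LF
contamination; raising the order further suppresses LF leakage at the
cost of HF accuracy.

Kernel descriptors: **IR magnitude** = peak |h| (ms/mL, immediate
respiratory influence); **dynamic gain** DG = band-averaged |DFT| of
the zero-padded (1024-point) kernel over total (0.04–0.4 Hz), LF and
HF bands; **characteristic time** t_char = lag of the peak absolute
coefficient measured from lag zero, transport delay included
(onset-to-peak; a decay-to-1/e variant would be a reasonable
alternative and is easy to add). An all-zero kernel yields zero
descriptors with a degenerate flag.

## Synthetic cohort generator

The generator exists so the whole chain can be verified against known
ground truth. Each subject is:

* **Respiration** — a tone at the breathing rate (0.2–0.3 Hz across the
  cohort, within the HF band) with 5% slow frequency wander and a
  15%-RMS band-limited (0.05–0.45 Hz) stochastic volume component
  emulating breath-to-breath variability. Tidal-volume amplitude
  400 mL. The broadband component keeps ≥95% of respiratory power
  within ±0.05 Hz of the fundamental while making the transfer
  function identifiable at every band bin, as with real
  (non-metronomic) breathing.
* **RRI profile** — baseline 900 ms (SD 50 ms across subjects), an LF
  oscillation at 0.09 Hz with 25 ms amplitude (SD 5 ms) standing in
  for baroreflex/Mayer-wave activity, plus the causal response of a
  ground-truth kernel to the ILV. The default kernel is a decaying
  exponential (peak 0.02 ms/mL, 1.5 s decay, 0.5 s delay, taps every
  0.25 s out to 6 s), giving an RSA amplitude of roughly 15–20 ms —
  ordinary for older adults.
* **Beats** — integral pulse frequency modulation of the instantaneous
  RRI profile, events quantized to the raw 250 Hz grid, then additive
  white Gaussian RRI noise (default 5 ms SD).
* **ECG** — a sharp biphasic template at each beat time over a small
  baseline wander (QRS ≥ 5× background), enough to exercise a real
  QRS detector, with no pretence of P/T-wave morphology.

The two-class cohort (default 18 cases / 11 controls) encodes the
group effect as a multiplicative attenuation of the coupling kernel
(cases × 0.6, log-normal subject scatter SD 0.1), mirroring the
blunted respiratory sinus arrhythmia expected under cardiovascular
autonomic neuropathy without asserting a literature magnitude. All
within-group distributions are stipulations, not estimates; passing
tests demonstrate that the estimators recover known coupling under
this idealized model, not that real recordings behave this way. In
particular the generator has no ectopy (unless injected), no
colored RRI noise, no posture transients, and white — not 1/f — LF
background.

## Known limitations and numerical notes

* **Beat-mediated observation low-pass.** Intervals average the
  underlying modulation, attenuating ~0.25 Hz content by ≈3–8%
  (sinc-like). This bounds end-to-end HF gain recovery even with
  noise-free signals; the midpoint stamping keeps the measured
  noise-free dg_HF error under ~7%.
* **LF identifiability.** When LF input excitation is weak, the
  non-respiratory LF oscillation leaks into the kernel's LF response;
  dg_LF and t_char are therefore noisier features than dg_HF, and the
  estimated transport delay is weakly identified under narrowband
  drive. This is a genuine property of open-loop identification from
  spontaneous breathing, not an implementation artifact.
* **Leakage-by-design in the evaluation.** Balancing and z-scoring are
  applied to the *full* table before the stratified 5-fold partitions
  are drawn, replicating the small-cohort exploratory design this
  package mirrors (SMOTE neighborhoods then span train and test
  folds). A methodologically clean fold-wise mode
  (`ExperimentConfig(foldwise=True)`) balances and normalizes inside
  each training fold and is labelled a deviation.
* Classifier hyperparameters are deliberately plain: logistic
  regression (L2, C=1), linear SVM (C=1), RBF SVM (C=1, γ = scale);
  AUC uses predicted probabilities for LR and decision values for
  SVMs. Correlation filtering drops a column only when |r| strictly
  exceeds 0.8 against an already-retained column (left-to-right greedy
  scan, ties by column order); z-scoring uses the sample SD (n−1).
* Degenerate inputs are typed errors, not NaNs: flat ECG →
  `NoBeatsError`; constant ILV → `IllConditionedError`; a fold whose
  test split lacks a class reports undefined metrics excluded from the
  mean with a warning.
* Test problem sizes: spectral and FRF oracles use 4096–16384-sample
  records at 4 Hz; the Monte-Carlo kernel-recovery sweep uses 20
  replicates of 960 samples at 10 dB SNR; cohort-level tests use 13 or
  29 subjects. These sizes give the oracles comfortable statistical
  margin over the asserted tolerances.
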