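# Methods

## Scope and data model

The package analyses continuous-wave fNIRS recordings of a passive
block-design auditory experiment: three conditions (speech 5.25 s, noise
5 s, silence 5 s), 20 trials each, inter-stimulus intervals uniform on
[10, 20] s (offset to next onset), raw sampling at 5.2 Hz.  The montage
has 12 sources and 12 detectors forming 24 long channels over four ROIs
(left IFG 4, left STG 6, right STG 6, occipital 8) plus 8 short
channels: detectors 8 mm from the sources at AF7, F7, T7, CP5, O1, O2,
CP6 and T8.  Optode positions come from MNE's standard 10-05 coordinate
table; all 24 long separations fall in 29.4–39.3 mm, inside the
20–40 mm analysis band, so the optional head-scale factor defaults
to 1.0.  Every stage transforms a `Recording` whose unit tag (raw
intensity → optical density → μM) enforces pipeline order.

## Optics

ΔOD is the negative natural log of intensity against the session-mean
intensity; the modified Beer–Lambert inversion uses bundled molar
extinction coefficients (default wavelengths 760/850 nm) with
`d_cm · ppf` as the effective pathlength and `ppf = 0.1` as the
configured default.  Two consequences are deliberate:

* concentrations are *changes* referenced to the session mean, so
  absolute traces are identified only up to an additive constant —
  identity checks compare mean-centred traces, and every analysis
  quantity (epoch baselines, GLM betas against a constant column) is
  offset-invariant;
* `ppf = 0.1` is small relative to typical differential pathlength
  factors; it is reproduced as configured, not corrected, and only
  scales the μM axis since simulator and analysis share the forward
  model.

## The simulator

`SimulationConfig` defaults define the study conditions with known
ground truth.  Neural responses exist only in ROIs with a configured
amplitude (speech 2.0 μM, noise 1.0 μM HbO peak in both STG regions);
each channel trace is the sum over events of amplitude × (stimulus
boxcar ⊛ canonical HRF), with the single-event kernel peak-normalised so
"amplitude" is the isolated-event peak in μM.  HbR is −HbO/3 (inverted,
smaller — configurable).  Systemic physiology — a 0.1 Hz Mayer sinusoid
(2.0 μM), a 1.1 Hz cardiac sinusoid (0.5 μM), and a random-walk drift
(0.1 μM/√sample) — is one shared trace per subject with random phase,
scaled per channel by gains U(0.5, 1.5), fully present in short channels
(which carry no neural signal).  Systemic HbR co-varies *in phase* with
HbO at ratio +0.2: systemic oscillations are blood-volume changes, and
an anti-phase ratio would nearly cancel the extinction-weighted cardiac
signature at 760 nm.  Additive noise is stationary AR(1) concentration
noise (σ = 1.0 μM, φ = 0.5) per row plus white instrument noise in OD
(σ = 2 × 10⁻⁵) per wavelength.  Subjects differ by a neural gain
~ N(1, 0.2) (floored at 0.1), which is what gives the group-level mixed
models a real between-subject variance component.  One master seed fixes
everything; subject *i* uses child seed `seed + i`.

Noise levels were fixed at design time to avoid an unrealistically clean
regime: with weaker noise the detection ROCs saturate at AUC 1 for every
method and the sweeps become uninformative.

What the simulator does *not* emulate: event-locked systemic responses,
motion artifacts (a spike/step injector exists as a test utility only),
1/f-structured physiological spectra beyond AR(1), optode-specific
sensitivity profiles, and any nonlinearity of the hemodynamic response.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model, not performance on real scalp data.

## Averaging pipeline

Downsample (polyphase, rational ratio) to 3 Hz → optical density → SCI →
TDDR → nearest-short-channel regression → Beer–Lambert → 20–40 mm
pruning → anti-correlation enhancement → 0.01–0.7 Hz bandpass → epochs
−3…14 s with per-epoch linear detrend → 100 μM peak-to-peak rejection →
per-condition means → ROI means → group bootstrap (subjects resampled
with replacement, percentile band clipped to bracket the mean).
Numerical choices:

* **SCI**: 5th-order zero-phase Butterworth bandpass 0.7–1.45 Hz on OD,
  Pearson correlation between the two wavelengths; threshold 0.8.  It
  requires the raw rate (it cannot be computed after downsampling below
  2.9 Hz, which is why the GLM pipeline at 1 Hz skips it).
* **TDDR**: split at 0.5 Hz (3rd-order Butterworth, no padding);
  iteratively reweight the low-frequency derivative with Tukey biweights
  (c = 4.685, scale 1.4826 × MAD, ≤ 50 iterations, relative tolerance
  √ε); integrate; restore the high-frequency part and the mean.  This is
  the published procedure and is bit-identical to MNE's implementation
  on shared inputs.  It mildly shrinks even clean low-frequency signals
  (~7% of range for a pure sinusoid) — an inherent property of the
  robust reweighting, documented rather than patched.
* **Short-channel regression**: for each long channel the spatially
  nearest short channel by midpoint distance (ties to the lowest index);
  per chroma, subtract `α·s` with the least-squares α computed on
  mean-centred signals.  The regression never increases variance about
  the short channel's fluctuations.
* **Filter**: Hamming-window linear-phase FIR, one edge filter per band
  edge sized by its own transition width (low: 0.005 Hz, high: 0.3 Hz),
  cascaded and applied with group-delay compensation and reflect
  padding (zero phase, single pass).  Contract: ≤ 1 dB loss at 0.05 Hz,
  ≥ 20 dB attenuation at 1 Hz at the 3 Hz analysis rate.
* **Detrending bias**: a linear fit over a −3…14 s epoch removes part of
  a response that occupies most of the window, so detrended averaging
  under-reads absolute amplitudes (roughly half for this response
  shape).  This mirrors the known amplitude gap between averaging and
  GLM estimates; `epoch(detrend=False)` and a pre-stimulus baseline
  option are available, and identity checks use them.
* The 5–7 s window mean is taken on the ROI waveform; for unweighted
  means the order (average channels then window, or vice versa) is
  immaterial.

## GLM pipeline

Designs contain per-condition regressors (canonical: boxcar of the
stimulus duration — or an override — convolved with the double-gamma HRF
with standard constants 6/16 s delays, unit dispersions, undershoot
ratio 1/6, 32 s support, peak-normalised per isolated event; FIR: one
one-second stick per integer delay 0–13 s), a DCT-II cosine drift set
with frequencies k/(2T) ≤ 0.01 Hz, a constant, and optional
short-channel nuisance columns (per-chroma mean; individual channels;
or left singular vectors of the centred short-channel matrix — a subset
or all).  Derivative terms are intentionally not offered.

Fitting per channel row: OLS → Yule–Walker ("adjusted") AR(4) on the
residuals → filter data and design by `1 − Σ aᵢ z⁻ⁱ` (dropping the
warm-up samples) → OLS refit; SEs from the whitened normal equations
with dof = whitened samples − regressors; two-sided t p-values, with a
one-sided ("greater") mode available for directional detection.  A
single whitening pass is the default; `iterate=True` repeats it once.
ROI pooling uses inverse-SE weights (`1/SE²` optional), pooled SE
`√(Σwᵢ²SEᵢ²)/Σwᵢ`, normal-approximation p.  FIR truncation at 14 s of a
~37 s response leaks the unmodelled tail into the constant, shifting the
deconvolved curve by a small DC (~2% of peak in the noiseless check);
curve-shape comparisons are made offset-free.

## Detection evaluation

Each (subject, STG channel or pooled ROI, condition, chroma) contributes
one p-value.  Silence rows are negatives, speech and noise rows
positives (per-condition filtering available).  FPR(θ) and TPR(θ) are
class fractions with p < θ over all distinct thresholds; AUC by
trapezoid — equal to the tie-corrected Mann–Whitney statistic — and
TPR@5%FPR by linear interpolation (step convention available).  Sweep
drivers re-run the canonical pipeline per nuisance method, sample rate,
or boxcar duration; the paper-style operating point is 0.6 Hz, all
short-channel PCs, 3 s boxcar.  Amplitude-recovery analyses instead use
boxcar = stimulus duration, since a 3 s boxcar deliberately mismatches
the 5 s response shape.

## Group inference

Estimate tables (subject, ROI, condition, chroma, μM) from either
pipeline enter the same models: a no-intercept cell-means model
(condition × ROI × chroma fixed effects, subject random intercept), the
speech − noise contrast over bilateral STG, and the left − right STG
contrast within speech, fitted per chromophore by REML via statsmodels
MixedLM with Wald tests.  When the random-intercept variance collapses
to ~0 the fit falls back to OLS with a warning (the two coincide in that
limit).  Concordance between sources (averaging vs GLM variants) is
flagged on sign and significance at α = 0.05; no multiple-testing
correction is applied, a reporting convention that is a known
limitation.

## Spectral QC

Welch periodograms (Hann, segment ≈ 1/0.01 Hz) of raw data, the
boxcar ⊛ HRF expected-response spectrum (power concentrates near
0.05 Hz, the average presentation rate), and the filter magnitude
response from its taps.  Flags: expected-response peak attenuated by
> 3 dB, cardiac peak attenuated by < 20 dB, or no cardiac peak found.

## Verification strategy and problem sizes

Unit oracles are independent of the code paths they check: hand-solved
2×2 Beer–Lambert systems, pooled-beta arithmetic (8/3), brute-force
Mann–Whitney AUC, MNE as a third-party oracle for optical density and
TDDR, and property tests (ISI bounds per seed, rejection monotonicity,
permutation invariance, ROC monotone-transform invariance).  End-to-end
checks run at the study scale chosen for a single-CPU workstation:
17-subject cohorts with 20 replicates for contrast power, 2000
channel-fits for null calibration (AR(4) coefficients 0.4/0.2/0.1/0.05),
10-subject cohorts for the nuisance/boxcar sweeps (the "strong systemic"
cohort raises the Mayer amplitude to 6 μM and drift to 0.15 μM/√sample),
200 channels for SCI discrimination, and a 24-permutation label-null
AUC.  The SCI cohort's cardiac-bearing channels use AR(1) φ = 0.9 (same
stationary σ): physiological hemodynamic noise is low-frequency
dominated, leaving the cardiac band to the pulse — the regime (band
SNR ≳ 5) in which the coupling index is defined; with near-white noise
the cross-wavelength correlation floor (~0.81, the angle between the
extinction rows) sits on the 0.8 threshold and the index measures the
noise model rather than coupling.

## Known limitations

* Simulator realism as listed above; in particular, detection at the
  default conditions is near ceiling for corrected methods, so sweep
  comparisons are orderings, not effect-size estimates of real data.
* The canonical-HRF constants, TDDR constants, cosine drift basis and
  Yule–Walker estimator are fixed conventions; alternates (e.g. other
  AR orders, other HRF families) are out of scope.
* Wavelengths and extinction values are configurable defaults; absolute
  μM values are only comparable across analyses sharing them.
* MixedLM Wald p-values treat the condition effect as fixed across
  subjects; per-subject gain heterogeneity makes them anti-conservative
  for very small within-subject noise (random slopes are not modelled).
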