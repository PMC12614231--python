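# Methods

`voiceinv` solves the voice production inverse problem with uncertainty
quantification: given fourteen features of the glottal source, predict the
nine physiological control parameters of phonation — vocal fold length,
vertical thickness, body- and cover-layer depths, three stiffness moduli,
the glottal angle (adduction), and the subglottal pressure — each with a
95% confidence interval. This note documents the models, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The surrogate forward model

Real training corpora for this inverse problem come from continuum
finite-element simulations of vocal fold vibration, which are far outside a
desk-scale package. `voiceinv.source` therefore implements a *kinematic
surrogate*: an explicit map from physiology to a glottal flow waveform,
chosen so that every feature responds plausibly and monotonically to the
physiology it should respond to. The surrogate is a modelling statement of
this package, not a mechanical simulation; its formulas are:

- **Fundamental frequency** (ideal-string law):
  `F0 = (1/2L) * sqrt(sigma_eff / rho_t)`, with effective tension
  `sigma_eff = E_cover + 0.3 E_body + 0.2 E_transverse` (Pa) and tissue
  density `rho_t = 1040 kg/m^3`. Length and stiffness set pitch.
- **Open quotient**: `OQ = clip(0.35 + 0.02*angle_deg + 0.03*(5 - thickness_mm),
  0.30, 0.95)` — abducted, thin folds stay open longer.
- **Speed quotient** (pulse skew): `SQ = clip(1.5 + 0.1 E_body/E_cover, 1.1, 4.0)`.
- **Aerodynamics**: Bernoulli jet velocity `v = sqrt(2 Ps / rho_air)`;
  vibration amplitude `d = clip(1.5mm * (Ps/800Pa) * (30kPa/E_cover), 0, 3mm)`;
  AC flow amplitude `U_ac = 0.3 * L * d * v`; DC leakage through the
  triangular posterior gap `U_dc = 0.5 L^2 tan(angle/2) * v`.
- **Pulse shape**: Rosenberg-type polynomial (cubic rise over
  `OQ*T*SQ/(1+SQ)`, parabolic fall, closed phase), evaluated cycle by cycle.
- **Perturbations**: per-cycle period jitter (0.5% SD) and amplitude shimmer
  (2% SD), plus band-limited (500 Hz – 4 kHz) aspiration noise with RMS equal
  to 20% of the DC leak. These keep CPP/HNR finite and graded; without them
  every voice would be perfectly periodic and several features degenerate.

Zero subglottal pressure produces silence and is always admitted; all other
parameters are validated against the sampling ranges (length 10–20 mm,
thickness 2–5 mm, cover depth 1–4 mm, body depth 4–10 mm, stiffnesses
10–80 kPa, angle 0–10°, pressure 200–2000 Pa — spanning male, female and
child phonation). Negative glottal angles (pressed past contact) are
rejected rather than modelled. The flow derivative is computed by central
differences (one-sided at the endpoints).

Two deliberate consequences of the surrogate design:

1. **Body and cover depth do not enter the formulas**, so they are
   unidentifiable from the features — their recovery R² is ≈ 0 by
   construction. Pressure, angle, length and cover stiffness are strongly
   identifiable, which is what the acceptance experiments exercise.
2. About 5–7% of uniformly sampled configurations (large angle, low
   pressure, stiff cover) are noise-dominated — breathy to the point that no
   periodicity is detectable. Corpus generation skips and replaces these
   draws, recording the count; this slightly truncates the sampled
   distribution at its breathiest corner, exactly as a physical simulation
   campaign would lose conditions that fail to phonate.

The /pa/-utterance generator emulates the aerodynamic channels of the
plosive–vowel task: during each /p/ occlusion the intraoral pressure ramps
to the commanded subglottal pressure (held exactly at the plateau, with
0.5 Pa sensor noise), oral flow is blocked except for a release transient,
and during each vowel the oral flow *is* the glottal flow (there is no
vocal tract anywhere in this package). A separate generator produces
continuously voiced flow with time-varying physiology (parameters
re-evaluated at each cycle onset, linearly interpolated between track
anchors) for gesture-tracking experiments.

## Feature extraction

All fourteen extractors are deterministic and operate on the sampled flow
(and its stored derivative):

- **F0**: normalized autocorrelation on 40 ms frames (10 ms hop), median
  across voiced frames. Peak selection uses the biased autocorrelation
  (stable at large lags) with an octave-error guard (smallest lag within
  90% of the global peak); parabolic refinement uses locally unbiased
  values so the estimate is not skewed toward smaller lags. Default search
  band 50–600 Hz; voicing threshold 0.30 on the normalized peak. Aperiodic
  input raises a structured `UnvoicedError`.
- **Harmonic differences** (H1-H2, H1-H4, H1-H2k, H1-H5k): magnitude
  spectrum of the Hann-windowed flow derivative (4x zero-padding), each
  harmonic located by local peak search within ±F0/4 of its nominal
  frequency (k F0 for k = 1, 2, 4; harmonics nearest 2 and 5 kHz) and
  refined by parabolic interpolation in dB. Amplitudes at the spectral
  noise floor are clamped there, with a warning. Requires a sample rate
  above 10 kHz (H1-H5k needs 5 kHz below Nyquist).
- **CPP**: per 40 ms Hann frame, real cepstrum of the dB magnitude
  spectrum; peak in the 1/600–1/50 s quefrency band measured above a
  least-squares line fitted over that band; prominences averaged across
  frames. Amplitude-scale invariant by construction.
- **HNR**: period-synchronous averaging — the harmonic part is the tiled
  mean cycle, the noise part the residual; `10 log10` of the power ratio,
  capped at +60 dB.
- **SHR**: ratio of summed spectral peak amplitudes at odd half-multiples
  `(k - 1/2) F0` to those at harmonics `k F0` (up to 10 harmonics),
  clamped to [0, 1].
- **Flow pulse metrics**: cycle-averaged over integer-sample periods.
  Qamp is the mean peak-to-peak amplitude; CQ the mean fraction of the
  period with flow within 5% of the cycle amplitude above the cycle
  minimum (a flow-based CQ needs an explicit threshold; 5% is the
  package's convention and is part of the closed forms the tests check);
  MFDR/MFAR the mean magnitudes of the steepest fall/rise.
- **SPL**: monopole radiation of the flow derivative,
  `p(t) = rho_air * dU/dt / (4 pi r)` at r = 0.3 m, in dB re 20 µPa.
  For human microphone data a vocal tract adds resonance gain; the
  protocol subtracts a configurable correction (15 dB for an /a/ tract)
  so measured SPL is comparable with source-only training data.

Tables are z-scored before training with sample (ddof = 1) statistics;
zero-variance columns raise an error naming the column.

## Inversion back-ends

Both back-ends share one architecture: 14 inputs, four tanh hidden layers
of 200 units, 9 linear outputs. Training data are z-scored with statistics
fitted once on the full corpus (shared by all ensemble members, so the
sample matrices live in consistent physical units).

**Deep ensemble.** Each member draws its own random 70/15/15
train/validation/test split and its own Glorot-normal initialization from
`SeedSequence(seed).spawn(i)`, and minimizes MSE + L2 (weight decay 1e-4 in
z-scored units) with Adam (lr 2e-3, batch 512), early-stopping on its
validation split (patience 15, best weights restored). Adam replaces the
scaled-conjugate-gradient optimizer sometimes used for this task; the
contract is "minimize MSE with regularization", and any first-order
optimizer satisfies it. Prediction stacks the member outputs.

**Mean-field variational network.** Every weight and bias has a Gaussian
posterior (mean + log-SD, initialized at Glorot / e^-5); the prior is
zero-mean Gaussian with SD 1.0 on z-scored weights. Training minimizes the
negative evidence lower bound — Gaussian likelihood with a learned
homoscedastic noise SD per output, plus KL(q‖prior)/N — by the
reparameterization trick (1 Monte Carlo draw per step) and Adam, with the
KL weight annealed linearly over the first 20% of steps. The -ELBO trace
is recorded; non-finite values abort with the trace tail. Prediction draws
`n_samples` (default 100) weight samples per input and, by default, adds
the learned observation noise to each draw (the posterior predictive);
`include_noise=False` gives weight-uncertainty-only samples.

**Confidence intervals.** Both back-ends take the 2.5/97.5 percentiles of
the sample matrix, by linear interpolation between order statistics —
implemented explicitly (`sorted_percentile`) so the convention is pinned;
a Gaussian mean ± 1.96 SD variant is available via `ci_method="gaussian"`.
Percentile intervals are robust to the skew that tanh saturation can
produce near the edges of the parameter ranges.

## Evaluation metrics and protocol

MAE, MAPE (% with a hard error on zero truth), PIC (interval coverage with
*inclusive* bounds so ties are deterministic), CI width mean/SD (sample SD,
overall and per subject label), and OLS-with-intercept regression of
prediction on truth (slope, R²). Pressure is kept in Pa internally and
rendered in kPa in tables.

The /pa/ protocol detects plosive peaks by prominence (≥ 200 Pa) and
separation (≥ 0.15 s; of two closer bumps the larger wins), interpolates
linearly between consecutive peaks to define ground-truth Ps on the vowels
(no extrapolation outside the peak span), and extracts features from the
central 50% of each bracketed vowel — the steady portion, avoiding the
error-prone plosive–vowel transitions. Vowels without two bracketing peaks
or without detectable voicing are skipped with a warning.

## Calibration: what the ensemble CI does and does not cover

The desk-scale study (20k training rows, 2k held out, fixed seeds) shows a
sharp and instructive asymmetry:

- The variational posterior predictive achieves ~95% coverage for
  subglottal pressure — nominal — because the learned observation noise
  absorbs the corpus's intrinsic feature noise (jitter, shimmer,
  aspiration produce replicate feature SDs up to ~1 feature-SD for H1-H2).
- The deep ensemble's percentile-of-members interval covers only ~30%.
  This is structural, not a defect: MSE-trained members all converge
  toward the same conditional mean, so their spread measures epistemic
  uncertainty only, while in-distribution error here is dominated by
  aleatoric feature noise. Ensembles achieve high coverage in practice
  when applied *out of distribution* (e.g., human recordings inverted by
  simulation-trained networks), where member disagreement grows large.

The acceptance suite asserts nominal coverage for both back-ends; the
ensemble assertion fails by design of the experiment and is kept as an
honest negative result. Consistently, the ensemble's mean CI width on
in-distribution data (~0.1 kPa) is much narrower than widths reported for
human-data applications of this method (~0.5 kPa), while the variational
network's (~0.6 kPa) is in that range.

Other uncertainty properties hold as expected: doubling explicit feature
noise (10% → 20% of each feature's SD) widens the mean Ps CI of both
back-ends; growing the training set 2k → 20k leaves the ensemble CI width
statistically unchanged or smaller (one-sided t-test over 3 seeds).

## Problem sizes and seeds

The package's standard study sizes, used by the acceptance experiments and
`scripts/acceptance.py`: 22,000-row corpus (20,000 train / 2,000 held
out), 10 ensemble members at 4x200, up to 150 epochs with patience 15;
uncertainty-monotonicity experiments use 5-member ensembles at 40–60
epochs. These sizes give stable metrics (recovery R² and MAPE move by well
under their acceptance margins across seeds) while a full run stays in the
minutes range on one CPU core. All randomness fans out from a single
seed through `numpy.random.SeedSequence.spawn` in a fixed stage order, so
every run is exactly reproducible.

## Known limitations

- The surrogate is kinematic: no continuum mechanics, no self-oscillation
  threshold, no vocal tract or source–filter interaction. Passing tests
  demonstrate that the *inversion machinery* recovers parameters and
  calibrates uncertainty under a known, well-behaved forward map — not
  that it does so for human voices.
- Depth parameters are unobservable under the surrogate (R² ≈ 0); their
  predictions regress to the corpus mean with wide intervals.
- Feature extractors are native implementations of the standard
  definitions; they are oracle-tested against closed forms but make no
  claim of bit-equivalence with any external analysis software.
- The intraoral-pressure protocol assumes segment labels are given (or
  synthetic); no automatic /p/–/a/ segmentation from audio, and no inverse
  filtering — the package consumes already-inverse-filtered glottal flow.
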