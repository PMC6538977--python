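# Methods

This note documents the models, estimators and design choices behind
`neodepth`, the assumptions they rest on, and what the synthetic-data
tests do and do not establish about real recordings.

## Synthetic session models

### Discontinuous neonatal LFP

A session is the sum of an aperiodic background and transient active
periods.

**Background.** Gaussian noise shaped in the frequency domain to
P(f) ∝ f^exponent (default exponent −2), with the spectrum held flat
below 1 Hz to emulate the hardware high-pass of physiological amplifiers
— without it, steep spectra are dominated by drift and carry almost no
power in the 1–100 Hz analysis band. The overall scale is `noise_sd_uv`
(default 10 µV).

**Active periods.** Initiation times follow a thinned Poisson process.
Candidates are drawn at a dead-time-compensated rate
r / (1 − r·d·D), where r is `burst_rate_hz` (default 0.12 Hz), d the dose
factor and D the mean event duration plus a 300-ms refractory guard, and
are accepted with probability proportional to d; this makes the realized
initiation rate exactly r·d and the baseline occupancy r·E[duration]
(≈ 50% with the defaults, matching the roughly half-active structure of
neonatal cortical activity). Durations are normal (mean 4 s, SD 1.5 s)
truncated at 2 s. Each event is a weighted mixture of band-limited noise
in the four canonical bands (power weights δ:θα:β:γ = 1:0.8:0.25:0.1 by
default), tapered with 100-ms cosine ramps so bursts wax and wane, and
scaled to a log-normal SNR (mean 5, log-SD 0.25) **relative to the
background's RMS in the 1–100 Hz detection band** — so "SNR ≥ 3" has a
direct meaning for the RMS detector.

**Dose law.** `dose_response` maps concentration to an occurrence factor
in [0, 1], equal to 1 at concentration 0 and nonincreasing. Nothing else
depends on dose: the within-burst band mix, amplitude law and firing are
identical at every level. This encodes the central empirical structure —
anesthesia suppresses how often the neonatal brain is active, not what
the activity looks like when it occurs.

**Spikes.** Within each burst, spike counts are Poisson
(`spike_rate_hz`, default 10 Hz) and spike times are placed where the
Hilbert phase of the burst's lock-band component (default θ–α, 4–12 Hz)
matches target phases drawn from a von Mises distribution with
concentration `spike_lock_kappa` (default 2). A biphasic ~1.2-ms kernel
(30 µV peak) is added at each spike so the 500–5000 Hz band carries
detectable multi-unit events when the sampling rate allows it.

### Continuous juvenile LFP

The burst process is disabled; each canonical band is a continuous
band-noise component whose natural-log power is offset by
`band_dose_slopes[band] × concentration`. Positive delta and negative
beta/gamma slopes reproduce the adult-like spectral shift. Doubling a
slope doubles the log-power offset, which the tests exploit as an oracle.

### Infant scalp EEG

Channels share band-limited sources (1–50 Hz in ten 5-Hz bands, band
power falling as 1/f²) with per-channel topographic gains drawn from
U(0.5, 1.5), plus independent sensor noise (3 µV). The per-channel gains
matter: a perfectly common source would be annihilated by common-average
referencing. Broadband amplitude is modulated by
(1 + `amplitude_dose_slope` × concentration); each band additionally by
its own log-power slope. Age-group defaults encode the developmental
switch: −0.4 per unit concentration at 0–2 months (broadband
suppression), +0.4 at 4–6 months, and a weak broadband slope (+0.1) with
frequency-specific band slopes (low bands up, high bands down) at 2–4
months. Concentration is a dimensionless fraction of an age-adjusted
reference; the pipeline is unit-agnostic.

Artifacts are injected on the 5-s epoch grid and recorded in ground
truth: digitizer-rail saturation runs (rail 3276.8 µV ≙ 16-bit at
0.1 µV/LSB), 300-µV transients, and 2-s segments in which all channels
are scaled ×8 (high cross-channel median). A generated subject must
retain at least 20 artifact-free minutes, mirroring the inclusion rule.

**What the generators do not emulate:** volume conduction with realistic
head geometry, respiration/cardiac artifacts, non-stationary sleep-state
structure, anesthetic pharmacokinetics beyond stepwise concentration
profiles, or inter-subject variability beyond seed-to-seed sampling.
Passing the recovery tests therefore shows that the estimators invert the
stated generative laws at realistic SNR — not that the model will reach
the same accuracy on clinical data.

## Detection

**MUA.** Local minima of the 500–5000 Hz signal below −5 × SD (SD over
the full trace) whose topographic prominence on the inverted trace
exceeds half the peak. Implemented with `scipy.signal.find_peaks`; a
brute-force O(n²) prominence scan in the test suite pins the semantics.

**Active periods.** The 1–100 Hz signal's RMS is computed in 200-ms
windows at 50% overlap (the window resolves 1-s minimum events with ≥ 8
points; the paper-family algorithm leaves this free). The RMS histogram
(100 bins from 0 to the maximum) is fitted with a Gaussian by least
squares using only bins up to and including the modal bin — the noise
floor of a discontinuous trace — and the threshold is µ + 3.5 σ.
Supra-threshold runs (strict >) become candidate events; gaps < 200 ms
merge; events must last strictly more than 1 s. Event amplitude is the
maximum absolute deflection of the band-filtered trace (the raw trace
would mix in out-of-band drift). On slowly modulated 1/f backgrounds the
detector produces occasional short false events just above threshold;
this is inherent to the variance-threshold family and is why evaluation
uses recall and temporal Jaccard against ground truth rather than raw
counts.

## Metrics

* **Welch PSD**: periodograms of non-overlapping 1-s Hann windows are
  averaged (1-Hz resolution). For within-event spectra, only complete 1-s
  windows inside events are used.
* **Band power**: trapezoid integral of the PSD over the band's closed
  frequency interval on the 1-Hz grid.
* **Imaginary coherence**: |Im(Sxy/√(Sxx·Syy))| with 1-s Hann segments at
  50% overlap — the PSD operation's non-overlap rule is specific to power
  estimation; coherence uses the standard bias/variance tradeoff.
* **PPC**: phases from the Hilbert transform of the zero-phase
  band-filtered field at spike times; the pairwise mean cosine is
  computed in closed form, ((Σcos)² + (Σsin)² − n)/(n(n−1)), whose
  expectation is the squared mean resultant length (I₁(κ)/I₀(κ))² for von
  Mises phases — the test oracle.
* **1/f slope**: iteratively reweighted (Tukey bisquare) linear fit of
  log₁₀ power on log₁₀ frequency over 20–40 Hz, per 1-min bin; matches
  the robust-regression convention of the source analyses. Nonpositive
  powers are dropped; fewer than 3 surviving points yields a missing
  estimate.
* **Sample entropy**: −ln(A/B) with m = 2, Chebyshev distance, tolerance
  0.2 × SD of the analyzed window, lag 1, self-matches excluded, and the
  same n − m templates for both lengths. For band-resolved entropy the
  signal is filtered into 2-Hz bands (4th-order zero-phase band-pass,
  grid anchored at 1 Hz) and decimated to 200 Hz so a 1.5-s window keeps
  300 samples (the estimator needs ≥ 50).

## Artifact rejection

Epochs are 5 s, anchored at t = 0; a partial trailing epoch is scored
only if at least half is present. The three rules: any sample > 150 µV on
a retained channel; ≥ 3 consecutive samples at the digitizer rail; and —
operationalizing the cross-channel median criterion — the per-sample
median across retained channels of the 1-s amplitude envelope exceeding
30 µV anywhere in the epoch. A minute is removed when contaminated time
strictly exceeds 10 s (two bad epochs keep the minute, three remove it).
Channel screening, done visually in clinical practice, is automated as a
variance rule: channels below 1% or above 100× the cross-channel median
variance are excluded.

## Features

Minute labels: for mice, the nominal delivered concentration of the
15-min block covering the minute midpoint; for infants, the mean of the
1-Hz concentration samples within the minute. Mouse tables have exactly
30 feature columns (15 × {PFC, HP}), infant tables exactly 55 (5 × 11
signals). Mouse amplitude features use the 1-s envelope (consistent with
the human features; the alternative raw-trace reading differs only by a
scale factor under the baseline normalization). Amplitude-quartile
classes are half-open [q₍ₖ₋₁₎, qₖ) with the top class closed, so the four
percentages always sum to 100. Normalization divides every feature column
by its median over baseline minutes — concentration-0 minutes, falling
back to the lowest-concentration minutes, with a manual override for
recordings started after induction; columns whose baseline median is 0
are left unscaled and the constant recorded. Normalization makes the
table invariant to overall signal scale.

## Depth model

The pipeline is QuantileTransformer → SelectPercentile (mutual
information, fixed `random_state` for determinism) → RBF SVC/SVR. The
classifier discriminates anesthetized (concentration > 0) from awake
minutes; its *prediction* is appended to the regressor's input (the
phrase "classifier input fed to the regressor" is read as the
classifier's output — feeding the input features twice would be a
no-op). During training the regressor receives the classifier's
*cross-validated* predictions on the training rows, so it never sees a
classifier output computed on its own training fold; at test time it
receives the refitted classifier's predictions.

Evaluation: `n_iterations` outer splits into training 2/3 and held-out
1/3 (row-level by default, mirroring the source procedure; a
group-by-subject mode is available and recommended when subject identity
must not leak). All hyper-parameters are re-tuned per iteration by 3-fold
grid search on the training rows. Degenerate splits (single class in
training) are redrawn with the next seed and logged. Metrics are pooled
over the concatenated held-out predictions: R² and median absolute
error.

Grids (the source gives none): n_quantiles ∈ {10, 100, 1000} (capped at
the inner-fold training size), percentile ∈ {25, 50, 75, 100},
C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01, 0.1, 1}, ε ∈ {0.01, 0.1, 0.5}.
`fast_grid()` is a reduced grid (n_quantiles 100, percentile {50, 100},
C {1, 10}, γ scale, ε 0.1) for cohort-scale recovery runs. One master
seed fans out per-iteration split seeds.

Age stratification: three independent regressors with cutoffs at 2 and
4 months, or a single model with `age_months` appended as a feature. The
decision-space map embeds feature rows with t-SNE (PCA initialization, so
duplicate rows stay coincident; perplexity min(30, (n−1)/3)) and colors
the plane by 1-nearest-neighbor regression on the predicted depth — a
Voronoi tessellation of the embedding.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the
whole suite completes in minutes on one CPU while keeping every rate and
effect size at its study value: mouse cohorts of 8 pups × 60 min at
1 kHz (ladder 0/1/2/3%, 15 min per level, occurrence factors
1/0.6/0.3/0.1), MUA segments at 20 kHz, infant cohorts of 12 subjects
(4 per age group) × 30 min × 8 channels at 256 Hz. The 256-Hz synthetic
EEG rate (clinical systems record at 1024 Hz) comfortably supports the
1–50 Hz feature band; model runs use the reduced grid with 10–20 outer
iterations.

## Known limitations

* The detector's temporal resolution is the RMS hop (100 ms); event
  boundaries inherit that granularity.
* Row-level resampling lets minutes of one subject appear in both train
  and test sets; with strong per-subject normalization this is mild on
  synthetic cohorts but group-level splitting should be preferred for
  real data.
* The infant generator's linear amplitude–concentration law is a
  deliberate simplification; saturation and hysteresis (induction vs
  emergence) are not modeled.
* Sample-entropy band analysis assumes the 2-Hz band grid starts at 1 Hz;
  the alternative 0-Hz anchor shifts band identities by 1 Hz.
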