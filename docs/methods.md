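# Methods

This note documents the models, algorithms and design choices behind
`vigispec`, in the order the pipeline runs them.

## Aperiodic model and spectral parameterization

The power spectrum of one channel in one vigilance state is modelled in
log10 space as an aperiodic component plus Gaussian oscillatory peaks:

    log10 P(f) = b − χ·log10 f + Σ_k h_k · exp(−(f − c_k)² / (2 s_k²))

over 1–65 Hz.  χ (dimensionless) is the aperiodic exponent, b the
offset in log10(µV²/Hz).  The model is *fixed* (no knee): a single
power law across the band.  Fitting proceeds in six steps:

1. straight-line least squares of log power on log frequency;
2. robust refit: residuals are clipped at zero, and only points whose
   clipped residual is at or below its 2.5th percentile are refitted —
   this drops points sitting on oscillatory bumps;
3. the spectrum is flattened (log power minus aperiodic fit);
4. peaks are extracted iteratively: take the flattened maximum, stop if
   it is below `peak_threshold_sd` (default 2.0) times the SD of the
   current flattened spectrum, otherwise seed a Gaussian there (height
   = the maximum; SD from the half-height extent, clipped to the FWHM
   limits, default 0.5–12 Hz), subtract it and repeat, at most
   `max_peaks` (default 6) times;
5. all Gaussians are refitted jointly by bounded nonlinear least
   squares (centers constrained to ±2 SD of their seed, SDs to the
   width limits; parameter tolerance 1e-8).  If the joint refit fails
   to converge the iterative estimates are kept and the results object
   is marked `converged=False`;
6. the fitted peaks are subtracted from the original log spectrum and
   the aperiodic component refitted on the remainder.

R² and MAE are computed on the log10 spectrum against the full model.
On a noiseless power law the fit is exact and no peaks are found; on a
power law plus one Gaussian peak the exponent moves by < 0.03 while a
naive log–log regression on the same spectrum moves by > 0.05 — peak
removal is the entire point of the parameterization.

The peak-fitting defaults are deliberately conventional for this class
of algorithm and are all configurable; none is dictated by theory.

## Power spectra

* Long, single-condition signals use Welch's method: 2-s Hann windows,
  50% overlap, truncated to 1–65 Hz.
* State-resolved spectra cannot use long windows, because a state's
  epochs are scattered 1-s fragments.  `state_psd` therefore averages
  rectangular-window periodograms of the individual 1-s epochs (1 Hz
  resolution).  A state is skipped below 30 epochs, where the estimator
  variance would dominate the fit.

## Preprocessing

All EEG channels are band-passed 0.5–70 Hz with an order-4 Butterworth
filter applied forward–backward (zero phase, so band-power scoring is
not phase-distorted).  EMG channels are instead high-passed at 10 Hz —
muscle tone lives above the EEG band and a 70-Hz low-pass would discard
most of it.

Artifact rejection follows the amplitude rule: per EEG channel, mean
and SD over the whole recording; any 1-s epoch containing a sample
beyond `threshold_sd` (default 3) SD on any EEG channel is flagged.
Two consequences worth knowing:

* For Gaussian data the per-epoch flag probability is
  1 − (2Φ(k) − 1)^n with n the effective number of independent samples
  per epoch — at 250 Hz and k = 3 this is a baseline flag rate of
  roughly 20–30% even on perfectly clean signals.  The rule is a
  *rejection* heuristic, not a detector with a controlled false-alarm
  rate; accuracy statistics in this package are therefore computed over
  epochs that survive it, and the flag rate itself is validated against
  the closed form.
* The rule is scale-invariant (the mask is unchanged when the signal is
  multiplied by a constant), and a constant channel (SD = 0) is a
  degenerate input and raises.

## Vigilance scoring

Each surviving 1-s epoch is assigned the state of its dominant band,
where dominance means the largest *bandwidth-normalised* band power
(delta 0.2–3 Hz → a1, theta 3.2–6 Hz → a2, alpha 6.2–12 Hz → a3); raw
band power would bias toward the widest band.  Ties break in the fixed
order delta > theta > alpha for determinism.  Multichannel recordings
are scored from band powers averaged over EEG channels.

In mouse mode an epoch with EMG power below threshold becomes `rem`
when theta-dominant and `nrem` when delta-dominant (the three nREM
sub-stages are collapsed into one class; the scoring signal does not
distinguish them).  The EMG threshold defaults to the **geometric
mean** of the epoch EMG powers: muscle tone is bimodal on a log scale
(wake ≫ sleep), and the geometric mean falls in the valley between the
modes regardless of the sleep/wake occupancy ratio.  A median was
considered and rejected — it only separates the modes when occupancy is
near 50/50.

For scoring, band powers are computed by filtering the whole recording
once per band and averaging squared samples per epoch.  The standalone
`epoch_band_powers` (for a single isolated 1-s epoch) instead
integrates periodogram bins: an order-4 filter with a 0.2-Hz edge
cannot settle within 250 samples, so filtering an isolated delta-band
epoch is dominated by its own transient.  The two routes agree for
in-band content and each is validated separately.

## Synthetic data

The generator exists so that every downstream stage can be tested
against planted truth.  What it emulates:

* **Aperiodic background** — spectral shaping: white Gaussian noise is
  FFT'd, the amplitude multiplied by √(fs/2 · 10^b f^(−χ)) with DC
  zeroed, and inverse-FFT'd.  The target one-sided PSD is hit exactly
  in expectation; generation is O(n log n) and a pure function of
  (parameters, seed).
* **State sequence** — a semi-Markov chain: the next state is drawn
  from the occupancy mix excluding the current state, and run lengths
  are geometric with state-specific mean d_s = c/(1 − mix_s), where
  c = dwell · Σ_s mix_s(1 − mix_s).  This construction makes long-run
  occupancy equal the mix *exactly* and the run-averaged dwell equal
  the nominal dwell (default 10 s).  A simpler iid-renewal model cannot
  satisfy both at once.
* **Oscillations** — per-epoch Gaussian-windowed sinusoid bursts with a
  fixed 0.35-s envelope; the requested spectral bandwidth is realised
  by jittering the carrier frequency across epochs.  Tying burst
  duration to bandwidth instead gives short, high-crest transients that
  trip the 3-SD artifact rule on the generator's own oscillations.
* **State presets** — active-state exponents 1.25 (a1), 1.0 (a2),
  0.737 (a3) with REM 1.1 and nREM 1.6 for mice; offsets are chosen per
  state so the 0.5–70 Hz aperiodic band power is equal across states
  (and across planted group shifts).  Without this, flat-exponent
  states carry several-fold more variance and the global 3-SD rule
  flags them preferentially; amplitude-comparable states are also the
  physiologically sensible choice.  Oscillation amplitudes are set so
  each state's defining band clearly dominates (the point of "scorable"
  synthetic data) while burst crests stay below the rejection
  threshold.
* **Artifacts** — biphasic 50–200 ms transients at 8–15 SD, Poisson in
  time at a configurable per-minute rate.
* **Cohorts** — groups with per-state exponent shifts and per-group
  occupancy mixes; each subject gets one shared exponent offset
  (between-subject SD 0.08, matching coefficient-of-variance values of
  0.06–0.10 seen in state-resolved exponent data) applied to all
  states.  The **masking preset** plants a 0.2 exponent gap in every
  state and chooses the two occupancy rows so the occupancy-weighted
  pooled means coincide identically:
  0.2·1.3 + 0.2·1.1 + 0.6·0.8 = 0.6·1.1 + 0.2·0.9 + 0.2·0.6 = 0.96.
  `simulate_exponent_table` is the cohort-scale twin of the signal
  generator: it draws the subject × state exponent table directly
  (subject SD 0.08, measurement SD 0.02, multinomial epoch counts),
  for replicate-heavy power studies where synthesising every signal
  adds nothing.

What the generator does **not** emulate: volume conduction or shared
channel covariance (channels are independent), realistic sleep
architecture beyond dwell-time structure, non-Gaussian background
activity, line noise, or electrode drift.  Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
spectral model, not robustness to every failure mode of real
recordings.

## Statistics

* **Effect estimates** — mean difference of group means with a
  percentile bootstrap CI (resampling with replacement within groups;
  default 5000 resamples).  For m planned comparisons the interval is
  taken at level 1 − α/m (Bonferroni); significance is read from
  whether the adjusted CI excludes zero.  Percentile rather than BCa:
  exactly specifiable and adequate at cohort sizes here.
* **ANOVA** — fixed-effects factorial OLS with all interactions and
  Type II sums of squares (sensible under mild unbalance).  One value
  per subject × state enters the table; a random subject effect is
  deliberately replaced by this subject-level aggregation, which
  preserves the masking logic while avoiding REML machinery.  Exact F
  values from a mixed model would differ.
* **Correlogram** — all-pairs Pearson r with two-sided p-values
  multiplied by the number of pairs and capped at 1.
* **Masking analysis** — the same subject × state table analysed twice.
  State-resolved branch: ANOVA with state as a factor plus per-state
  adjusted effect estimates (m = states × group pairs).  Pooled branch:
  each subject collapsed to an epoch-count-weighted mean exponent,
  then a group ANOVA and an unadjusted effect estimate.  "Masking
  demonstrated" = every within-state CI excludes zero while the pooled
  CI does not.

## Validation experiments and problem sizes

The benchmark experiments in `vigispec.evaluation` (run by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`) use
these sizes, chosen to keep estimator variance well below the margins
being tested:

* exponent recovery: χ ∈ {0.5, 0.737, 1.0, 1.25, 2.0}, 50 signals
  each, 300 s at 250 Hz; success = |χ̂ − χ| ≤ 0.05;
* peak robustness: 25 replicates, alpha-band peaks with height
  0.3–0.8 log10 units and SD 0.8–2 Hz on χ = 1 spectra;
* state ordering: 50 subjects, 360 s each, equal state mix (which
  leaves ≥ 30 epochs per state after baseline flagging), scored blind
  to ground truth;
* scoring accuracy: one 600-s human and one 600-s mouse recording;
  artifact sensitivity from 60 injected 10-SD transients;
* masking: 100 table-level cohort replicates at n = 27 per group
  (matching the cohort scale the masking design emulates);
* bootstrap coverage: 1000 simulations at n = 100 per group and 4000
  resamples — sizes where the percentile interval's asymptotic
  calibration applies; at n ≈ 30 the percentile method is known to
  undercover by about a point, which is a property of the method, not
  of the implementation;
* ANOVA oracle: balanced 2 × 2 design, 8 observations per cell,
  compared term-by-term with textbook sums of squares.

## Known limitations

* The 70-Hz low-pass (order 4, applied twice by zero-phase filtering)
  depresses the top of the 1–65 Hz fit range; state-resolved exponents
  fitted from filtered recordings are biased upward by roughly
  +0.03 to +0.07 depending on the state's spectrum.  The bias is not
  compensated — the pipeline fits what the filtered data show — and it
  cancels in the group and state *differences* that the analyses
  report.  Welch fits of unfiltered signals do not carry it.
* Broad peaks (SD ≳ 2 Hz) near the 1-Hz edge of the fit range are only
  partially removable and can shift χ̂ by more than 0.05; this is a
  shared property of iterative peak-removal parameterizations.
* Human EDF recordings are truncated to the first 15 minutes in human
  mode, matching the resting-state segment convention.
* Epochs rejected by the 3-SD rule are excluded from state PSDs; on
  oscillation-rich states the rule preferentially removes the
  largest-amplitude epochs, slightly attenuating measured peak heights
  (not the aperiodic slope).
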