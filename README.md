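# vigispec

Vigilance-state-resolved analysis of the aperiodic (1/f) component of
EEG/LFP power spectra.

## The problem

The broadband background of an EEG power spectrum falls off roughly as a
power law, `P(f) ∝ f^(−χ)`.  The **aperiodic exponent** χ — the negative
slope of the spectrum in log–log coordinates once oscillatory peaks are
removed — is a candidate readout of cortical excitation/inhibition
balance and is being explored as a biomarker for psychiatric and
neurodegenerative conditions.  But χ also changes strongly with the
brain's **vigilance state** (active wake, theta-dominated wake, quiet
rest, REM, nREM).  If two groups of subjects distribute their time over
states differently, a real within-state group difference in χ can vanish
entirely when each subject is collapsed to a single pooled exponent:
state composition **masks** the effect.

`vigispec` packages the full analysis chain needed to estimate χ in a
state-aware way, for researchers working with rodent LFP or human scalp
EEG:

1. **synth** — synthetic recordings and cohorts with planted aperiodic,
   oscillatory, state and group structure, so every stage can be
   validated against known ground truth;
2. **preprocess** — 0.5–70 Hz order-4 zero-phase Butterworth filtering
   and rejection of 1-s epochs containing samples beyond 3 SD of the
   channel mean;
3. **score** — classification of each 1-s epoch into vigilance states
   from bandwidth-normalised band powers (delta 0.2–3, theta 3.2–6,
   alpha 6.2–12 Hz), with EMG-gated REM/nREM rules for mice;
4. **spectral** — state-resolved PSDs and the spectral-parameterization
   model

   `log10 P(f) = b − χ·log10 f + Σ_k h_k exp(−(f−c_k)²/2s_k²)`

   fitted over 1–65 Hz by iterative Gaussian-peak extraction
   (`SpectralParameterization(...).fit() → SpectralFitResults`);
5. **stats** — estimation statistics (bootstrap mean differences with
   Bonferroni-adjusted CIs), factorial ANOVA, Bonferroni-corrected
   correlograms, age regression, and the pooled-vs-state-resolved
   `MaskingAnalysis`.

Recordings are read from EDF (via `mne`) or a raw float32+JSON fixture
format; all outputs are plain CSV/JSON.  A `vigispec` command-line tool
glues the stages together (`synth`, `preprocess`, `score`, `fit`,
`analyze`, `run`).

## Worked example

Fit the aperiodic exponent of a synthetic 300-s signal with planted
χ = 1.25:

```python
import vigispec as v

x = v.generate_aperiodic_noise(250 * 300, fs=250, exponent=1.25, seed=42)
fit = v.fit_spectral_model(v.welch_psd(x, 250))
print(fit.summary())
```

```
Spectral parameterization (fixed aperiodic mode)
================================================
frequency range   1.00-65.00 Hz (129 points)
offset (b)        -0.0458 log10(uV^2/Hz)
exponent (chi)     1.2235
peaks             6
    ...
R^2                0.9975
MAE (log10)        0.0193
```

The exponent comes back within 0.03 of the planted value; the small
"peaks" are estimator noise absorbed by the peak stage rather than by
the aperiodic slope.

Now the masking phenomenon on a designed cohort: two groups of 27
subjects differ by 0.2 in every state, but the second group spends more
time in high-exponent states, so the occupancy-weighted pooled means
coincide by construction:

```python
table = v.simulate_exponent_table(v.masking_design(n_per_group=27), seed=42)
result = v.masking_analysis(table, seed=42)
print(result.summary())
```

```
State-resolved branch:
ANOVA: exponent ~ group * state * sex
  group                    F(1,150) =  167.798   p = 3.125e-26
  ...
  pt vs hc in a1: -0.183 [-0.241; -0.129]*
  pt vs hc in a2: -0.171 [-0.226; -0.118]*
  pt vs hc in a3: -0.185 [-0.24; -0.131]*

Pooled branch (occupancy-weighted subject exponents):
ANOVA: exponent ~ group * sex
  group                    F(1,50) =    0.972   p = 0.3288
  ...
  pt vs hc (pooled): 0.023 [-0.0248; 0.0675]

group effect within states: significant
group effect after pooling:  not significant
=> pooling across vigilance states masks the group effect
```

Within every state the patient group sits ≈0.18 lower (adjusted 95% CIs
exclude zero, starred); after pooling, the difference is 0.02 and the CI
straddles zero.  Same data, opposite conclusion — the reason vigilance
state must be a factor in aperiodic-exponent analyses.

The same comparison runs end-to-end from signals:

```bash
vigispec synth --preset masking --seed 1 --n-per-group 8 --duration 480 --out cohort/
vigispec run cohort/ --species human --seed 1 --out results/
cat results/masking_report.txt
```

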