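# Methods

## Recording model

All signals live on a 20 kHz grid in microvolts, with epochs starting at
stimulus onset (ABR epoch 0–24.7 ms; FFR epoch 0–127 ms). A recording is

```
mastoid(t) = −neural(t) + pam(t) + noise(t)         (Fpz–M2)
neck(t)    = +neural(t)           + noise(t)        (Fpz–C7)
```

The sign flip of the neural component between references implements the
~180° phase difference seen between mastoid- and neck-referenced sustained
responses; the muscle potential appears only at the mastoid, which is what
makes channel subtraction (mastoid − neck) isolate it.

**Neural component.** For clicks, an ABR template: three positive Gaussian
waves (I/III/V) at 1.5/3.5/5.5 ms with widths 0.25/0.35/0.45 ms and
amplitudes 0.06/0.08/0.12 μV, all scaled by a subject's neural gain. For
pulse trains, the neural FFR is the superposition of that template at every
pulse *plus* a sustained phase-locked steady-state component — harmonics at
F0/2F0/3F0 with amplitude ratios 0.35/1.0/0.60, a 7 ms onset delay, and a
per-subject phase offset (a conduction-delay degree of freedom). The
sustained term is the neural response a single-click recording cannot
predict; without it the convolution model would be trivially perfect on
synthetic data. Its harmonic profile deliberately emphasizes 2F0/3F0, where
the superposed muscle response carries little energy, so the two components
are close to orthogonal for every subject latency and phase — otherwise the
planted music → neural-gain effect washes in and out of FFR rms through
sign-varying interference.

**Muscle component.** The PAM wavelet is a biphasic difference of
Gaussians (positive lobe σ = 1.3 ms; trough 3.2 ms later, σ = 2.0 ms,
relative amplitude 0.8), numerically re-centered so its maximal deflection
falls exactly at the subject's peak latency (drawn uniformly from
12.5–14.5 ms), and normalized so its peak-to-peak amplitude equals the
subject's PAM size times the gaze gain. The wavelet's magnitude spectrum
falls from 100 to 200 Hz, which is the mechanism behind weaker
muscle-driven FFRs at higher stimulus F0s. For pulse-train stimuli the
muscle contribution is the linear superposition of one wavelet per pulse
(`conv(wavelet, pulse train)`), truncated to the FFR epoch with no circular
wrap — the physical process is onset-locked.

**Gaze gain.** `g(θ) = floor + (1 − floor)·(|θ|/70)^γ`, symmetric, equal to
1 at ±70° and to the floor at midline. The neck channel never sees it.

**Noise.** Per-sweep Gaussian noise band-limited to 50–3000 Hz;
`noise_sd` is the standard deviation of the band-limited samples.

## Cohort structure

Per subject: years of musical training from a zero-inflation/Gamma mixture
moment-matched to mean 6.5, sd 7.3 years on [0, 23] (zero mass 0.25);
`log PAM p2p = μ_L + σ_L (a·z + √(1−a²) ε)` clipped to [0.18, 9.7] μV; and
`log neural gain = σ_g (b·z + √(1−b²) ε′) − σ_g²/2`, where `z` is music
standardized by the population constants (6.5, 7.3). `a` and `b` are the
planted standardized paths music → PAM and music → neural gain.

**Between-block muscle state.** Each recording block (stimulus × gaze
condition) draws a mean-one log-normal amplitude factor (`pam_state_sd`)
and a log-normal wavelet-width factor (`pam_shape_sd`) for the reflex.
Tonic muscle tension drifts between blocks, so the PAM expressed during the
click run and during the FFR run of the same subject are correlated but not
identical in size or exact time course. This is load-bearing: with a fully
deterministic reflex the click-measured PAM would predict the FFR almost
perfectly (r > 0.95) and the convolution model would score r ≈ 1, neither
of which resembles real recordings. Within a block the reflex is
deterministic across sweeps (no trial-to-trial jitter).

## Calibrated defaults

The observable cohort statistics are outputs of the whole
recording-and-analysis chain, not generative parameters, so the
`EffectStructure` defaults were fixed once by a seeded coordinate search
over full pipeline runs (`pamffr.calibrate`; final verification on three
disjoint 25-seed sets) and then frozen:

| parameter | value | role |
|---|---|---|
| `a_music_pam` | 0.41 | music → log PAM path |
| `b_music_neural` | 0.56 | music → log neural gain path |
| `gaze_floor` | 0.095 | PAM gain at midline |
| `gaze_exponent` | 1.05 | shape of the gaze curve |
| `snr_neural_pam` | 0.21 | sustained-neural rms vs reference PAM superposition |
| `noise_sd` | 6.2 μV | per-sweep band-limited noise |
| `pam_state_sd` | 0.40 | log-sd of the per-block amplitude state |
| `pam_shape_sd` | 0.30 | log-sd of the per-block width factor |
| `log_pam_mu`, `log_pam_sigma` | 0.56, 0.90 | PAM p2p distribution (μV log scale) |
| `neural_gain_sigma` | 1.40 | spread of neural gain |
| `music_zero_prob` | 0.25 | never-trained mass |

With these defaults, 25-cohort averages land at: measured PAM p2p ≈ 2.4 μV
(0.18–9.7 μV range); PAM–FFR r ≈ 0.7 at maximal gaze; convolution-model
r ≈ 0.71 with mean r² ≈ 0.55; ±70°/0° mastoid rms ratio ≈ 3.2 (neck ≈ 1.0);
row-level partial correlations ≈ 0.47 (PAM | music) and ≈ 0.20
(music | PAM); music–FFR r ≈ 0.33; Sobel z ≈ 2.3–2.7 with a partial
mediation pattern; VIFs < 1.3. A note on r²: the mean of per-subject
squared correlations exceeds the square of the mean correlation by the
variance of r across subjects (≈ 0.04 here), so a cohort with mean r = 0.71
and sd ≈ 0.21 reports mean r² ≈ 0.55, not 0.50.

## Analysis conventions

- Rejection (any sample beyond ±50 μV discards the sweep) is applied to raw
  sweeps, before filtering; the zero-phase filters (2nd-order Butterworth
  band-pass + Q = 30 notch, generous padding for the notch's ~0.16 s ring)
  are applied to the average. Zero-phase filtering keeps latency metrics
  unbiased.
- PAM peak-to-peak is measured on the channel-subtracted click average in
  8–18 ms; FFR rms on 10–110 ms (stimulus duration plus ~10 ms conduction
  delay); FFR onset latency in 6–12 ms; spectra use the rms window with a
  rectangular taper zero-padded to 1 Hz bins.
- Cross-correlation scans lags within ±20 ms and reports the signed maximum
  of the per-lag Pearson correlation on the overlapping segment; the
  convolution model is scored on the 10–110 ms steady-state window so onset
  transients do not dominate.
- The convolution model's default input is the PAM-contaminated mastoid
  click response at maximal gaze (passing the isolated PAM instead gives
  the pure-artifact variant).
- The correlation/regression/mediation battery uses subject × gaze rows for
  the FFR side but the *subject-level* PAM measure (isolated PAM at maximal
  ipsilateral gaze — the condition the artifact is defined in). Rows within
  a subject are not independent; reported degrees of freedom follow the
  naive row count, a deliberate mirroring of common practice that inflates
  nominal significance.
- Gaze effects are tested with orthogonal polynomial contrasts built by
  Gram–Schmidt for the true unequal spacing, reduced to per-subject scores
  and a one-sample t (df = n − 1), replacing mixed-model machinery.
- VIFs are computed on the main-effects design (intercept, music, PAM);
  the interaction model's nested F compares against the music-only model.
- Mediation: OLS paths (`a` from M ~ X; `b`, `c′` from Y ~ X + M; `c` from
  Y ~ X; the identity c = c′ + a·b is asserted internally), Sobel
  z = a·b / √(b²SE_a² + a²SE_b²) with a normal reference, and a
  case-resampling percentile bootstrap CI for a·b. Partial mediation =
  indirect effect significant while the direct path survives.

## Scale of the shipped computations

Full-size runs synthesize each 2000-sweep ensemble average directly as
signal + band-limited noise of sd `noise_sd/√2000`. This is
distributionally identical to averaging individually synthesized clean
sweeps, because at 6.2 μV the ±50 μV criterion sits at ~8σ and essentially
never rejects a clean sweep; sweep matrices and the rejection path are
exercised explicitly at small n in the tests. The headline numbers are
averages over 25 cohorts of n = 20; single-cohort statistics are noisy
(per-cohort Sobel z has sd ≈ 2 and can flip sign when a sampled cohort
happens to contain few trained musicians).

## Known limitations

- Background EEG is white-in-band Gaussian: no 1/f spectrum, alpha, or
  state drift; no eye-tracking or attention/sleep modulation.
- The per-block muscle state is the only source of PAM non-stationarity;
  habituation and within-block fatigue are not modeled.
- The percentile bootstrap CI for the indirect effect is calibrated at
  nominal 95% for well-behaved exposures at n = 20, but drops to ~91% when
  the exposure is the zero-inflated, right-skewed music distribution, and
  collapses entirely (~54%) if mediation is run on pooled subject × gaze
  rows where exposure and mediator repeat within subject. The package
  therefore mediates on the subject-level aggregated table; both figures
  are asserted in the test suite.
- Passing tests show the pipeline recovers structure the generator planted;
  they cannot certify behavior on real EEG with non-Gaussian artifacts,
  electrode drift, or genuinely nonlinear muscle dynamics.
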