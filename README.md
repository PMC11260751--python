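# pamffr

Synthetic evoked-potential cohorts and an analysis pipeline for quantifying
how much of the auditory **frequency-following response (FFR)** can be
explained by the **postauricular muscle (PAM)** startle reflex — a myogenic
artifact, not a brain response.

## The problem

The FFR is a scalp-recorded potential phase-locked to the periodicity of a
sound (e.g., a 100 Hz click train), widely used as a biomarker of auditory
neuroplasticity. Most studies record it with a reference electrode on the
mastoid — centimeters from the PAM, a vestigial pinna muscle that twitches
reflexively ~12–15 ms after every transient sound. Because PAM motor units
follow stimulation rates up to ~200 Hz, a periodic stimulus elicits a train
of overlapping muscle twitches that is itself periodic at the stimulus F0
and masquerades as a neural FFR. The size of the reflex scales with lateral
eye gaze, varies ~50-fold between listeners, and is larger in musically
trained listeners — so it can imitate "experience-dependent plasticity".

`pamffr` packages this confound as a testable pipeline:

- **`stimgen`** — click and periodic pulse-train stimuli,
  `h(t) = Σₙ δ(t − nT)` with `T = 1/F0`, convolved with a 100 μs click;
- **`cohort`** — a seeded generator of two-channel (mastoid `Fpz–M2` and
  neck `Fpz–C7`) ABR/FFR recordings for cohorts of listeners, with planted
  effect structure: log-normal PAM amplitudes (0.18–9.7 μV), gaze-gain
  `g(θ) = floor + (1−floor)(|θ|/70)^γ`, and standardized paths
  music → PAM (`a`) and music → neural gain (`b`);
- **`preprocess`** — zero-phase 50–3000 Hz band-pass + 60 Hz notch, ±50 μV
  sweep rejection, ensemble averaging, and PAM isolation by channel
  subtraction (mastoid − neck);
- **`metrics`** — PAM peak-to-peak (8–18 ms), FFR rms (10–110 ms), onset
  latencies, spectral amplitudes, normalized cross-correlation (±20 ms lag);
- **`conv_model`** — the superposition model: convolve a subject's
  PAM-contaminated click response with the stimulus pulse train to *derive*
  an FFR, and score it against the measured FFR
  (`FFR_deriv(t) = (ABR/PAM ∗ h)(t)`);
- **`stats`** — square-root transform, orthogonal polynomial gaze contrasts
  for the unequally spaced azimuths (−70°, −35°, 0°, +35°, +70°), Pearson
  and partial correlations, OLS regression `FFR_rms ~ music * PAM` with
  variance-inflation factors, and bootstrap Sobel mediation of the
  music → PAM → FFR path.

## Worked example

```python
from pamffr.pipeline import analyze_cohort

res = analyze_cohort(seed=1)   # n = 20 subjects, 2000-sweep averages
print(f"cohort-mean isolated PAM p2p (gaze 5): {res['mean_pam_p2p_g5']:.2f} uV")
print(f"PAM-FFR coupling at hard-right gaze:   r = {res['r_pam_ffr_g5']:.2f}")
print(f"convolution model fit:                 r = {res['model_mean_r']:.2f}, "
      f"R2 = {100*res['model_mean_r2']:.1f}%")
print(f"gaze amplification (mastoid / C7):     "
      f"{res['ratio_mastoid']:.2f}x / {res['ratio_c7']:.2f}x")
print(f"mediation (music -> PAM -> FFR):       Sobel z = {res['sobel_z']:.2f}, "
      f"p = {res['sobel_p']:.3f} ({res['mediation_label']})")
```

prints

```
cohort-mean isolated PAM p2p (gaze 5): 2.08 uV
PAM-FFR coupling at hard-right gaze:   r = 0.48
convolution model fit:                 r = 0.70, R2 = 53.6%
gaze amplification (mastoid / C7):     3.38x / 0.99x
mediation (music -> PAM -> FFR):       Sobel z = 2.71, p = 0.007 (partial)
```

Reading: on this cohort the isolated muscle reflex averages ~2 μV
peak-to-peak; convolving each subject's own click response with the 100 Hz
pulse train predicts their measured FFR with r ≈ 0.7 (about half the
response variance is muscle, not brain); directing gaze to ±70° more than
triples the mastoid-referenced FFR while the neck-referenced channel does
not move; and the music–FFR association is partially mediated by PAM size.
Single cohorts of n = 20 are noisy — correlation-type statistics swing
substantially from seed to seed, which is why the headline numbers below
are averaged over 100 cohorts.

There is also a CLI (`pamffr stimgen / simulate / preprocess / metrics /
model / stats / run / calibrate`); `pamffr run --seed 1 --out out/` executes
the whole pipeline and writes `metrics.csv`, `model_fits.csv`,
`summary.json` and a reproducibility manifest.

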