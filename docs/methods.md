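# Methods

`ownvoice` implements, end to end and on synthetic data, the analysis
pipeline of an own-voice word-recognition study: adult female bilingual
talkers record both members of Cantonese vowel minimal pairs; each talker's
*contrastiveness* for each pair is scored acoustically; talkers are grouped
by contrastiveness per pair; each talker then serves as a listener in a
personalized two-alternative forced-choice (2AFC) task containing her own
disguised productions and those of her group peers; identification accuracy
is analyzed with a Bayesian multilevel logistic regression.

## Acoustic contrastiveness

Each vowel token is reduced to seven dimensions: the first three DCT-II
coefficients of the Bark-scaled F1 and F2 trajectories, plus duration in
seconds. The coefficients are interpretable as trajectory mean, slope and
curvature. Conventions:

* **Bark transform** — Traunmüller's rational form
  `z = 26.81 f / (1960 + f) − 0.53`. Any monotone auditory scale would do;
  this form is invertible and standard in sociophonetic work.
* **Fixed-length resampling** — trajectories are linearly resampled to 20
  uniform points before the DCT so that coefficients are comparable across
  token durations; duration information enters only through the seventh
  dimension.
* **DCT scaling** — coefficients are scaled so that `c0` equals the
  arithmetic mean of the resampled track. Because every dimension is
  z-scored downstream, any consistent linear scaling would give identical
  distances; the choice is fixed for reproducibility only.
* **Repetition pooling** — the two repetitions of a word are averaged in
  coefficient space. Scoring single repetitions instead changes distances
  only through repetition noise.

For one minimal pair, the word vectors of every talker producing both words
are standardized jointly (each dimension centered and scaled to unit sample
SD over all word vectors of that pair; zero-variance dimensions map to 0
rather than NaN), and a talker's contrastiveness is the Euclidean distance
between her two standardized word vectors. The standardization frame is
pair-local because group assignment is pair-local. Talkers missing either
word of a pair are excluded from that pair.

Ranked distances are cut into five contiguous ordered groups A (most
contrastive) through E with largest-remainder balancing (33 talkers →
7, 7, 7, 6, 6); remainders go to the earliest groups and ties break by
talker id, so assignment is deterministic and permutation-invariant. An
override table can reproduce any manual regrouping; infeasible size bounds
relax with a warning.

## Formant measurement

`measure_formants` is a bespoke LPC tracker: audio is resampled to twice
the formant ceiling (default 5,500 Hz, appropriate for adult female
talkers), pre-emphasized (0.97), and analyzed in 45 ms Hamming frames every
2 ms by the autocorrelation method with order `2 + 2 × n_formants`
(default `n_formants = 4`, matched to the three synthesized formants plus
source residue — using 5 invites spurious root-chasing of harmonics at
high f0). Formants are the angles of complex LPC-polynomial roots with
bandwidth under 400 Hz, sorted ascending; frames with fewer than two valid
formants are interpolated from neighbors. Round-trip accuracy against the
synthesizer is ±30–40 Hz for F1 and ±60 Hz for F2 over the cohort's f0
range (180–240 Hz); as in all LPC analysis of high-pitched voices, accuracy
degrades when a formant sits below about three harmonics of f0.

## Synthetic talkers and productions

The generator defines the study conditions:

* **Cohort** — 33 talkers, 13 minimal pairs (the perception roster), f0
  drawn uniformly on 180–240 Hz, per-formant multiplicative idiosyncrasy
  log-normal with log-SD 0.05.
* **Contrast separation** — each talker × pair carries `δ ≥ 0`, log-normal
  with median 1 and log-SD 0.5. Word 1 sits at its canonical nucleus target;
  word 2 is displaced toward the second nucleus by `δ` (durations
  interpolate in log space). `δ = 0` collapses the pair; `δ = 1` gives the
  canonical contrast. The distribution was chosen so that all five groups
  are populated with overlapping, decreasing distance distributions; no
  per-pair δ distributions are observable from published material.
* **Repetition jitter** — multiplicative log-normal noise, default 0.04
  (≈4% relative SD, a realistic within-talker repetition variability),
  applied per token to formant tracks (plus smaller per-point noise) and
  duration.
* **Audio** — source-filter synthesis: a band-limited (windowed-sinc)
  pulse train at the talker's f0 with −22 dB aspiration noise, −12 dB/oct
  glottal shaping, cascaded second-order resonators at F1(t), F2(t) and a
  fixed F3 = 3,200 Hz, and a first-difference radiation characteristic.
  Pulses are placed at exact fractional sample positions with the window
  centered on the pulse; grid-quantized or off-center pulses inject
  audible subharmonics that derail any pitch tracker. The aspiration noise
  uses a fixed internal seed, making synthesis a pure function of its
  arguments (identical repetitions are bit-identical at zero jitter).

Under these defaults the Spearman correlation between generating δ and
measured contrast distance exceeds 0.9 across the cohort. The generator
does not model tone (all words are level-tone by design), consonants, or
naturalistic source variation (vocal fry, shimmer); passing tests therefore
certify the pipeline's arithmetic and statistical calibration, not its
robustness to real recording conditions.

## Stimulus preparation

* **Disguise** — f0 and formants are lowered multiplicatively (defaults
  0.62 and 0.81, the female-to-male "change gender" manipulation). Two
  paths: (a) parametric re-synthesis with scaled parameters (exact, for
  generator tokens); (b) DSP: playback-rate resampling at the formant
  factor (spectrum compression), then one pitch-synchronous overlap-add
  pass that simultaneously restores duration and corrects f0 to the target
  factor. PSOLA uses 2.5-period Hann grains and uniform period marks (valid
  for these quasi-constant-f0 level-tone vowels). Output duration is within
  2% of the input. The two paths agree on measured formants within 7% for
  vowels whose disguised F1 is at least ~3× the disguised f0; below that,
  harmonic sampling limits any formant measurement.
* **f0 estimation** — a two-stage estimator: candidate f0s on a dense grid
  are scored by harmonic-comb contrast on a multitaper spectrum (level at
  harmonics minus the higher neighboring half-harmonic level, which defeats
  spectral slope), with guards against sub- and supermultiple errors, then
  refined on a 4× oversampled cepstrum. Validated to <1% error for the
  stimulus conditions (f0 110–250 Hz, F1/f0 ≳ 3).
* **Levels** — "65 dB" follows the Praat SPL convention (full scale = 1 Pa,
  reference 2×10⁻⁵ Pa): RMS = 2×10⁻⁵·10^(65/20) ≈ 0.035566.
* **Speech-shaped noise** — Gaussian noise filtered by a 1,025-tap FIR
  (frequency-sampling design) matched to the Welch long-term average
  spectrum of the concatenated corpus; matches the corpus LTAS within
  ±3 dB in third-octave-scale bands over 100–8,000 Hz. Noise is generated
  once per experiment and gated per trial with 200 ms of leading and
  trailing noise around the token.
* **Mixing** — the noise segment is scaled so token RMS sits +5 dB above
  noise RMS (exact to ±0.01 dB); clipping raises a warning.

## Experiment construction

For each pair where the participant produced both words, the roster holds
both words × every voice in her group for that pair (herself included) ×
4 repetitions; a voice missing either word of a pair is dropped for both
words ("the removal of one item entails the removal of two"), and a pair
missing the participant's own token is dropped entirely. Trials are
uniformly permuted under a seed and split into 4 contiguous blocks with
sizes differing by at most one. Responses are scored against the intended
word. Reaction times under 200 ms or over 5,000 ms are removed (bounds kept
on the inclusive side), which under the generator's 2% contamination rate
removes just under 2% of trials.

## Response model and inference

Correctness is Bernoulli with logit link:

```
logit P(correct) = β₀ + β_V·VoiceMatch + β_T·Trial_z + Σⱼ γⱼ·Gⱼ
                 + VoiceMatch×Group + Trial×Group + VoiceMatch×Trial
                 + u₀[part] + u_V[part]·VoiceMatch + u_T[part]·Trial_z
```

Voice Match is treatment-coded (other voice = reference); Group is
forward-difference coded (coefficient j = μⱼ − μⱼ₊₁ of adjacent ordered
groups; 16 fixed-effect columns in all); Trial is centered and scaled
within the dataset (sample SD). By-participant random intercepts and
slopes are fully correlated. Priors: Normal(0, 5) on the intercept,
Normal(0, 2.5) on other population-level effects, half-Normal(2.5) on
random-effect SDs, LKJ(2) on the correlation Cholesky factor.

Sampling is Hamiltonian Monte Carlo written for this model: non-centered
random effects; unconstrained log-SDs; the 3×3 correlation parameterized by
tanh-transformed C-vine partial correlations, under which the LKJ(η) prior
plus transform Jacobian reduces to `Σ αᵢ log(1 − zᵢ²)` with
α = (η+½, η+½, η) — so all gradients are closed-form (and are tested
against finite differences). Warmup uses dual-averaging step-size
adaptation (target acceptance 0.85) and Stan-style expanding windows for a
diagonal mass matrix; trajectories are jittered around 1.5 time units
capped at 48 leapfrog steps. Default run: 4 chains × 4,000 iterations with
1,000 warm-up, i.e. 12,000 retained draws ("4,000 iterations" is read as
per-chain total including warm-up; both knobs are exposed). Energy errors
beyond 1,000 count as divergences; a fit is *converged* iff every
split-R-hat (arviz) is below 1.01, and non-convergence is reported, never
silently accepted.

Summaries report the posterior median (means are also emitted), equal-tailed
95% credible interval, and probability of direction
`pd = max(P(β ≥ 0), P(β ≤ 0))`. An effect is *compelling* if the CrI
excludes 0 and *weak evidence* if the CrI includes 0 but pd ≥ 0.95.

The sampler is validated against a 1-D quadrature posterior (intercept-only
model), by MLE coding-equivalence between forward-difference and treatment
coding, by null calibration (≈5% of null replicates reach pd > 0.975), and
by parameter recovery at the full design scale.

## Problem sizes and defaults used in checks

The recovery study simulates the full design — 33 participants × 13 pairs ×
group sizes 5–7 × 2 words × 4 repetitions ≈ 21,000 trials — with generating
fixed effects at the package's reference values (a 1.66 log-odds baseline,
0.23 own-voice benefit, 0.07 trial slope, group contrasts of ±0.2–0.3) and
random-effect SDs (0.5, 0.3, 0.1) with identity generating correlation.
Property suites run at reduced sizes (8–33 talkers, hundreds of trials,
1–2 chains) chosen so the whole suite completes in minutes on one CPU.

## Known limitations

* The deterministic largest-remainder grouping replaces the original
  manual balancing; an override table is the escape hatch, but the exact
  manual adjustments are unrecoverable.
* Per-participant trial totals depend on the study's item-availability
  mask, which is not published; rosters report their own totals.
* Single-replicate parameter recovery at this design size has posterior
  SDs of ≈0.09 (voice match) to ≈0.18 (intercept) log-odds, so recovered
  medians move by that order across seeds.
* The DSP disguise path assumes quasi-constant f0; it is not a
  general-purpose pitch shifter.
* LPC formant accuracy, and hence path-a/path-b agreement, degrades when
  F1 falls below about three harmonics of f0 — a physical limit of formant
  analysis in high-pitched voices, not specific to this implementation.
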