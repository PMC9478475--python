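# ownvoice

Tools for studying the **own-voice benefit** in word recognition: do
listeners identify words more accurately when the (disguised) voice is
their own? The package implements the full analysis pipeline of such a
study — acoustic contrastiveness scoring of minimal-pair productions,
perception-stimulus preparation, personalized two-alternative forced-choice
(2AFC) experiment construction, and Bayesian multilevel analysis of
identification accuracy — together with a synthetic-data generator that
emulates the study's talkers and listeners, so every stage can be exercised
and validated without access to human recordings.

It is aimed at speech scientists and psycholinguists who want a tested,
scriptable re-implementation of this design, or a simulation bench for
planning similar experiments.

## The pipeline

1. **Acoustic features** (`acoustic_features`). Each vowel token becomes a
   7-dimensional vector: the first three DCT coefficients (mean, slope,
   curvature) of its Bark-scaled F1 and F2 trajectories
   (`z = 26.81f/(1960+f) − 0.53`), plus duration. Formant trajectories come
   from the generator or from a bespoke LPC tracker.
2. **Contrastiveness** (`contrastiveness`). For each minimal pair, all
   talkers' word vectors are jointly centered and scaled, and a talker's
   contrastiveness is the Euclidean distance between her two standardized
   word vectors: `d = sqrt(Σᵢ₌₁⁷ (z₁ᵢ − z₂ᵢ)²)`. Talkers are ranked per
   pair and cut into ordered groups A (most contrastive) … E.
3. **Stimulus preparation** (`stimprep`). Vocal disguise by multiplicative
   f0/formant lowering (defaults 0.62 / 0.81), RMS normalization to 65 dB
   (Praat SPL convention, RMS ≈ 0.035566), speech-shaped noise matched to
   the corpus long-term average spectrum, and mixing at +5 dB SNR.
4. **Experiment** (`experiment`). Personalized rosters — own plus
   same-group voices per pair, 4 repetitions — randomized into 4 blocks;
   scoring; reaction-time filtering (keep 200–5000 ms).
5. **Inference** (`inference`). Accuracy ~ Bernoulli(logit⁻¹(η)) with
   treatment-coded Voice Match, centered-and-scaled Trial,
   forward-difference-coded Group, their interactions, and correlated
   by-participant random intercepts and slopes. Priors: Normal(0, 5)
   intercept, Normal(0, 2.5) slopes, half-Normal(2.5) SDs, LKJ(2)
   correlations. Fit by Hamiltonian Monte Carlo (4 chains × 4000
   iterations, 1000 warm-up) with split-R-hat/ESS diagnostics; summaries
   report posterior medians, 95% credible intervals, and the probability
   of direction.
6. **Synthetic data** (`synthdata`). Talkers with per-pair contrast
   separation δ, source-filter vowel audio, and simulated 2AFC responses
   drawn from the same hierarchical model the analysis fits.

See `docs/methods.md` for model details, defaults, and limitations.

## Worked example

Simulate a 12-talker study and fit the accuracy model:

```sh
$ ownvoice simulate --talkers 12 --pairs 13 --seed 7 --out sim
wrote 2880 trials for 12 talkers (2.1% outside the RT window)

$ ownvoice score sim/trials.csv
accuracy 0.819 (own voice 0.812, other voices 0.823)

$ ownvoice fit sim/trials.csv --chains 2 --iterations 1500 --warmup 500 \
      --seed 3 --out summary.csv
fit 2820 trials (2.1% RT-filtered); max R-hat 1.0194, min bulk ESS 244

$ ownvoice report summary.csv | head -4
* Intercept                           +1.56 [+1.18, +1.99]  pd=100.00%
  Voice Match (Own Voice)             +0.07 [-0.33, +0.54]  pd=63.40%
  Trial                               +0.09 [-0.10, +0.29]  pd=81.70%
  Group A vs. B                       -0.13 [-0.47, +0.22]  pd=76.05%
```

Reading the output: the intercept (+1.56 log-odds ≈ 83% accuracy at the
reference cell) shows listeners are good at the task; the `*` flags effects
whose 95% credible interval excludes zero ("compelling"), `.` flags weak
evidence (CrI includes 0 but pd ≥ 95%). At this small scale (12 listeners,
2,880 trials — a quarter of the full design) the simulated +0.23 own-voice
benefit is not reliably detectable, which is exactly what the credible
interval says.

The same steps in Python:

```python
from ownvoice import study, inference

data = study.simulate_study(n_talkers=33, seed=1)      # full design
design = inference.build_design(data.analyzed)         # RT-filtered trials
result = inference.fit(design)                          # 4 x 4000 HMC
print(result.summary())
```

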