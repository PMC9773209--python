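# Methods

This note documents the models, conventions and numerical choices behind
`speechrestore`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Stimulus construction

**Gating.** A sentence of length `n` samples at rate `fs` is partitioned by
a square wave of rate `rate_hz` and duty cycle `duty` into alternating
speech and gap intervals (half-open, 0-based, boundaries at exact multiples
of the duty-split period rounded to the nearest sample). Defaults
`rate_hz = 2.0`, `duty = 0.5` give 250 ms speech / 250 ms silence. Two
conventions the procedure leaves open were fixed as follows:

* *Start phase*: sentences open with speech (`speech_first`), preserving
  sentence onsets — the common convention; `gap_first` is available.
* *Sentence-final partial segment*: truncated at the sentence end, with its
  ramp shortened to half the remaining segment if needed.

**Ramps.** Each surviving speech edge gets a raised-cosine (Hann-edge)
taper `0.5·(1 − cos(πt/T))` over `ramp_ms = 10` ms, rising at onsets and
mirrored at offsets. "Cosine ramp" admits several shapes; the raised cosine
is the one that is both C¹ at the join and standard in gating work. Ramps
must fit inside every full speech segment (`ramp_ms ≤ duty/(2·rate)`,
validated), so gap samples are exactly zero and segment interiors are
untouched.

**Speech-shaped noise.** The noise model is the magnitude of one FFT of the
entire concatenated corpus, zero-padded to the next power of two (the most
literal reading of a single combined transform of all sentences; averaging
per-sentence magnitude spectra is available as `fft_policy="average"`).
Synthesis interpolates the model magnitudes onto the rfft grid of the
requested length, draws i.i.d. uniform phases (DC and Nyquist kept real),
and inverse transforms — Hermitian by construction, hence exactly real. The
DC bin is zeroed at synthesis: the corpus waveforms have a nonzero mean
component that would otherwise appear as a constant offset in the noise.
Noise is synthesized at full stimulus length and then gated to the gap
intervals with the same ramp length — equivalent to interleaving separate
bursts, and easier to verify.

**Levels.** Both components are RMS-normalized over their *active*
intervals (speech intervals for speech, gap intervals for noise) — chosen
because the level statement in the source procedure references the
interrupted speech *segments*; whole-file scope is available by config
(`rms_scope="whole"`). With active-segment scope, `snr_db` is exactly the
measured speech-minus-noise segment level of the assembled stimulus; the
default −10 dB puts the bursts 10 dB above the speech, the configuration
known to maximize restoration. The two stimuli are then added linearly, so
`noise_burst − silent_gap` recovers the gated noise bit-exactly.

**Seeding.** One master seed; per-stimulus noise seeds derive from
`sha256(master, "noise", sentence_id)` truncated below 2³¹, so corpus order
never changes any output.

## Transcript autoscoring

Keywords are content words; transcripts are lowercased, whitespace
collapsed, punctuation stripped except intra-word apostrophes (hyphens split
words; digits are dropped). A candidate token matches a keyword iff it is
an exact match, or differs by exactly **one** application of an enabled
rule: doubled-letter omission, adjacent transposition, apostrophe
insertion/omission, or an entry in the custom-spelling list. No chaining —
strictness is the point of the rule set. Matching is a maximum bipartite
assignment (scipy's Hopcroft–Karp), so scoring is order-independent,
idempotent, monotone in transcript tokens, and duplicated keywords require
duplicated tokens.

Condition aggregation is pooled by default — `100·Σ correct / Σ possible`
over the condition's sentences — because the scored quantity is "number of
keywords correctly identified"; per-sentence mean-of-percentages is
available (`method="mean"`).

## Cognitive battery

Reading span is exact-match recall (case-insensitive, any order, injective
over typed words); no typo tolerance is applied to recall — a deliberate
strictness, relaxable by scoring the recall text through the autoscorer.
Digit span applies the two-wrong stop rule per direction before totalling,
and maps the combined total through a user-supplied monotone normative
table; without a table the percentile is *absent*, never zero. Stroop
interference is the mean-correct-RT ratio CW/C (dimensionless, > 1 means
interference); processing speed is the mean correct W RT. Flanker
interference is the mean-correct-RT difference (may be negative). LexTALE
accuracy is the class-balanced average of word and non-word percent correct
(so the 40/20 imbalance does not double-weight words); timeouts (2,000 ms)
score incorrect; word RT pools correct, non-timeout real words. No RT
outlier trimming is applied anywhere (none is part of the procedure; a
config hook exists but is off).

## Statistical pipeline

* **Fence**: quartiles by linear interpolation between order statistics
  (the mainstream default; the method is configurable since none is named).
  Values strictly beyond `Q1 − k·IQR` / `Q3 + k·IQR` (k = 3) are replaced
  by Q1/Q3 — the parenthetical "(i.e., the first or third quartile)"
  reading — and fence-exact values are retained. Replacement by the
  quartile never reorders untouched values and never crosses the median.
* **Descriptives**: sample SD (n−1), adjusted Fisher–Pearson skewness,
  excess kurtosis (bias-corrected); conventions are stated because none was
  given.
* **Levene**: mean-centered (classic) by default — the citation is to
  Levene, not Brown–Forsythe; median centering is a flag.
* **Welch ANOVA**: groups weighted by n/s²; Welch–Satterthwaite denominator
  df (fractional). For two groups it reduces exactly to the squared Welch
  t; in the balanced equal-variance limit it equals classic ANOVA up to the
  small-sample correction factor.
* **Pairwise**: all C(g,2) Welch t tests, BH step-up adjustment over that
  family.
* **Regression**: predictors z-scored by sample mean/SD before OLS, so β is
  percent per sample-SD of the measure and is invariant to affine rescaling
  of the raw predictor. 95% CIs from the t distribution; VIF as 1/(1−R²_j);
  studentized Breusch–Pagan; Shapiro–Wilk on residuals.
* **Purposeful selection**: from the saturated model, the non-hypothesis
  predictor with the largest p above `p_stay = 0.25` is removed; if any
  retained β then shifts by more than 20% (relative, coefficients below
  1e-8 skipped) the removed predictor is reinstated and locked. Pairwise
  interactions among survivors are screened one at a time at α = 0.05. The
  direction of the p-rule follows the cited selection method (*remove when
  p exceeds the stay threshold*); the literal inverted reading that appears
  in some descriptions is reproducible via `literal_direction=True`. Note
  that under the default threshold a true-null predictor is removed with
  probability 1 − p_stay ≈ 0.75 per pass — the method is a covariate
  screen, not a significance filter.
* **Power**: the regression R² test is F(k, N−k−1); under the alternative,
  noncentral F with λ = f²·N (total-sample-size convention, which is what
  standard power software uses and what reproduces the published minimum of
  57 at f² = 0.3, α = 0.05, power 0.90, k = 4); λ = f²·(error df) is behind
  a flag. The search increments N from k+2; power is monotone in N so the
  first hit is minimal. A vectorized Monte-Carlo simulation of the F test
  serves as an independent cross-check.
* **Missing data**: complete-case per analysis.

## Synthetic data: what it emulates, and what it does not

**Sentences** are harmonic pulse trains (f0 = 100 Hz with 0.2% jitter)
through parallel two-pole resonators at 500/1500/2500 Hz (bandwidth
80 + 0.04·f Hz), amplitude-modulated by a 4 Hz raised-cosine syllabic
envelope with a 50 ms edge taper, at 16 kHz, 2 s — roughly the syllable
rate and duration of conversational sentence material. This gives the DSP
everything it is sensitive to (speech-band spectra, segment-scale
envelopes, levels); it is **not** intelligible speech, so nothing here
validates human scoring behavior or phonetic content.

**Cohorts** draw four latent abilities from a multivariate normal with a
weak-correlation structure (as observed among such predictor batteries;
the resulting VIFs are near 1) and generate each condition score as
`mean_c + Σ_j β_cj·z_j + ε`, `ε ~ N(0, 7.5²)`, clipped to [0, 100]. The
default condition means, the 6×4 β matrix, and the observed-measure affine
maps (e.g. RST = 73.5 + 14.3·z) are fixed documented constants chosen to
emulate a realistic adult online cohort, with the residual SD set so model
R² lands in the 15–30% range typical of such data. Clipping after noise
induces mild attenuation where the maps press against a bound (the lexical
accuracy map, mean 88.7, clips ~11% of draws at 100) — accepted, and small
relative to a 2-SE band at n = 63. Demographics and self-report columns are
generated independent of the abilities. The default screened table is 17
measures per participant (13 experimental + age + three self-report hearing
domains); years-of-education is generated as a covariate but, being a
discrete schooling count, is not fenced by default.

**Transcripts** include each keyword with probability `p_report` and corrupt
included keywords with probability `p_typo` by exactly one rule-covered
typo, so the scored percent depends only on `p_report` (generator–scorer
closure, asserted in tests). **Trial logs** are constructed so that the
task scorers reproduce the cohort table up to item-count granularity; the
digit-span normative table used in simulation is an explicitly synthetic
logistic stand-in, not published norms.

A note on parameter-recovery checks: because the fitted model z-scores
predictors by their *sample* SD, the quantity a replicate estimates is the
generative β per sample-SD of the observed measure (β·s_j/σ_map). Recovery
coverage is therefore assessed against that per-replicate target, for which
normal theory gives exact ~95% coverage of 2-SE bands; against the
population β the extra s_j fluctuation at n = 63 costs a few points of
coverage.

## Problem sizes used in the checked runs

The shipped tests and acceptance script run at sizes chosen to make every
claim checkable quickly while keeping estimators in their working range:
noise-spectrum matches on 60 s syntheses, SNR calibration on 10 synthetic
sentences, type-I rates on 300–2000 null replicates, selection behavior on
30–40 seeded datasets, parameter recovery on 200 cohorts of n = 63, the
Monte-Carlo power cross-check on 10,000 replicates, and the end-to-end CLI
run on a 6-condition × 2-sentence, 16-participant miniature of the default
6 × 60, 63-participant design.

## Known limitations

* No text-to-speech or phonetic content; scores are generated by the linear
  model, not by simulated listening, so the pipeline validates measurement
  and inference, not perception.
* No loudness (dB SPL) calibration; all levels are relative RMS.
* The normative digit-span percentile requires a user-supplied table.
* No mixed-effects or item-level modelling; one row per participant.
* Interaction screening covers pairwise products of surviving main effects
  only.
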