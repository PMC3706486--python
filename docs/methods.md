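# Methods

This note records the models, parameter choices, and numerical decisions
behind each module, plus known limitations. Defaults quoted here are the
code's defaults; tests often use smaller settings for speed.

## Labels

Five emotions in canonical order: Neutral, Happy, Sad, Angry, Anxious
(`EmotionLabel`, values 0–4). Ties anywhere in the package are broken by
this order, and ambiguous fusion results are flagged.

## Front end (`frontend`)

- **Framing:** 25 ms Hamming windows advanced by 10 ms. The number of
  frames is `1 + (len - win) // hop`; signals shorter than one window are
  rejected.
- **Speech-activity detection:** frame log-energy thresholded 30 dB below
  the peak frame, with a minimum retained speech duration of 0.1 s and a
  0.1 s hangover implemented by dilating the voiced mask. An all-silent
  input raises `EmptySpeechError` rather than returning empty features.
- **MFCC:** mel scale `2595 * log10(1 + f/700)`; 26 triangular filters
  with equal mel spacing, each renormalized so its peak is exactly 1;
  orthonormal-style DCT `c_i = sqrt(2/N) * sum_j m_j cos(pi*i*(j-0.5)/N)`.
  Cepstra 1–19 (c0 excluded) plus log frame energy give 20 static
  features; delta and delta-delta by +/-2-frame regression with edge
  replication give 60 total. Excluding c0 makes the cepstra invariant to
  input gain; only the log-energy column shifts, by `log(gain^2)`.
- Log arguments are floored at 1e-10.

## Emotion detector (`emogmm`)

- **UBM:** diagonal-covariance GMM trained by EM, seeded from randomly
  chosen frames with the global variance; per-dimension variances floored
  at 1e-3 of the global variance. The log-likelihood is monotone
  non-decreasing across iterations (tested), and small instances
  cross-check against scikit-learn and closed-form single-Gaussian
  moments.
- **MAP adaptation:** means only,
  `m_k' = alpha_k * E_k(x) + (1 - alpha_k) * m_k` with
  `alpha_k = n_k / (n_k + r)`, relevance factor `r = 16`. Empty data is
  the identity. Weights and covariances are copied from the UBM, which
  keeps sparsely observed components regularized.
- **Scoring and classification:** per-emotion summed frame
  log-likelihoods; posterior by softmax over model scores with equal
  priors. Default mixture size is 64 components; tests and examples use 8
  at their small data scales.
- **Evaluation:** stratified k-fold, retraining UBM and adapted models in
  every fold; results as a 5x5 concordance matrix.

## Emotional-truth fusion (`fusion`)

- Up to four sources per recording: relate votes, transcriber votes
  (count vectors), self-assessment, and detector output (single labels).
  Count sources contribute vote proportions; single-label sources
  contribute 0/1 indicators.
- Default weights 0.3 / 0.4 / 0.1 / 0.2
  (relate / transcriber / self / detector). Weights of absent sources are
  renormalized over the present ones, so the fused vector is always a
  probability distribution. A table with no source present is structural
  error, not a numeric result.
- **Certainty:** `certainty_factor(n) = min(1, 0.13768 + 0.16982 n)`
  where `n` counts *human* responses agreeing with the fused label
  (relate votes + transcriber votes for that label, plus the
  self-assessment if it matches; the detector is excluded). Certainty is
  confidence times this factor. Six or more agreeing responses saturate
  the cap.

## Synthetic trials (`synthio`)

- **Call schedule:** a negative-binomial total of placed calls per
  participant (dispersion 0.9, mean 2.54 calls/day over the trial),
  spread multinomially over days; each placed call is answered with an
  i.i.d. group-level Bernoulli probability. This thinned design keeps
  three invariants at once: the placed-call distribution shape, the
  group answer rates, and exact ledger conservation
  (placed = answered + aborted) on every draw.
- **Groups:** three default profiles (sizes 44 / 33 / 36; answer
  probabilities 0.564 / 0.493 / 0.186) with per-emotion state,
  awareness, and empathy probabilities. Probability vectors not pinned
  down by any published summary are free design choices, documented on
  the `DEFAULT_GROUPS` definitions.
- **Durations:** log-normal with `mu = ln(median)` and
  `sigma = sqrt(2 ln(mean/median))` so the sample mean and median match
  the corpus targets (3.79 s mean, 2.97 s median, sigma ~= 0.698); the
  same shape is shared across groups.
- **Votes:** each recording receives a normally distributed number of
  votes (mean 5, sd 2, floored at 1), each agreeing with the truth label
  with probability 0.8 and otherwise uniform over the other four labels;
  votes are split between relate and transcriber sources.
- **Audio:** a harmonic stack with an emotion-specific prosody profile
  (F0, energy gain, pause fraction), syllabic amplitude modulation,
  voiced-only noise, and exactly placed non-overlapping pause gaps, so
  the realized pause fraction matches the profile.

## Measures (`measures`)

Per-state indicators: self-awareness (self-label equals fused truth),
empathy (guess equals the stimulus's truth; conditioned on the stimulus
label), expressiveness (duration and fused confidence). Aggregation
returns mean, numerator, denominator, and n by group or participant,
optionally per emotion and with a certainty floor; observations missing a
required field raise `ExcludedObservation` paths rather than silently
contributing.

## Multilevel model (`mlm`)

- **Variance components:** one-way ANOVA method-of-moments with the
  unbalanced-design `n0`; negative between-cluster estimates are clamped
  to 0, and the ICC of constant data is 0 by convention.
- **Pooled mean:** inverse-variance weights `1 / (tau^2 + sigma^2/n_j)`;
  reduces to size-weighting as tau^2 -> 0 and to the unweighted mean as
  tau^2 -> infinity.
- **Random-intercept logistic:** marginal likelihood by adaptive
  Gauss-Hermite quadrature (per-cluster Newton mode and curvature-scaled
  nodes, 15 nodes default; deviance stable to ~1e-8 relative under node
  doubling). Optimized by L-BFGS-B over `(beta, log sigma)` with
  `log sigma` bounded in [-8, 4]; standard errors from a central-difference
  numerical Hessian; group probabilities via Wald intervals on the logit
  scale, back-transformed (hence asymmetric near 0 and 1).
  `|beta| > 15` raises `SeparationError`. With tau^2 ~= 0 the fit matches
  ordinary logistic regression (cross-checked against statsmodels).
- **Deviance test:** likelihood-ratio statistic against chi-squared with
  df = parameter difference; a negative statistic (numerical noise in
  nested fits) warns and clamps to 0.

## Monitoring (`monitor`)

- **Dropout:** the observation window ends at
  `min(horizon, last placed day + 1)`. A terminal unanswered run of at
  least the gap threshold (7 days default) is a dropout event at the day
  after the last answered call; participants whose calls stop being
  placed mid-trial are censored at the end of their window. Participants
  who never answer drop out at day 0, so retention curves may start
  below 1.
- **Retention:** Kaplan-Meier product-limit via `lifelines`, evaluated on
  integer days up to the horizon.
- **Alerts:** maximal runs of consecutive unanswered days at or above a
  threshold, and maximal runs of consecutive answered days whose states
  are all negative (Sad, Angry, Anxious).

## Build-vs-buy

Standard numerics are delegated: scipy (optimization, special functions,
WAV I/O), lifelines (Kaplan-Meier), pandas (tables), click (CLI).
The MFCC front end, the GMM/EM/MAP stack, and the adaptive-quadrature
mixed model are implemented here because their exact conventions (HTK
mel/DCT details, means-only MAP with relevance weighting, per-cluster
adaptive nodes) are the point of the package, and are each verified
against closed forms or independent implementations in the tests.

## Limitations

- The synthetic audio is a prosody caricature (harmonics + noise +
  pauses), adequate for exercising the front end and detector but not a
  substitute for real speech; detector accuracies on it say nothing about
  field performance.
- Group-level answer probabilities are i.i.d. across calls; real
  compliance decays over time and within days.
- The certainty model is linear in agreeing-response count with a hard
  cap; it is an empirical crowd-sourcing fit, not a calibrated
  probability.
- MAP adaptation updates means only; weight/variance adaptation and
  channel compensation are out of scope.
- The mixed model supports a single random intercept and one categorical
  fixed effect; no crossed or nested random effects.
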