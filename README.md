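# emotruth

Speech-based emotional monitoring for telephone-delivered momentary
assessment: a synthetic trial generator, an MFCC/GMM emotion detector, a
multi-source "emotional truth" label-fusion scheme, psychological measures
derived from fused labels, random-intercept logistic analysis of clustered
outcomes, and compliance monitoring (answer rates, Kaplan-Meier retention,
alerts).

## The science, briefly

In telephone-based experience sampling, participants receive automated
calls several times a day and speak short answers about their current
emotional state. Each answered call yields a recording whose *emotional
truth* is uncertain: anonymous phone relates, professional transcribers,
the speaker's own self-assessment, and an automatic detector may all label
it, and they may disagree. This package implements that pipeline
end to end:

- **`synthio`** — generates synthetic trials: negative-binomial call
  schedules, group-level answer probabilities, per-call emotional states
  with self-assessment and empathy responses, log-normal utterance
  durations, and harmonic/noise audio with emotion-specific prosody.
- **`frontend`** — energy-threshold speech-activity detection and a
  60-dimensional MFCC stream (19 cepstra + log energy, with delta and
  delta-delta appended).
- **`emogmm`** — a universal background model (diagonal-covariance GMM
  trained by EM) with means-only MAP adaptation per emotion; scoring,
  classification, and stratified k-fold evaluation.
- **`fusion`** — weighted fusion of up to four label sources (default
  weights 0.3 relate / 0.4 transcriber / 0.1 self / 0.2 detector) into a
  fused distribution; a linear crowd-agreement model converts the count of
  agreeing human responses into a certainty factor.
- **`measures`** — self-awareness (self-label matches fused truth),
  empathy (guess matches a stimulus's truth), and expressiveness
  (utterance duration, fused confidence), aggregated by group or
  participant.
- **`mlm`** — ANOVA variance components and ICC, precision-weighted
  pooled means, and a random-intercept logistic model fitted by adaptive
  Gauss-Hermite quadrature, with Wald intervals and deviance tests.
- **`monitor`** — answer rates, dropout/censoring definitions,
  Kaplan-Meier retention, and alerts for missed-call and negative-mood
  runs.

## Worked example

The canonical fusion example: one relate votes Happy, eight transcribers
split seven Happy / one Neutral, the speaker self-assesses Happy, and the
detector says Happy.

```python
import numpy as np
from emotruth import EmotionLabel, VoteTable, fuse

relate = np.zeros(5);      relate[int(EmotionLabel.HAPPY)] = 1
transcriber = np.zeros(5); transcriber[int(EmotionLabel.HAPPY)] = 7
transcriber[int(EmotionLabel.NEUTRAL)] = 1
truth = fuse(VoteTable(relate, transcriber,
                       self_label=EmotionLabel.HAPPY,
                       detector_label=EmotionLabel.HAPPY))
print(truth.label, truth.confidence, truth.n_human_responses, truth.certainty)
```

Running `python examples/03_fusion_worked_example.py` prints:

```
fused distribution:
  Neutral  0.0500
  Happy    0.9500
  Sad      0.0000
  Angry    0.0000
  Anxious  0.0000
label:       Happy
confidence:  0.9500
agreeing human responses: 9
certainty factor at n=9: 1.0000
certainty:   0.9500
```

The other scripts in `examples/` walk through trial simulation
(`01_simulate_trial.py`), training and cross-validating the audio emotion
detector (`02_emotion_detector.py` — 0.86 overall accuracy on a tiny
10-utterance-per-class corpus against a 0.20 chance floor), multilevel
group contrasts (`04_multilevel_analysis.py`), and compliance monitoring
(`05_monitoring.py`). Each is deterministic given its seed.

A thin CLI wraps the same library calls:

```sh
emotruth simulate --config config.json --out trial/ --seed 4
emotruth features trial/audio/rec.wav --out features.csv
emotruth fuse trial/votes.csv --out truth.csv
emotruth measures trial/states.csv --out measures.csv
emotruth mlm trial/states.csv --emotion Happy
emotruth monitor trial/calls.csv trial/states.csv --horizon 60 --out mon/
```

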