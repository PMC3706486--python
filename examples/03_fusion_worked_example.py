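"""The emotional-truth fusion worked example, reproduced end to end.

One anonymous phone relate votes Happy; eight professional transcribers
split seven Happy / one Neutral; the speaker self-assesses Happy; the
automatic detector outputs Happy.  With source weights 0.3 / 0.4 / 0.1 / 0.2
the fused distribution puts 0.95 on Happy and 0.05 on Neutral, and nine
human responses agree with the fused label, saturating the certainty model.
"""

import numpy as np

from emotruth import (
    EMOTION_NAMES,
    EmotionLabel,
    FusionWeights,
    VoteTable,
    certainty_factor,
    fuse,
)

relate = np.zeros(5)
relate[int(EmotionLabel.HAPPY)] = 1
transcriber = np.zeros(5)
transcriber[int(EmotionLabel.HAPPY)] = 7
transcriber[int(EmotionLabel.NEUTRAL)] = 1

votes = VoteTable(relate, transcriber,
                  self_label=EmotionLabel.HAPPY,
                  detector_label=EmotionLabel.HAPPY)
truth = fuse(votes, FusionWeights())

print("fused distribution:")
for name, p in zip(EMOTION_NAMES, truth.fused_probs):
    print(f"  {name:8s} {p:.4f}")
print(f"label:       {truth.label}")
print(f"confidence:  {truth.confidence:.4f}")
print(f"agreeing human responses: {truth.n_human_responses}")
print(f"certainty factor at n={truth.n_human_responses}: "
      f"{certainty_factor(truth.n_human_responses):.4f}")
print(f"certainty:   {truth.certainty:.4f}")

print("\ncertainty factor vs. agreeing responses:")
for n in range(7):
    print(f"  n={n}: {100 * certainty_factor(n):5.1f}%")
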