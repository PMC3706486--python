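"""Per-observation affect measures and their aggregation.

Four quantities per momentary state: the emotional truth itself,
expressiveness (speech length and fused confidence, analysed as two separate
outcomes), self-awareness (self-report matches the truth), and empathy
(guess matches the stimulus recording's truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fusion import EmotionalTruth
from .labels import EmotionLabel


class ExcludedObservation(ValueError):
    """The state lacks the field this measure needs; exclude it, don't fail."""


@dataclass(frozen=True)
class MomentaryState:
    """One sampled observation: fused truth plus the dialogue responses."""

    participant_id: str
    group: str
    timestamp: float
    truth: EmotionalTruth
    self_label: EmotionLabel | None
    duration_s: float
    empathy_stimulus_truth: EmotionLabel | None = None
    empathy_guess: EmotionLabel | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def self_awareness(state: MomentaryState) -> int:
    """1 iff the self-report matches the fused emotional truth."""
    if state.self_label is None:
        raise ExcludedObservation("missing self-assessment")
    return int(state.self_label == state.truth.label)


def empathy(state: MomentaryState) -> int:
    """1 iff the guess matches the stimulus recording's emotional truth."""
    if state.empathy_stimulus_truth is None or state.empathy_guess is None:
        raise ExcludedObservation("missing empathy stimulus or guess")
    return int(state.empathy_guess == state.empathy_stimulus_truth)


def expressiveness(state: MomentaryState) -> tuple[float, float]:
    """(speech length in seconds, fused confidence) — two separate outcomes."""
    return state.duration_s, state.truth.confidence


def aggregate(
    states: pd.DataFrame,
    measure: str,
    by: str = "group",
    per_emotion: bool = True,
    certainty_floor: float = 0.0,
) -> pd.DataFrame:
    """Stratum-level rates/means of one measure from a states table.

    ``states`` columns (as written by the synthetic generator or the fusion
    stage): participant_id, group, truth_label, self_label,
    empathy_stimulus_truth, empathy_guess, duration_s, and optionally
    confidence / certainty.

    ``measure`` is one of ``self_awareness``, ``empathy``, ``emotion_rate``,
    ``duration``, ``confidence``.  Binary measures return mean, numerator and
    denominator; continuous ones mean and count.  Per-emotion conditioning
    uses the truth label, except empathy, which conditions on the stimulus
    truth.  Observations below ``certainty_floor`` are excluded (default 0:
    keep everything).
    """
    if states.empty:
        raise ValueError("no states to aggregate")
    if by not in ("group", "participant"):
        raise ValueError("by must be 'group' or 'participant'")
    df = states.copy()
    if certainty_floor > 0 and "certainty" in df.columns:
        df = df[df["certainty"] >= certainty_floor]

    key = "group" if by == "group" else "participant_id"

    if measure == "self_awareness":
        df = df.dropna(subset=["self_label"])
        df["indicator"] = (df["self_label"] == df["truth_label"]).astype(int)
        emotion_col = "truth_label"
    elif measure == "empathy":
        df = df.dropna(subset=["empathy_stimulus_truth", "empathy_guess"])
        df["indicator"] = (df["empathy_guess"] == df["empathy_stimulus_truth"]).astype(int)
        emotion_col = "empathy_stimulus_truth"
    elif measure == "emotion_rate":
        emotion_col = "truth_label"
    elif measure in ("duration", "confidence"):
        value_col = "duration_s" if measure == "duration" else "confidence"
        emotion_col = "truth_label"
    else:
        raise ValueError(f"unknown measure {measure!r}")

    rows = []
    for stratum, grp in df.groupby(key, sort=True):
        if grp.empty:
            continue
        if measure == "emotion_rate":
            total = len(grp)
            for emotion, sub in grp.groupby(emotion_col, sort=True):
                rows.append({key: stratum, "emotion": emotion, "measure": measure,
                             "mean": len(sub) / total, "numerator": len(sub),
                             "denominator": total, "n": total})
        elif measure in ("duration", "confidence"):
            groups = grp.groupby(emotion_col, sort=True) if per_emotion else [("all", grp)]
            for emotion, sub in groups:
                rows.append({key: stratum, "emotion": emotion, "measure": measure,
                             "mean": float(sub[value_col].mean()),
                             "numerator": float(sub[value_col].sum()),
                             "denominator": len(sub), "n": len(sub)})
        else:
            groups = grp.groupby(emotion_col, sort=True) if per_emotion else [("all", grp)]
            for emotion, sub in groups:
                rows.append({key: stratum, "emotion": emotion, "measure": measure,
                             "mean": float(sub["indicator"].mean()),
                             "numerator": int(sub["indicator"].sum()),
                             "denominator": len(sub), "n": len(sub)})
    return pd.DataFrame(rows)
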