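"""The five-class emotion inventory.

The fixed ordering (Neutral, Happy, Sad, Angry, Anxious) is load-bearing:
ties everywhere in the package are broken by this order, and serialized
vectors (vote counts, fused probabilities, mixture scores) follow it.
"""

from __future__ import annotations

import enum


class EmotionLabel(enum.IntEnum):
    """One of the five momentary-emotion categories.

    The integer value is the canonical position used for tie-breaking and
    for indexing 5-vectors of counts or probabilities.
    """

    NEUTRAL = 0
    HAPPY = 1
    SAD = 2
    ANGRY = 3
    ANXIOUS = 4

    def __str__(self) -> str:  # "Neutral", "Happy", ...
        return self.name.capitalize()

    @classmethod
    def from_name(cls, name: str) -> "EmotionLabel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown emotion label: {name!r}") from None


#: Canonical label order used for every 5-vector in the package.
EMOTIONS: tuple[EmotionLabel, ...] = tuple(EmotionLabel)

#: Column/row names matching :data:`EMOTIONS`.
EMOTION_NAMES: tuple[str, ...] = tuple(str(e) for e in EMOTIONS)

N_EMOTIONS = len(EMOTIONS)
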