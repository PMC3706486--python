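import numpy as np
import pandas as pd
import pytest

from emotruth import (
    EMOTIONS,
    EmotionLabel,
    GroupProfile,
    ProsodyProfile,
    TrialConfig,
    generate_trial,
)


def small_group(name, n, answer_prob, emotion_probs, awareness=0.9, empathy=0.85):
    return GroupProfile(
        name=name,
        n_participants=n,
        answer_prob=answer_prob,
        emotion_probs=np.asarray(emotion_probs, dtype=float),
        awareness_probs=np.full(5, awareness),
        empathy_probs=np.full(5, empathy),
        duration_mean_s=3.79,
        duration_median_s=2.97,
    )


@pytest.fixture(scope="session")
def small_trial():
    """A compact 2-group synthetic trial shared across tests."""
    config = TrialConfig(
        groups=(
            small_group("A", 8, 0.6, (0.4, 0.3, 0.1, 0.1, 0.1)),
            small_group("B", 6, 0.3, (0.2, 0.2, 0.3, 0.2, 0.1)),
        ),
        trial_days=20,
        calls_per_day=2.0,
        seed=7,
    )
    return generate_trial(config)


@pytest.fixture(scope="session")
def default_trial():
    """One trial at the full default study configuration."""
    return generate_trial(TrialConfig(seed=11))


#: Widely separated prosody, one profile per emotion, for classifier tests.
SEPARATED_PROSODY = {
    EmotionLabel.NEUTRAL: ProsodyProfile(80.0, 10.0, 0.4, 3.0, 0.10),
    EmotionLabel.HAPPY: ProsodyProfile(150.0, 30.0, 0.9, 4.0, 0.18),
    EmotionLabel.SAD: ProsodyProfile(220.0, 40.0, 1.5, 5.0, 0.26),
    EmotionLabel.ANGRY: ProsodyProfile(300.0, 50.0, 2.2, 6.0, 0.32),
    EmotionLabel.ANXIOUS: ProsodyProfile(390.0, 60.0, 3.0, 7.0, 0.40),
}
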