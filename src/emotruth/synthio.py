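"""Synthetic experience-sampling trials, votes, and emotion-conditioned audio.

The generator emulates the statistical structure the downstream analysis
assumes: three participant groups with distinct call-answer probabilities,
right-skewed per-participant sample counts, log-normal utterance durations
calibrated to printed corpus moments, group-specific emotion base rates,
per-emotion self-awareness and empathy accuracies, per-recording vote tables
with a varying number of transcribers, and simple harmonic-plus-noise audio
whose prosody (F0, energy, pauses) is conditioned on the emotion.

Everything is driven by a single integer seed: identical (config, seed)
pairs produce byte-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .frontend import Recording
from .fusion import VoteTable
from .labels import EMOTION_NAMES, EMOTIONS, N_EMOTIONS, EmotionLabel

#: Corpus utterance-duration calibration (seconds).
CORPUS_DURATION_MEAN_S = 3.79
CORPUS_DURATION_MEDIAN_S = 2.97
#: Shared log-normal shape from the corpus mean/median ratio.
DURATION_SIGMA = float(np.sqrt(2.0 * np.log(CORPUS_DURATION_MEAN_S / CORPUS_DURATION_MEDIAN_S)))
MIN_DURATION_S = 0.1

UNANSWERED_OUTCOMES = ("no_answer", "busy", "voicemail")
UNANSWERED_PROBS = (0.60, 0.15, 0.25)


class ConfigurationError(ValueError):
    """A trial configuration contains non-finite or out-of-range values."""


def _check_prob(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class ProsodyProfile:
    """Acoustic control parameters for one emotion's synthetic voice."""

    f0_mean_hz: float
    f0_range_hz: float
    energy_gain: float
    articulation_rate: float  # syllables / s
    pause_fraction: float

    def __post_init__(self) -> None:
        if self.f0_mean_hz <= 0:
            raise ConfigurationError("f0_mean_hz must be positive")
        _check_prob("pause_fraction", self.pause_fraction)


#: Default per-emotion prosody.  Anger and happiness raise mean F0, range and
#: energy (anger pauses ~32% of speaking time); sadness lowers F0, range and
#: energy with a slow tempo; anxiety raises mean F0 moderately with ~31%
#: pauses.  Neutral sits in the middle.  All constants are overridable.
DEFAULT_PROSODY: dict[EmotionLabel, ProsodyProfile] = {
    EmotionLabel.NEUTRAL: ProsodyProfile(120.0, 20.0, 1.0, 4.0, 0.20),
    EmotionLabel.HAPPY: ProsodyProfile(180.0, 60.0, 1.6, 4.5, 0.18),
    EmotionLabel.SAD: ProsodyProfile(95.0, 8.0, 0.5, 3.0, 0.35),
    EmotionLabel.ANGRY: ProsodyProfile(210.0, 45.0, 2.0, 5.0, 0.32),
    EmotionLabel.ANXIOUS: ProsodyProfile(155.0, 35.0, 1.2, 4.8, 0.31),
}


@dataclass(frozen=True)
class GroupProfile:
    """Study-group parameters: size, compliance, emotion mix, accuracies."""

    name: str
    n_participants: int
    answer_prob: float
    emotion_probs: np.ndarray
    awareness_probs: np.ndarray
    empathy_probs: np.ndarray
    duration_mean_s: float
    duration_median_s: float

    def __post_init__(self) -> None:
        _check_prob("answer_prob", self.answer_prob)
        for name in ("emotion_probs", "awareness_probs", "empathy_probs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_EMOTIONS,):
                raise ConfigurationError(f"{name} must be a 5-vector")
            _check_prob(name, arr)
            object.__setattr__(self, name, arr)
        if not np.isclose(self.emotion_probs.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("emotion_probs must sum to 1")
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if self.duration_mean_s < self.duration_median_s:
            raise ConfigurationError(
                "duration_mean_s must be >= duration_median_s (right-skew)"
            )

    def duration_lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal matching the configured moments.

        mu = ln(median); sigma = sqrt(2 ln(mean/median)).
        """
        sigma = float(np.sqrt(2.0 * np.log(self.duration_mean_s / self.duration_median_s)))
        return float(np.log(self.duration_median_s)), sigma


def _group(name, n, answer, emotion, awareness, empathy, mean_s) -> GroupProfile:
    # group medians are not printed; the corpus log-normal shape is shared
    median_s = mean_s * np.exp(-(DURATION_SIGMA**2) / 2.0)
    return GroupProfile(name, n, answer, np.array(emotion), np.array(awareness),
                        np.array(empathy), mean_s, float(median_s))


#: The three study groups.  Printed values: sizes 44/33/36, answer rates
#: 0.564/0.493/0.186, duration means 3.46/3.31/2.39 s, happiness rates
#: 0.247/0.240/0.152, anxiety rates (AA 0.048, SUBX 0.022), and the
#: per-emotion self-awareness/empathy rates from the group contrasts.
#: Unprinted cells (e.g. anger accuracies, the residual Sad/Angry emotion
#: mass) are documented defaults chosen to complete each distribution.
#: Vector order: Neutral, Happy, Sad, Angry, Anxious.
DEFAULT_GROUPS: tuple[GroupProfile, ...] = (
    _group("GP", 44, 0.564,
           emotion=(0.450, 0.247, 0.150, 0.118, 0.035),
           awareness=(0.707, 0.788, 0.896, 0.900, 0.958),
           empathy=(0.740, 0.930, 0.900, 0.940, 0.935),
           mean_s=3.46),
    _group("AA", 33, 0.493,
           emotion=(0.440, 0.240, 0.160, 0.112, 0.048),
           awareness=(0.717, 0.780, 0.913, 0.900, 0.956),
           empathy=(0.717, 0.930, 0.900, 0.940, 0.904),
           mean_s=3.31),
    _group("SUBX", 36, 0.186,
           emotion=(0.500, 0.152, 0.200, 0.126, 0.022),
           awareness=(0.632, 0.753, 0.853, 0.880, 0.918),
           empathy=(0.765, 0.930, 0.900, 0.940, 0.935),
           mean_s=2.39),
)


@dataclass(frozen=True)
class TrialConfig:
    """Everything needed to generate one synthetic trial, bit-for-bit."""

    groups: tuple[GroupProfile, ...] = DEFAULT_GROUPS
    trial_days: int = 60
    calls_per_day: float = 2.54  # mean placed calls per participant-day
    seed: int = 0
    vote_count_mean: float = 5.0  # transcriber votes per recording
    vote_count_sd: float = 2.0
    voter_agreement: float = 0.8
    relate_vote_prob: float = 0.5
    nb_dispersion: float = 0.9  # shape of the per-participant call-volume mix

    def __post_init__(self) -> None:
        if self.trial_days < 1:
            raise ConfigurationError("trial_days must be >= 1")
        if self.calls_per_day <= 0:
            raise ConfigurationError("calls_per_day must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        _check_prob("voter_agreement", self.voter_agreement)
        _check_prob("relate_vote_prob", self.relate_vote_prob)

    def to_json(self) -> str:
        def encode(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj
        d = asdict(self)
        return json.dumps(d, default=encode, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrialConfig":
        d = json.loads(text)
        groups = tuple(
            GroupProfile(
                name=g["name"],
                n_participants=g["n_participants"],
                answer_prob=g["answer_prob"],
                emotion_probs=np.array(g["emotion_probs"]),
                awareness_probs=np.array(g["awareness_probs"]),
                empathy_probs=np.array(g["empathy_probs"]),
                duration_mean_s=g["duration_mean_s"],
                duration_median_s=g["duration_median_s"],
            )
            for g in d.pop("groups")
        )
        return cls(groups=groups, **d)


@dataclass(frozen=True)
class TrialDataset:
    """Participants nested in groups, with call logs, states, and votes."""

    participants: pd.DataFrame  # participant_id, group
    calls: pd.DataFrame  # participant_id, group, day, outcome, recording_id
    states: pd.DataFrame  # one row per answered call / momentary state
    votes: pd.DataFrame  # long format: recording_id, source, label, count
    config: TrialConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.calls.to_csv(out / "calls.csv", index=False)
        self.states.to_csv(out / "states.csv", index=False)
        self.votes.to_csv(out / "votes.csv", index=False)
        manifest = {"seed": self.config.seed, "config": json.loads(self.config.to_json())}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, in_dir) -> "TrialDataset":
        p = Path(in_dir)
        manifest = json.loads((p / "manifest.json").read_text())
        return cls(
            participants=pd.read_csv(p / "participants.csv"),
            calls=pd.read_csv(p / "calls.csv"),
            states=pd.read_csv(p / "states.csv"),
            votes=pd.read_csv(p / "votes.csv"),
            config=TrialConfig.from_json(json.dumps(manifest["config"])),
        )


def _draw_other(rng: np.random.Generator, truth: int) -> int:
    """Uniform draw over the four labels other than ``truth``."""
    k = int(rng.integers(0, N_EMOTIONS - 1))
    return k if k < truth else k + 1


def _corpus_emotion_mix(groups) -> np.ndarray:
    sizes = np.array([g.n_participants for g in groups], dtype=float)
    probs = np.vstack([g.emotion_probs for g in groups])
    mix = sizes @ probs / sizes.sum()
    return mix / mix.sum()


def generate_votes(
    truth: EmotionLabel,
    n_transcribers: int,
    n_relates: int,
    agreement: float,
    seed: int | np.random.Generator,
    self_accuracy: float | None = None,
    detector_accuracy: float | None = None,
    recording_id: str = "",
) -> VoteTable:
    """Simulate a vote table for a recording with known true emotion.

    Each human vote equals the truth with probability ``agreement`` and is
    otherwise uniform over the other four labels.  Self-assessment and
    detector labels are generated the same way from their supplied
    accuracies, or omitted when the accuracy is ``None``.
    """
    if n_transcribers < 0 or n_relates < 0:
        raise ValueError("vote counts must be non-negative")
    _check_prob("agreement", agreement)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = int(truth)

    def draw_counts(n: int) -> np.ndarray:
        counts = np.zeros(N_EMOTIONS)
        for _ in range(n):
            if rng.random() < agreement:
                counts[t] += 1
            else:
                counts[_draw_other(rng, t)] += 1
        return counts

    def draw_label(acc: float | None) -> EmotionLabel | None:
        if acc is None:
            return None
        _check_prob("accuracy", acc)
        idx = t if rng.random() < acc else _draw_other(rng, t)
        return EMOTIONS[idx]

    return VoteTable(
        relate_counts=draw_counts(n_relates),
        transcriber_counts=draw_counts(n_transcribers),
        self_label=draw_label(self_accuracy),
        detector_label=draw_label(detector_accuracy),
        recording_id=recording_id,
    )


def generate_trial(config: TrialConfig) -> TrialDataset:
    """Generate a full synthetic trial.

    Per participant, the number of placed calls is negative-binomial
    (participants differ widely in call volume, producing the right-skewed
    corpus count distribution), spread over the trial days; each placed call
    is answered independently with the group's answer probability.  Every
    answered call yields a momentary state: a true emotion from the group's
    base rates, a self-report matching the truth with the per-emotion
    awareness probability, an empathy stimulus drawn from the corpus emotion
    mix with a guess matching it at the per-emotion empathy rate, a
    log-normal duration, and a simulated vote table.
    """
    rng = np.random.default_rng(config.seed)
    corpus_mix = _corpus_emotion_mix(config.groups)

    participants, calls, states, votes = [], [], [], []
    for group in config.groups:
        mu, sigma = group.duration_lognormal_params()
        for p in range(group.n_participants):
            pid = f"{group.name}-{p:03d}"
            participants.append({"participant_id": pid, "group": group.name})

            mean_placed = config.trial_days * config.calls_per_day
            r = config.nb_dispersion
            placed = int(rng.negative_binomial(r, r / (r + mean_placed)))
            per_day = rng.multinomial(placed, np.full(config.trial_days, 1.0 / config.trial_days))

            state_idx = 0
            for day in range(config.trial_days):
                for c in range(int(per_day[day])):
                    answered = rng.random() < group.answer_prob
                    rec_id = f"{pid}-d{day:02d}-{state_idx:03d}" if answered else ""
                    outcome = (
                        "answered"
                        if answered
                        else UNANSWERED_OUTCOMES[
                            rng.choice(len(UNANSWERED_OUTCOMES), p=UNANSWERED_PROBS)
                        ]
                    )
                    calls.append(
                        {"participant_id": pid, "group": group.name, "day": day,
                         "outcome": outcome, "recording_id": rec_id}
                    )
                    if not answered:
                        continue

                    truth = int(rng.choice(N_EMOTIONS, p=group.emotion_probs))
                    aware = rng.random() < group.awareness_probs[truth]
                    self_label = truth if aware else _draw_other(rng, truth)
                    stimulus = int(rng.choice(N_EMOTIONS, p=corpus_mix))
                    empathic = rng.random() < group.empathy_probs[stimulus]
                    guess = stimulus if empathic else _draw_other(rng, stimulus)
                    duration = max(MIN_DURATION_S, float(rng.lognormal(mu, sigma)))

                    states.append(
                        {"participant_id": pid, "group": group.name, "day": day,
                         "recording_id": rec_id,
                         "truth_label": EMOTION_NAMES[truth],
                         "self_label": EMOTION_NAMES[self_label],
                         "empathy_stimulus_truth": EMOTION_NAMES[stimulus],
                         "empathy_guess": EMOTION_NAMES[guess],
                         "duration_s": duration}
                    )

                    n_tr = max(1, int(round(rng.normal(config.vote_count_mean, config.vote_count_sd))))
                    n_rel = int(rng.random() < config.relate_vote_prob)
                    table = generate_votes(
                        EMOTIONS[truth], n_tr, n_rel, config.voter_agreement, rng,
                        self_accuracy=None, detector_accuracy=None, recording_id=rec_id,
                    )
                    for label_idx in range(N_EMOTIONS):
                        for source, counts in (("relate", table.relate_counts),
                                               ("transcriber", table.transcriber_counts)):
                            if counts[label_idx] > 0:
                                votes.append({"recording_id": rec_id, "source": source,
                                              "label": EMOTION_NAMES[label_idx],
                                              "count": int(counts[label_idx])})
                    votes.append({"recording_id": rec_id, "source": "self",
                                  "label": EMOTION_NAMES[self_label], "count": 1})
                    state_idx += 1

    columns_states = ["participant_id", "group", "day", "recording_id", "truth_label",
                      "self_label", "empathy_stimulus_truth", "empathy_guess", "duration_s"]
    columns_calls = ["participant_id", "group", "day", "outcome", "recording_id"]
    return TrialDataset(
        participants=pd.DataFrame(participants, columns=["participant_id", "group"]),
        calls=pd.DataFrame(calls, columns=columns_calls),
        states=pd.DataFrame(states, columns=columns_states),
        votes=pd.DataFrame(votes, columns=["recording_id", "source", "label", "count"]),
        config=config,
    )


def sample_durations(
    n: int,
    mean_s: float = CORPUS_DURATION_MEAN_S,
    median_s: float = CORPUS_DURATION_MEDIAN_S,
    seed: int = 0,
) -> np.ndarray:
    """Log-normal durations moment-matched to a printed mean/median pair."""
    sigma = float(np.sqrt(2.0 * np.log(mean_s / median_s)))
    rng = np.random.default_rng(seed)
    return np.maximum(MIN_DURATION_S, rng.lognormal(np.log(median_s), sigma, size=n))


def synthesize_utterance(
    emotion: EmotionLabel,
    duration_s: float,
    profile: ProsodyProfile | None = None,
    sample_rate: int = 8000,
    seed: int = 0,
) -> Recording:
    """Harmonic-plus-noise utterance with emotion-conditioned prosody.

    A slowly varying F0 contour (mean ± half the range) drives a small
    harmonic stack; a syllabic amplitude modulation at the articulation rate
    shapes energy; randomly placed silent gaps total ``pause_fraction`` of
    the duration; everything is scaled by ``energy_gain``.  The synthesis is
    deliberately simple — it exists to exercise the front-end and the
    classifier, not to model speech.
    """
    if duration_s < MIN_DURATION_S:
        raise ValueError(f"duration must be >= {MIN_DURATION_S} s (minimum utterance length)")
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    profile = profile or DEFAULT_PROSODY[emotion]
    rng = np.random.default_rng(seed)

    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate

    f0 = profile.f0_mean_hz + 0.5 * profile.f0_range_hz * np.sin(
        2 * np.pi * 0.6 * t + rng.uniform(0, 2 * np.pi)
    )
    phase = 2 * np.pi * np.cumsum(f0) / sample_rate
    signal = np.zeros(n)
    for h, gain in enumerate((1.0, 0.6, 0.35, 0.2, 0.1), start=1):
        signal += gain * np.sin(h * phase + rng.uniform(0, 2 * np.pi))

    syllabic = 0.55 + 0.45 * np.sin(
        2 * np.pi * profile.articulation_rate * t + rng.uniform(0, 2 * np.pi)
    )
    signal *= syllabic

    # one silent gap per ~second, placed inside disjoint segments so the
    # total pause length is exact (gaps never overlap)
    voiced = np.ones(n, dtype=bool)
    n_pause = int(round(profile.pause_fraction * n))
    if n_pause > 0:
        n_gaps = max(1, int(duration_s))
        seg = n // n_gaps
        gap = n_pause // n_gaps
        for g in range(n_gaps):
            length = gap + (n_pause - gap * n_gaps if g == 0 else 0)
            length = min(length, seg)
            start = g * seg + int(rng.integers(0, seg - length + 1))
            voiced[start : start + length] = False
    signal = np.where(voiced, signal, 0.0)

    noise = 0.02 * rng.standard_normal(n) * voiced
    out = 0.12 * profile.energy_gain * (signal + noise)
    return Recording(out, sample_rate, recording_id=f"synthetic-{emotion}-{seed}")
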