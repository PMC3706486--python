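"""Multi-source "emotional truth" fusion.

Each recording can carry up to four label sources: majority votes from
anonymous phone-call relates, majority votes from professional transcribers,
the speaker's own self-assessment, and the automatic detector.  The fused
truth is a weighted mixture of the per-source label distributions; its
maximum is the confidence, and a crowd-sourcing regression on the number of
agreeing human responses converts confidence into a predicted accuracy
("certainty").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import EMOTION_NAMES, EMOTIONS, N_EMOTIONS, EmotionLabel

#: Intercept and slope of the linear certainty model (crowd-sourced word
#: transcription accuracy vs. number of agreeing human responses).
CERTAINTY_INTERCEPT = 0.13768
CERTAINTY_SLOPE = 0.16982


class FusionError(ValueError):
    """Raised when a vote table has no usable source."""


@dataclass(frozen=True)
class VoteTable:
    """Per-recording vote counts from the four source types.

    ``relate_counts`` and ``transcriber_counts`` are 5-vectors in canonical
    label order; ``self_label`` / ``detector_label`` are single labels or
    ``None`` when the source is absent.
    """

    relate_counts: np.ndarray
    transcriber_counts: np.ndarray
    self_label: EmotionLabel | None = None
    detector_label: EmotionLabel | None = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        for name in ("relate_counts", "transcriber_counts"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_EMOTIONS,):
                raise ValueError(f"{name} must be a 5-vector")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be non-negative and finite")
            object.__setattr__(self, name, arr)
        if not any(self.sources_present().values()):
            raise FusionError("vote table has no source present")

    def sources_present(self) -> dict[str, bool]:
        return {
            "relate": float(self.relate_counts.sum()) > 0,
            "transcriber": float(self.transcriber_counts.sum()) > 0,
            "self": self.self_label is not None,
            "detector": self.detector_label is not None,
        }


@dataclass(frozen=True)
class FusionWeights:
    """Source weights; defaults are the study's operating point."""

    w_relate: float = 0.3
    w_transcriber: float = 0.4
    w_self: float = 0.1
    w_detector: float = 0.2

    def __post_init__(self) -> None:
        w = self.as_array()
        if np.any(w < 0):
            raise ValueError("fusion weights must be non-negative")
        if w.sum() <= 0:
            raise ValueError("fusion weights must not all be zero")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.w_relate, self.w_transcriber, self.w_self, self.w_detector]
        )


@dataclass(frozen=True)
class EmotionalTruth:
    """Fused label with confidence and certainty for one recording."""

    label: EmotionLabel
    confidence: float
    certainty: float
    n_human_responses: int
    fused_probs: np.ndarray
    ambiguous: bool = False
    recording_id: str = ""


def mv_estimate(counts: np.ndarray) -> np.ndarray:
    """Majority-vote estimate: per-label vote proportions c_e / C.

    Raises :class:`FusionError` when the total count is zero — an absent
    source is a structural signal, not a numeric result.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_EMOTIONS,):
        raise ValueError("counts must be a 5-vector")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise FusionError("source absent: zero total votes")
    return counts / total


def _indicator(label: EmotionLabel) -> np.ndarray:
    v = np.zeros(N_EMOTIONS)
    v[int(label)] = 1.0
    return v


def certainty_factor(n_human_responses: int) -> float:
    """Predicted accuracy of a crowd vote with ``n`` agreeing human responses.

    Linear in the response count and capped at 1; six or more agreeing
    responses saturate the model.
    """
    if n_human_responses < 0:
        raise ValueError("number of human responses must be >= 0")
    return min(1.0, CERTAINTY_INTERCEPT + CERTAINTY_SLOPE * n_human_responses)


def fuse(votes: VoteTable, weights: FusionWeights | None = None) -> EmotionalTruth:
    """Fuse the present sources into an emotional-truth estimate.

    Each count source contributes its vote proportions; self-assessment and
    the detector contribute 0/1 indicators.  Weights of absent sources are
    renormalized over the present ones so the fused vector stays a
    probability distribution.  Ties at the maximum are broken by canonical
    label order and flagged as ambiguous.
    """
    weights = weights or FusionWeights()
    present = votes.sources_present()
    w = weights.as_array()

    dists = np.zeros((4, N_EMOTIONS))
    if present["relate"]:
        dists[0] = mv_estimate(votes.relate_counts)
    if present["transcriber"]:
        dists[1] = mv_estimate(votes.transcriber_counts)
    if present["self"]:
        dists[2] = _indicator(votes.self_label)
    if present["detector"]:
        dists[3] = _indicator(votes.detector_label)

    mask = np.array([present[s] for s in ("relate", "transcriber", "self", "detector")])
    w_eff = w * mask
    w_eff = w_eff / w_eff.sum()

    fused = w_eff @ dists
    label_idx = int(np.argmax(fused))  # argmax takes the first max: canonical order
    confidence = float(fused[label_idx])
    ambiguous = int(np.sum(np.isclose(fused, confidence))) > 1
    label = EMOTIONS[label_idx]

    n_human = _agreeing_human_responses(votes, label)
    cert = confidence * certainty_factor(n_human)
    return EmotionalTruth(
        label=label,
        confidence=confidence,
        certainty=cert,
        n_human_responses=n_human,
        fused_probs=fused,
        ambiguous=ambiguous,
        recording_id=votes.recording_id,
    )


def _agreeing_human_responses(votes: VoteTable, label: EmotionLabel) -> int:
    """Count human responses agreeing with the fused label.

    Relate and transcriber votes for the label, plus the self-assessment if
    it matches.  The automatic detector is not a human response.
    """
    n = int(votes.relate_counts[int(label)]) + int(votes.transcriber_counts[int(label)])
    if votes.self_label is not None and votes.self_label == label:
        n += 1
    return n


def certainty(truth: EmotionalTruth) -> float:
    """Certainty = confidence x certainty_factor(# agreeing human responses)."""
    return truth.confidence * certainty_factor(truth.n_human_responses)


# ---------------------------------------------------------------------------
# Tabular interface


def fuse_frame(votes_df: pd.DataFrame, weights: FusionWeights | None = None) -> pd.DataFrame:
    """Fuse a long-format votes table, one output row per recording.

    ``votes_df`` columns: recording_id, source (relate|transcriber|self|
    detector), label, count (ignored for self/detector).
    """
    rows = []
    for rec_id, grp in votes_df.groupby("recording_id", sort=True):
        relate = np.zeros(N_EMOTIONS)
        transcriber = np.zeros(N_EMOTIONS)
        self_label = detector_label = None
        for _, r in grp.iterrows():
            label = EmotionLabel.from_name(str(r["label"]))
            source = str(r["source"])
            if source == "relate":
                relate[int(label)] += float(r.get("count", 1))
            elif source == "transcriber":
                transcriber[int(label)] += float(r.get("count", 1))
            elif source == "self":
                self_label = label
            elif source == "detector":
                detector_label = label
            else:
                raise ValueError(f"unknown vote source {source!r}")
        truth = fuse(
            VoteTable(relate, transcriber, self_label, detector_label, str(rec_id)),
            weights,
        )
        row = {
            "recording_id": rec_id,
            "label": str(truth.label),
            "confidence": truth.confidence,
            "certainty": truth.certainty,
            "n_human_responses": truth.n_human_responses,
            "ambiguous": truth.ambiguous,
        }
        row.update({f"p_{n.lower()}": p for n, p in zip(EMOTION_NAMES, truth.fused_probs)})
        rows.append(row)
    return pd.DataFrame(rows)
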