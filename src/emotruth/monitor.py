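"""Call-compliance analytics: answer rates, trial retention, and alerts.

Works on the day-indexed call log written by the synthetic generator
(columns: participant_id, group, day, outcome, recording_id) and the states
table carrying a fused truth label per answered call.  Days, not individual
calls, are the run unit for both retention and alerting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .labels import EmotionLabel

#: Emotions counted as negative mood for alerting.
DEFAULT_NEGATIVE_SET = frozenset({"Sad", "Angry", "Anxious"})

DEFAULT_DROPOUT_GAP_DAYS = 7


@dataclass(frozen=True)
class Alert:
    participant_id: str
    kind: str  # "missed_run" | "negative_mood_run"
    start_day: int
    end_day: int

    @property
    def run_length(self) -> int:
        return self.end_day - self.start_day + 1


def answer_rates(calls: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Answered/placed call rates per stratum, with the raw counts."""
    if calls.empty:
        raise ValueError("empty call log")
    if by not in ("group", "participant"):
        raise ValueError("by must be 'group' or 'participant'")
    key = "group" if by == "group" else "participant_id"
    rows = []
    for stratum, grp in calls.groupby(key, sort=True):
        placed = len(grp)
        if placed == 0:
            continue
        answered = int((grp["outcome"] == "answered").sum())
        rows.append({key: stratum, "answered": answered, "placed": placed,
                     "rate": answered / placed})
    return pd.DataFrame(rows)


def _answered_days(grp: pd.DataFrame) -> set[int]:
    return set(grp.loc[grp["outcome"] == "answered", "day"].astype(int))


def dropout_times(
    calls: pd.DataFrame,
    horizon_days: int = 60,
    dropout_gap_days: int = DEFAULT_DROPOUT_GAP_DAYS,
) -> pd.DataFrame:
    """Per-participant time-to-dropout with censoring indicators.

    Dropout is a *terminal* unanswered run: if a participant's last answered
    day is followed by at least ``dropout_gap_days`` unanswered days running
    to the end of their observation window, the dropout event occurs on the
    first day of that run.  The observation window ends at the horizon or,
    for a participant whose calls stop being placed earlier (withdrawal from
    the calling schedule), the day after the last placed call — such
    participants are censored mid-trial.  A participant who never answers is
    an event at day 0.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    rows = []
    for pid, grp in calls.groupby("participant_id", sort=True):
        obs_end = min(horizon_days, int(grp["day"].max()) + 1)
        answered = {d for d in _answered_days(grp) if d < obs_end}
        last = max(answered) if answered else -1
        gap = obs_end - (last + 1)
        if gap >= dropout_gap_days:
            rows.append({"participant_id": pid, "time": last + 1, "event": True})
        else:
            rows.append({"participant_id": pid, "time": obs_end, "event": False})
    return pd.DataFrame(rows)


def km_retention(
    calls: pd.DataFrame,
    horizon_days: int = 60,
    dropout_gap_days: int = DEFAULT_DROPOUT_GAP_DAYS,
) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier retention curve and the survival estimate at the horizon.

    Returns (curve, S(horizon)); the curve has columns ``day`` and
    ``survival`` and is non-increasing from 1.
    """
    times = dropout_times(calls, horizon_days, dropout_gap_days)
    kmf = KaplanMeierFitter()
    kmf.fit(times["time"], event_observed=times["event"])
    sf = kmf.survival_function_
    curve = pd.DataFrame({"day": sf.index.to_numpy(float),
                          "survival": sf.iloc[:, 0].to_numpy(float)})
    s_horizon = float(kmf.predict(horizon_days))
    return curve, s_horizon


def _maximal_runs(days: list[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers in a sorted unique day list."""
    runs = []
    for d in days:
        if runs and d == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], d)
        else:
            runs.append((d, d))
    return runs


def scan_alerts(
    calls: pd.DataFrame,
    states: pd.DataFrame | None = None,
    missed_threshold_days: int = 3,
    negative_run_days: int = 3,
    negative_set: frozenset[str] = DEFAULT_NEGATIVE_SET,
) -> list[Alert]:
    """Rule-based alerts for missed-call runs and negative-mood runs.

    A missed run is a maximal run of >= ``missed_threshold_days`` consecutive
    days without a single answered call, inside the participant's observed
    day span.  A negative-mood run is a maximal run of >=
    ``negative_run_days`` consecutive days on which every registered state's
    truth label is in ``negative_set``.  Only maximal runs alert — never
    nested sub-runs.
    """
    if missed_threshold_days < 1 or negative_run_days < 1:
        raise ValueError("alert thresholds must be >= 1")
    alerts: list[Alert] = []

    for pid, grp in calls.groupby("participant_id", sort=True):
        span = range(int(grp["day"].min()), int(grp["day"].max()) + 1)
        answered = _answered_days(grp)
        missed = [d for d in span if d not in answered]
        for start, end in _maximal_runs(missed):
            if end - start + 1 >= missed_threshold_days:
                alerts.append(Alert(pid, "missed_run", start, end))

    if states is not None and not states.empty:
        label_col = "truth_label" if "truth_label" in states.columns else "label"
        for pid, grp in states.groupby("participant_id", sort=True):
            by_day = grp.groupby(grp["day"].astype(int))[label_col].agg(list)
            negative_days = sorted(
                d for d, labels in by_day.items() if all(l in negative_set for l in labels)
            )
            for start, end in _maximal_runs(negative_days):
                if end - start + 1 >= negative_run_days:
                    alerts.append(Alert(pid, "negative_mood_run", start, end))

    return alerts
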