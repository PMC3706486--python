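"""Compliance monitoring: answer rates, retention curves, and alerts.

Dropout is defined as a terminal run of unanswered days at least as long
as the gap threshold; participants whose calls simply stop being placed
are censored.  Retention is estimated with the Kaplan-Meier product-limit
estimator, and the alert scanner flags long missed-call runs and
consecutive days of negative mood.
"""

from emotruth import (
    DEFAULT_GROUPS,
    TrialConfig,
    answer_rates,
    generate_trial,
    km_retention,
    scan_alerts,
)

trial = generate_trial(TrialConfig(groups=DEFAULT_GROUPS, trial_days=60, seed=3))

print("per-group answer rates:")
print(answer_rates(trial.calls, by="group").to_string(index=False))

curve, s60 = km_retention(trial.calls, horizon_days=60, dropout_gap_days=7)
print(f"\nKaplan-Meier retention at day 60: {s60:.3f}")
print("last curve steps:")
print(curve.tail().to_string(index=False))

alerts = scan_alerts(trial.calls, trial.states,
                     missed_threshold_days=5, negative_run_days=5)
print(f"\n{len(alerts)} alerts at thresholds (5 missed days / 5 negative days)")
for a in alerts[:10]:
    print(f"  {a.participant_id}: {a.kind} days {a.start_day}-{a.end_day} "
          f"(run length {a.run_length})")
if len(alerts) > 10:
    print(f"  ... and {len(alerts) - 10} more")
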