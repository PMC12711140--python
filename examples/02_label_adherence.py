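"""Label daily adherence from a MEMS bottle-opening log.

A day is adherent when a dose follows the previous one by 18-30 hours
(24 +/- 6 h, bounds inclusive); days without an opening, or whose
openings fall outside the window, are non-adherent. The first dose day
has no prior reference and is excluded.
"""

import pandas as pd

from adhersense import dedupe_events, inter_dose_intervals, label_daily_adherence

events = pd.DataFrame(
    {
        "participant_id": "P01",
        "opened_at": pd.to_datetime(
            [
                "2024-03-01 08:05",
                "2024-03-01 08:15",  # cap re-seated: merged by dedupe
                "2024-03-02 08:10",  # 24.1 h  -> adherent
                "2024-03-03 13:40",  # 29.5 h  -> adherent (late but in window)
                "2024-03-05 08:00",  # 42.3 h  -> non-adherent
                "2024-03-06 08:00",  # 24.0 h  -> adherent
            ]
        ),
    }
)

log = dedupe_events(events, collapse_window=60)
print("deduplicated events:", len(log), "of", len(events))

iv = inter_dose_intervals(log)
print(iv.assign(hours=iv["hours_since_previous"].round(1)).to_string(index=False))

labels = label_daily_adherence(log, pd.date_range("2024-03-01", periods=6))
print(labels.to_string(index=False))
print(f"\nadherent days: {int(labels['label'].sum())} of {len(labels)} labeled")
# 2024-03-04 has no opening -> 0; 2024-03-05 follows by 42.3 h -> 0.
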