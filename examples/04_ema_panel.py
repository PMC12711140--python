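"""From schedule-based EMA responses to a complete daily feature panel.

Five schedules (daily morning/evening, random every 3 days, biweekly,
monthly) are merged onto a full date grid; missing categorical items are
filled by a trailing-7-day rolling mode, numeric items by
chained-equation imputation, and episodic items are forward-filled
across their cadence (3/14/28 days).
"""

import pandas as pd

from adhersense import CohortConfig, simulate_cohort
from adhersense import build_daily_panel, expected_prompts, impute_ema, propagate_episodic
from adhersense.ema import panel_features
from adhersense.synthetic import EMA_ITEM_TYPES

dates = pd.date_range("2024-01-01", periods=28)
cal = expected_prompts(dates)
print("expected prompts over 28 days:")
print(cal["schedule"].value_counts().to_string())

cohort = simulate_cohort(CohortConfig(n_participants=3, n_days=28, seed=8))
panel = build_daily_panel(cohort.ema, dates, EMA_ITEM_TYPES,
                          participants=[0, 1, 2])
print(f"\npanel: {panel.values.shape[0]} participant-days x "
      f"{panel.values.shape[1]} items, "
      f"{panel.observed.to_numpy().mean():.1%} cells observed")

completed = propagate_episodic(impute_ema(panel, seed=8))
features = panel_features(completed)
missing = features.drop(columns=["participant_id", "date"]).isna().mean().mean()
print(f"after imputation + propagation: {missing:.1%} missing")
print("\ndaily features (one participant, first days):")
show = features[features["participant_id"] == 0].head(5)
print(show[["date", "morning_mood", "evening_sadness",
            "biweekly_social_support", "monthly_qol"]].round(2).to_string(index=False))
# biweekly/monthly columns are constant across each cadence interval —
# that is the forward-fill turning episodic surveys into daily predictors.
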