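"""Generate a synthetic multimodal cohort and inspect its streams.

The generator emulates a mobile-sensing adherence study: a smart pill
bottle (MEMS) logging openings, a wrist wearable recording minute-level
steps / heart rate / sleep, five EMA survey schedules, and a one-shot
baseline survey — all driven by a shared latent model so downstream
analyses have recoverable ground truth.
"""

from adhersense import CohortConfig, simulate_cohort, truth_labels

cfg = CohortConfig(n_participants=5, n_days=28, seed=42)
cohort = simulate_cohort(cfg)

print(f"{cfg.n_participants} participants x {cfg.n_days} days")
print(f"MEMS openings:        {len(cohort.mems):6d} events")
print(f"wearable minutes:     {len(cohort.wearable):6d} rows "
      f"({cohort.wearable['heart_rate'].isna().mean():.1%} non-wear)")
print(f"EMA item responses:   {len(cohort.ema):6d} rows "
      f"({cohort.ema['response_time'].notna().mean():.1%} answered)")
print(f"latent adherence rate: {truth_labels(cohort)['label'].mean():.3f}")
print()
print("first MEMS events:")
print(cohort.mems.head(5).to_string(index=False))

# The latent adherence rate is the fraction of participant-days on which
# the generative model actually produced a dose; the MEMS log records an
# opening on exactly those days.
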