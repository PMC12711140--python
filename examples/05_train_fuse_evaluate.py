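"""Two-tier modeling on a small synthetic cohort.

Tier 1: one sequence model per modality (MEMS dosing context, EMA
self-reports, wearable features) trained under nested
leave-one-participant-out cross-validation. Tier 2: constrained
soft-voting fusion of the modality probabilities, with weights optimized
per fold on training participants only. Metrics are macro balanced
accuracy and macro F1 with participant-level bootstrap CIs; the majority
baseline scores 0.50 by construction.

Runtime: ~1-2 minutes on one CPU.
"""

from adhersense import CohortConfig, simulate_cohort, majority_baseline
from adhersense.experiment import run_experiment
from adhersense.metrics import macro_balanced_accuracy
from adhersense.models import HyperGrid

cohort = simulate_cohort(CohortConfig(n_participants=8, n_days=60, seed=21))
result = run_experiment(cohort, window_len=2, grid=HyperGrid.reduced(), n_boot=200)

y = result.fusion[(("mems", "ema", "wearable"), "optimized")].fused["label"]
maj = majority_baseline(y).predict(len(y))
print(f"majority baseline  macro BA {macro_balanced_accuracy(y, maj):.2f}")
for name, rep in result.reports.items():
    ci = rep.ci.get("macro_ba")
    ci_txt = f"  95% CI [{ci[0]:.3f}, {ci[1]:.3f}]" if ci else ""
    print(f"{name:18s} macro BA {rep.macro_ba:.3f}{ci_txt}")

w = result.fusion[(("mems", "ema", "wearable"), "optimized")].fold_weights
first = next(iter(w.items()))
print(f"\nfold {first[0]} optimized weights: "
      + ", ".join(f"{m}={v:.2f}" for m, v in zip(first[1].modalities, first[1].weights)))
# MEMS (recent dosing behavior) typically dominates both Tier-1 accuracy
# and the learned fusion weights — recency is the strongest signal for
# next-day adherence.
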