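"""Missing-data stress tests.

EMA and wearable feature cells are removed before imputation — either
completely at random (10-50% of cells) or as structured 3-day gaps in
10% of participant-weeks — and the pipeline is re-scored with the cached
per-fold models and fusion weights. The reported delta is the change in
optimized-fusion macro balanced accuracy versus the unperturbed run.

Runtime: ~2-3 minutes on one CPU.
"""

from adhersense import CohortConfig, simulate_cohort
from adhersense.experiment import run_experiment
from adhersense.models import HyperGrid
from adhersense.stress import stress_test

cohort = simulate_cohort(CohortConfig(n_participants=8, n_days=60, seed=21))
result = run_experiment(cohort, window_len=2, grid=HyperGrid.reduced(), n_boot=200)

table = stress_test(result, cohort.dates, seed=21)
print(table.round(4).to_string(index=False))

mcar = table[table["regime"].str.startswith("mcar")]
print(f"\nmean macro-BA change under MCAR 10-50%: {mcar['delta'].mean():+.4f}")
# Small deltas indicate the pipeline tolerates substantial missingness:
# imputation absorbs cell-level gaps, and fusion leans on the unmasked
# MEMS modality when the sensed modalities degrade.
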