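"""Configuration for the synthetic multimodal cohort generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort's generative model.

    Next-day adherence is Bernoulli with
    ``logit p = logit(base) + b_i + beta_persist*(prev - base)
    + beta_weekend*is_weekend + state_effect*state``,
    where ``b_i`` is a participant random intercept and ``state`` a latent
    AR(1) mood/symptom process (stationary SD 1) shared with the wearable
    and EMA streams.

    Parameters
    ----------
    n_participants, n_days
        Cohort size; 20 x 120 emulates a scaled-down longitudinal study.
    adherence_base_rate
        Marginal probability of an adherent day for an average participant
        on a weekday with neutral state.
    persistence
        Day-to-day adherence coupling in [0, 1]; mapped internally to a
        log-odds coefficient ``2.5 * persistence`` on yesterday's outcome.
    weekend_penalty
        Probability decrement of adherence on Saturdays/Sundays, applied on
        the logit scale anchored at the base rate.
    dosing_hour_mean, dosing_hour_sd
        Clock time (hours) of bottle openings on adherent days.
    circadian_amplitude_steps, circadian_acrophase
        Cosinor structure of the minute-level step stream (steps/min, peak
        clock hour). The mesor equals the amplitude so the noiseless curve
        touches zero at the trough without clipping.
    wear_gap_rate
        Per-day probability of a contiguous non-wear gap (missing heart
        rate) of 2-20 h; long gaps create invalid (<8 h wear) days.
    ema_nonresponse_rate
        Per-prompt probability that an EMA prompt goes unanswered.
    state_effect
        Log-odds of next-day adherence per SD of the latent state.
    spurious_open_rate
        Probability of a curiosity opening on a non-adherent day (default
        off: openings proxy ingestion).
    """

    n_participants: int = 20
    n_days: int = 120
    seed: int = 11
    adherence_base_rate: float = 0.75
    persistence: float = 0.6
    weekend_penalty: float = 0.10
    dosing_hour_mean: float = 8.0
    dosing_hour_sd: float = 1.0
    circadian_amplitude_steps: float = 10.0
    circadian_acrophase: float = 14.0
    wear_gap_rate: float = 0.15
    ema_nonresponse_rate: float = 0.25
    state_effect: float = 0.8
    spurious_open_rate: float = 0.0
    # secondary knobs of the generative model
    state_ar: float = 0.7
    participant_sd: float = 0.5
    step_noise_sd: float = 3.0
    hr_noise_sd: float = 2.0
    start_date: str = "2024-01-01"

    _PROBS = (
        "adherence_base_rate",
        "persistence",
        "weekend_penalty",
        "wear_gap_rate",
        "ema_nonresponse_rate",
        "spurious_open_rate",
    )

    def __post_init__(self) -> None:
        for name in self._PROBS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("n_participants", "n_days"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        for name in ("dosing_hour_mean", "circadian_acrophase"):
            v = getattr(self, name)
            if not 0.0 <= v < 24.0:
                raise ValueError(f"{name} must be an hour in [0, 24), got {v!r}")
        for name in ("dosing_hour_sd", "circadian_amplitude_steps", "step_noise_sd",
                     "hr_noise_sd", "participant_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.state_ar < 1.0:
            raise ValueError(f"state_ar must be in [0, 1), got {self.state_ar!r}")

    @property
    def beta_persist(self) -> float:
        return 2.5 * self.persistence

    def to_dict(self) -> dict:
        return asdict(self)
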