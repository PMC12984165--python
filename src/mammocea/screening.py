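"""Application of a reading strategy at a screening round.

Screen-eligible states are Healthy and the undiagnosed (preclinical)
stages; diagnosed, remission, and recurrence women follow clinical
surveillance instead of population screening.  Classification splits
attendees into true/false positives/negatives in expectation; every
recall (TP or FP) triggers an ultrasound, and a configurable fraction
additionally a biopsy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import CostSet, ParameterValidationError, StrategyProfile
from .states import HealthState, N_STAGES, UNDX_SLICE


@dataclass(frozen=True)
class ScreeningEvent:
    """Screening effect handed to the transition-matrix builder."""

    compliance: float
    strategy: StrategyProfile

    @property
    def detection_probability(self) -> float:
        """Per-cycle probability an undiagnosed attendee-to-be is screen-detected."""
        return self.compliance * self.strategy.sensitivity


@dataclass
class ScreenOutcome:
    """Expected classification counts for one screening round."""

    attendees: float
    tp: float
    fp: float
    tn: float
    fn: float
    screen_detected_by_stage: np.ndarray = field(
        default_factory=lambda: np.zeros(N_STAGES)
    )
    workup_cost: float = 0.0


def classify_screen(
    occupancy: np.ndarray, compliance: float, strategy: StrategyProfile
) -> ScreenOutcome:
    """Split one round's attendees into TP/FP/TN/FN in expectation.

    ``occupancy`` is a full state-occupancy vector (persons); only the
    Healthy and undiagnosed entries are screen-eligible.  Attendance is
    ``compliance`` of the eligible; positives among attendees with
    preclinical cancer occur at the strategy's sensitivity (preserving
    stage), negatives among cancer-free attendees at its specificity.
    """
    if not 0.0 <= compliance <= 1.0:
        raise ParameterValidationError("classify_screen: compliance must lie in [0, 1]")
    healthy = float(occupancy[HealthState.HEALTHY])
    undx = np.asarray(occupancy[UNDX_SLICE], dtype=float)
    att_healthy = compliance * healthy
    att_undx = compliance * undx
    tp_by_stage = strategy.sensitivity * att_undx
    tp = float(tp_by_stage.sum())
    fn = float(att_undx.sum()) - tp
    tn = strategy.specificity * att_healthy
    fp = att_healthy - tn
    return ScreenOutcome(
        attendees=att_healthy + float(att_undx.sum()),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        screen_detected_by_stage=tp_by_stage,
    )


def workup_cost(outcome: ScreenOutcome, costs: CostSet) -> float:
    """Undiscounted diagnostic work-up cost of one round's recalls.

    Every recall (TP + FP) incurs an ultrasound;
    ``biopsy_fraction_of_recalls`` of recalls additionally a biopsy.
    """
    recalls = outcome.tp + outcome.fp
    return recalls * (
        costs.ultrasound_cost + costs.biopsy_fraction_of_recalls * costs.biopsy_cost
    )
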