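"""Discounted cost and QALY accumulation, incremental analysis, and net
monetary benefit.

Costs and QALYs are booked at cycle start with the same discount
exponent (discount factor ``1/(1+r)^t`` for cycle ``t``), so the ratio
of incremental cost to incremental effect is not distorted by
asymmetric timing.  A negative ICER arising from a cost-saving,
QALY-gaining comparison is labelled dominant and reported alongside the
signed ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .natural_history import CohortTrace
from .parameters import CostSet, EconomicSettings, StrategyProfile, UtilitySet
from .states import DX_SLICE, HealthState, N_STATES, REM_SLICE, UNDX_SLICE

#: dominance labels used by :func:`incremental`
DOMINANT = "dominant (cost-saving per QALY gained)"
DOMINATED = "dominated (costlier per QALY lost)"
DOMINANCE_BY_COST = "dominance by cost (equal QALYs)"
EQUIVALENT = "equivalent"


def discount_factor(t, r: float):
    """Present-value factor ``1/(1+r)^t`` for cycle index ``t`` (vectorised)."""
    return (1.0 + r) ** (-np.asarray(t, dtype=float))


def utility_vector(utilities: UtilitySet) -> np.ndarray:
    """Per-state utility weights (dead states weigh 0)."""
    u = np.zeros(N_STATES)
    u[HealthState.HEALTHY] = utilities.healthy
    u[UNDX_SLICE] = utilities.undiagnosed
    u[DX_SLICE] = np.asarray(utilities.by_stage)
    u[REM_SLICE] = utilities.remission
    u[HealthState.RECURRENCE] = utilities.recurrence
    return u


@dataclass
class EconomicResult:
    """Discounted totals for one strategy run.

    ``breakdown`` itemises the cost total into screening, work-up,
    treatment, remission surveillance, and recurrence management.
    """

    total_cost: float
    total_qalys: float
    breakdown: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.breakdown:
            parts = sum(self.breakdown.values())
            if abs(parts - self.total_cost) > 1e-6 * max(1.0, abs(self.total_cost)):
                raise ValueError(
                    f"cost breakdown ({parts!r}) does not sum to total ({self.total_cost!r})"
                )


def accumulate(
    trace: CohortTrace,
    costs: CostSet,
    utilities: UtilitySet,
    settings: EconomicSettings,
    strategy: StrategyProfile,
    half_cycle_correction: bool = False,
    cycles: tuple[int, int] | None = None,
) -> EconomicResult:
    """Discounted cost and QALY totals over (a cycle range of) a trace.

    Per cycle ``t``: screening cost = mammograms x per-scan price;
    work-up cost = recalls x (ultrasound + biopsy fraction x biopsy);
    treatment, remission-surveillance and recurrence costs follow state
    occupancy; QALYs weight occupancy by state utility.  Everything is
    multiplied by ``discount_factor(t)`` on a global cycle clock, so
    accumulation is additive over disjoint cycle ranges.

    ``half_cycle_correction`` halves the first and last cycle's
    state-occupancy terms (events are left untouched).
    """
    T = trace.n_cycles
    t0, t1 = cycles if cycles is not None else (0, T)
    if not 0 <= t0 <= t1 <= T:
        raise ValueError(f"cycle range ({t0}, {t1}) outside trace of length {T}")
    t = np.arange(t0, t1)
    df = discount_factor(t, settings.discount_rate)
    occ = trace.occupancy[t0:t1]

    screening = trace.mammograms[t0:t1] * strategy.cost_per_scan
    recalls = trace.tp[t0:t1] + trace.fp[t0:t1]
    workup = recalls * (
        costs.ultrasound_cost + costs.biopsy_fraction_of_recalls * costs.biopsy_cost
    )
    stage_cost = np.asarray(costs.treatment_cost, dtype=float)
    treatment = occ[:, DX_SLICE] @ stage_cost
    remission = occ[:, REM_SLICE] @ (costs.remission_fraction * stage_cost)
    recurrence = occ[:, HealthState.RECURRENCE] * costs.recurrence_cost
    qalys = occ @ utility_vector(utilities)

    w = np.ones(t1 - t0)
    if half_cycle_correction and len(w):
        if t0 == 0:
            w[0] = 0.5
        if t1 == T:
            w[-1] = 0.5
    breakdown = {
        "screening": float(screening @ df),
        "workup": float(workup @ df),
        "treatment": float((treatment * w) @ df),
        "remission": float((remission * w) @ df),
        "recurrence": float((recurrence * w) @ df),
    }
    return EconomicResult(
        total_cost=sum(breakdown.values()),
        total_qalys=float((qalys * w) @ df),
        breakdown=breakdown,
    )


@dataclass
class IncrementalComparison:
    """Candidate-vs-reference deltas, ICER and net monetary benefit."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    nmb: float
    label: str = ""


def incremental(
    reference: EconomicResult, candidate: EconomicResult, wtp: float
) -> IncrementalComparison:
    """Incremental comparison of ``candidate`` against ``reference``.

    ICER = delta cost / delta QALYs when the denominator is non-zero;
    otherwise a dominance label replaces the ratio.  NMB =
    ``wtp x delta QALYs - delta cost`` at the given willingness-to-pay.
    """
    dc = candidate.total_cost - reference.total_cost
    dq = candidate.total_qalys - reference.total_qalys
    nmb = wtp * dq - dc
    if dq == 0.0:
        label = DOMINANCE_BY_COST if dc != 0.0 else EQUIVALENT
        return IncrementalComparison(dc, dq, None, nmb, label)
    icer = dc / dq
    if dq > 0.0 and dc <= 0.0:
        label = DOMINANT
    elif dq < 0.0 and dc >= 0.0:
        label = DOMINATED
    else:
        label = ""
    return IncrementalComparison(dc, dq, icer, nmb, label)
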