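"""The Markov cohort engine.

Annual cycles; within each cycle, competing events are composed
multiplicatively in a fixed order — other-cause death, breast-cancer
death, screen detection (screening cycles only), clinical/interval
detection, stage progression, onset — so each later event is conditioned
on the earlier ones not occurring and every transition row sums to one
by construction.  Diagnosed women spend one cycle in treatment, then
move to stage-specific remission; remission can relapse into a single
stage-invariant recurrence state whose survivors return to Remission(IV)
after one cycle of recurrence treatment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .parameters import NaturalHistoryParams, ScreeningPolicy, StrategyProfile
from .screening import ScreeningEvent, classify_screen
from .states import (
    DX_SLICE,
    EARLY_STAGES,
    HealthState,
    LATE_STAGES,
    N_STAGES,
    N_STATES,
    UNDX_SLICE,
    dx,
    remission,
    undx,
)

logger = logging.getLogger(__name__)

_ROW_TOL = 1e-9
_CONSERVATION_TOL = 1e-6


class ModelConsistencyError(RuntimeError):
    """A composed transition row failed its internal consistency check."""


class ConservationError(RuntimeError):
    """Cohort occupancy drifted away from the cohort size."""


def is_screening_cycle(age: int, policy: ScreeningPolicy) -> bool:
    """True when a screening round is offered at ``age``."""
    return (
        policy.start_age <= age <= policy.stop_age
        and (age - policy.start_age) % policy.interval == 0
    )


def _rate(table: dict[int, float], age: int, label: str) -> float:
    try:
        return table[age]
    except KeyError:
        raise ModelConsistencyError(
            f"natural history: no {label} entry for age {age}"
        ) from None


def build_transition_matrix(
    age: int,
    params: NaturalHistoryParams,
    screening_event: ScreeningEvent | None = None,
) -> np.ndarray:
    """One-cycle transition matrix at ``age``.

    When ``screening_event`` is given, undiagnosed survivors are
    screen-detected with probability compliance x sensitivity before
    clinical detection is applied to the remainder.
    """
    nh = params
    om = _rate(nh.other_cause_mortality, age, "other_cause_mortality")
    onset = _rate(nh.onset_rate, age, "onset_rate")
    p_screen = (
        screening_event.detection_probability if screening_event is not None else 0.0
    )

    M = np.zeros((N_STATES, N_STATES))
    so = 1.0 - om

    M[HealthState.HEALTHY, HealthState.DEAD_OTHER] = om
    M[HealthState.HEALTHY, HealthState.UNDX_0] = so * onset
    M[HealthState.HEALTHY, HealthState.HEALTHY] = so * (1.0 - onset)

    for s in range(N_STAGES):
        b = nh.bc_mortality_by_stage[s]
        u = undx(s)
        M[u, HealthState.DEAD_OTHER] = om
        M[u, HealthState.DEAD_BC] = so * b
        survive = so * (1.0 - b)
        det_screen = survive * p_screen
        rest = survive - det_screen
        det_clin = rest * nh.clinical_detection[s]
        rest -= det_clin
        M[u, dx(s)] = det_screen + det_clin
        g = nh.stage_progression[s]
        if s < N_STAGES - 1:
            M[u, undx(s + 1)] = rest * g
            M[u, u] = rest * (1.0 - g)
        else:
            M[u, u] = rest

        d = dx(s)
        M[d, HealthState.DEAD_OTHER] = om
        M[d, HealthState.DEAD_BC] = so * b
        M[d, remission(s)] = so * (1.0 - b)

        r = remission(s)
        rr = nh.recurrence_rate[s]
        M[r, HealthState.DEAD_OTHER] = om
        M[r, HealthState.RECURRENCE] = so * rr
        M[r, r] = so * (1.0 - rr)

    rec = HealthState.RECURRENCE
    M[rec, HealthState.DEAD_OTHER] = om
    M[rec, HealthState.DEAD_BC] = so * nh.bc_mortality_recurrence
    # recurrence survivors resume surveillance as advanced-stage remission
    M[rec, remission(N_STAGES - 1)] = so * (1.0 - nh.bc_mortality_recurrence)

    M[HealthState.DEAD_BC, HealthState.DEAD_BC] = 1.0
    M[HealthState.DEAD_OTHER, HealthState.DEAD_OTHER] = 1.0

    rows = M.sum(axis=1)
    if np.abs(rows - 1.0).max() > _ROW_TOL:
        worst = int(np.abs(rows - 1.0).argmax())
        raise ModelConsistencyError(
            f"transition row {HealthState(worst).name} at age {age} sums to {rows[worst]!r}"
        )
    if M.min() < 0.0 or M.max() > 1.0:
        raise ModelConsistencyError(f"transition entry outside [0, 1] at age {age}")
    return M


def seed_prevalence(
    params: NaturalHistoryParams, cohort_size: float, entry_age: int = 49
) -> np.ndarray:
    """Burn-in occupancy at model entry.

    The cohort starts all-Healthy one year before screening entry and
    runs one pre-screening cycle (onset, progression, clinical
    detection, mortality — no screening), creating the preclinical
    prevalence present at the first screening round.
    """
    v0 = np.zeros(N_STATES)
    v0[HealthState.HEALTHY] = cohort_size
    return v0 @ build_transition_matrix(entry_age, params, None)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and event flows for one strategy run.

    ``occupancy[t]`` is the expected state occupancy at the start of
    cycle ``t`` (``t = 0`` is age ``start_age``); event arrays hold the
    expected flow during cycle ``t``.  Occupancy may be fractional —
    these are expected counts for the closed cohort.
    """

    ages: np.ndarray
    occupancy: np.ndarray
    mammograms: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    screen_detected: np.ndarray
    clinical_detected: np.ndarray
    onsets: np.ndarray
    deaths_bc: np.ndarray
    deaths_other: np.ndarray
    cohort_size: float

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    def tallies(self) -> dict[str, float]:
        """Cumulative event tallies over the whole horizon."""
        screen_by_stage = self.screen_detected.sum(axis=0)
        clin_by_stage = self.clinical_detected.sum(axis=0)
        detected = screen_by_stage + clin_by_stage
        out = {
            "mammograms": float(self.mammograms.sum()),
            "tp": float(self.tp.sum()),
            "fp": float(self.fp.sum()),
            "tn": float(self.tn.sum()),
            "fn": float(self.fn.sum()),
            "undiagnosed_cases": float(self.onsets.sum()),
            "deaths_bc": float(self.deaths_bc.sum()),
            "deaths_other": float(self.deaths_other.sum()),
            "screen_detected": float(screen_by_stage.sum()),
            "clinical_detected": float(clin_by_stage.sum()),
            "early_stage": float(detected[list(EARLY_STAGES)].sum()),
            "late_stage": float(detected[list(LATE_STAGES)].sum()),
        }
        for s in range(N_STAGES):
            out[f"screen_detected_stage_{s}"] = float(screen_by_stage[s])
            out[f"clinical_detected_stage_{s}"] = float(clin_by_stage[s])
        return out

    def check_conservation(self) -> None:
        totals = self.occupancy.sum(axis=1)
        drift = np.abs(totals - self.cohort_size).max()
        if drift > _CONSERVATION_TOL:
            raise ConservationError(
                f"cohort occupancy drifted by {drift:.3e} persons"
            )


def _empty_trace(ages: np.ndarray, initial: np.ndarray) -> CohortTrace:
    T = len(ages)
    occ = np.zeros((T + 1, N_STATES))
    occ[0] = initial
    z = lambda *shape: np.zeros(shape if shape else T)  # noqa: E731
    return CohortTrace(
        ages=ages,
        occupancy=occ,
        mammograms=z(),
        tp=z(),
        fp=z(),
        tn=z(),
        fn=z(),
        screen_detected=z(T, N_STAGES),
        clinical_detected=z(T, N_STAGES),
        onsets=z(),
        deaths_bc=z(),
        deaths_other=z(),
        cohort_size=float(initial.sum()),
    )


def _run_expectation(
    initial: np.ndarray,
    policy: ScreeningPolicy,
    strategy: StrategyProfile,
    params: NaturalHistoryParams,
    compliance: float,
) -> CohortTrace:
    ages = np.arange(policy.start_age, policy.start_age + policy.horizon)
    trace = _empty_trace(ages, initial)
    nh = params
    b = np.asarray(nh.bc_mortality_by_stage)

    for t, age in enumerate(ages):
        v = trace.occupancy[t]
        screening = is_screening_cycle(int(age), policy) and compliance > 0.0
        event = ScreeningEvent(compliance, strategy) if screening else None
        M = build_transition_matrix(int(age), nh, event)

        om = nh.other_cause_mortality[int(age)]
        so = 1.0 - om
        # survivor-conditioned occupancy: tallies use the same conditioning
        # order as the matrix (deaths resolve before any detection)
        surv = v.copy()
        surv[HealthState.HEALTHY] *= so
        surv[UNDX_SLICE] *= so * (1.0 - b)

        p_screen = event.detection_probability if event is not None else 0.0
        if screening:
            out = classify_screen(surv, compliance, strategy)
            trace.mammograms[t] = out.attendees
            trace.tp[t] = out.tp
            trace.fp[t] = out.fp
            trace.tn[t] = out.tn
            trace.fn[t] = out.fn
            trace.screen_detected[t] = out.screen_detected_by_stage
        trace.clinical_detected[t] = (
            surv[UNDX_SLICE] * (1.0 - p_screen) * np.asarray(nh.clinical_detection)
        )
        trace.onsets[t] = surv[HealthState.HEALTHY] * nh.onset_rate[int(age)]
        alive = v[: HealthState.DEAD_BC].sum()
        trace.deaths_other[t] = om * alive
        trace.deaths_bc[t] = (
            so * float((b * (v[UNDX_SLICE] + v[DX_SLICE])).sum())
            + so * nh.bc_mortality_recurrence * v[HealthState.RECURRENCE]
        )

        trace.occupancy[t + 1] = v @ M
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "cycle %d age %d occupancy_sum %.6f mammograms %.2f",
                t,
                age,
                trace.occupancy[t + 1].sum(),
                trace.mammograms[: t + 1].sum(),
            )

    trace.check_conservation()
    return trace


def _merge_traces(a: CohortTrace, b: CohortTrace) -> CohortTrace:
    return CohortTrace(
        ages=a.ages,
        occupancy=a.occupancy + b.occupancy,
        mammograms=a.mammograms + b.mammograms,
        tp=a.tp + b.tp,
        fp=a.fp + b.fp,
        tn=a.tn + b.tn,
        fn=a.fn + b.fn,
        screen_detected=a.screen_detected + b.screen_detected,
        clinical_detected=a.clinical_detected + b.clinical_detected,
        onsets=a.onsets + b.onsets,
        deaths_bc=a.deaths_bc + b.deaths_bc,
        deaths_other=a.deaths_other + b.deaths_other,
        cohort_size=a.cohort_size + b.cohort_size,
    )


def run_cohort(
    initial: np.ndarray,
    policy: ScreeningPolicy,
    strategy: StrategyProfile,
    params: NaturalHistoryParams,
) -> CohortTrace:
    """Propagate the cohort over the full horizon and tally events.

    Screening is applied in cycles where the age falls on the policy's
    screening grid.  By default compliance acts as an independent
    per-round attendance probability; with ``policy.fixed_attenders``
    the compliant fraction is a fixed subgroup attending every round
    (the run splits into an always-attend and a never-attend subcohort
    and the traces are summed).
    """
    initial = np.asarray(initial, dtype=float)
    c = policy.compliance
    if policy.fixed_attenders and 0.0 < c < 1.0:
        attenders = _run_expectation(initial * c, policy, strategy, params, 1.0)
        abstainers = _run_expectation(initial * (1.0 - c), policy, strategy, params, 0.0)
        trace = _merge_traces(attenders, abstainers)
        trace.check_conservation()
        return trace
    return _run_expectation(initial, policy, strategy, params, c)
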