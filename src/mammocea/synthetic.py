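"""Synthetic natural-history/cost/utility bundles and an individual-level
microsimulation oracle for the cohort engine.

The generator emits complete, internally consistent parameter bundles:
age-specific onset rising along a logistic curve (scaled so lifetime
risk lands near 1 in 10-13), preclinical dwell times per stage,
clinical-detection and breast-cancer-mortality gradients increasing
with stage, Gompertz-like other-cause mortality, treatment costs
escalating stage 0 -> IV, and utilities declining with stage.  The three
published reading-strategy profiles and every other printed scenario
constant (scan prices, AI fee, discount rate, compliance, WTP, cohort
size, horizon, screening ages and interval) are embedded verbatim, so
tests of printed numbers never depend on synthesis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .parameters import (
    CostSet,
    EconomicSettings,
    NaturalHistoryParams,
    ParameterBundle,
    ScreeningPolicy,
    StrategyProfile,
    UncertaintySettings,
    UtilitySet,
    derive_scan_costs,
)
from .natural_history import is_screening_cycle
from .states import EARLY_STAGES, HealthState, LATE_STAGES, N_STAGES

#: published test characteristics (sensitivity, specificity) per strategy
PUBLISHED_TEST_CHARACTERISTICS = {
    "conventional": (0.691, 0.954),
    "companion": (0.715, 0.968),
    "standalone": (0.805, 0.893),
}


class SyntheticGenerationError(ValueError):
    """A bundle spec produced an invalid probability."""


@dataclass
class SyntheticBundleSpec:
    """Knobs of the synthetic bundle generator.

    ``seed`` drives the (optional) multiplicative ``jitter`` applied to
    the scale-type knobs, producing families of distinct but valid
    bundles for property testing; with ``jitter = 0`` the generator is a
    pure function of the remaining fields and the default spec is the
    reference scenario.
    """

    seed: int = 0
    jitter: float = 0.0
    age_min: int = 49
    age_max: int = 105
    # onset: logistic in age
    onset_scale: float = 0.003
    onset_midpoint: float = 62.0
    onset_width: float = 8.0
    # preclinical natural history
    stage_dwell_years: list[float] = field(
        default_factory=lambda: [2.0, 1.5, 1.5, 1.25]
    )
    clinical_detection_base: float = 0.05
    clinical_detection_growth: float = 2.0
    bc_mortality_base: float = 0.002
    bc_mortality_growth: float = 3.2
    bc_mortality_recurrence: float = 0.12
    recurrence_base: float = 0.006
    recurrence_growth: float = 1.8
    other_mortality_at_50: float = 0.0025
    other_mortality_log_slope: float = 0.085
    # costs (SGD 2023)
    cost_level: float = 20_000.0
    cost_escalation: float = 1.35
    remission_fraction: float = 0.10
    recurrence_cost: float = 30_000.0
    ultrasound_cost: float = 180.0
    biopsy_cost: float = 1_000.0
    biopsy_fraction_of_recalls: float = 0.5
    mammogram_base_cost: float = 110.0
    radiologist_read_fee: float = 17.5
    ai_fee: float = 5.0
    # utilities
    utility_healthy: float = 0.98
    utility_undiagnosed: float = 0.98
    stage_utility_start: float = 0.94
    stage_utility_decrements: list[float] = field(
        default_factory=lambda: [0.04, 0.06, 0.10, 0.14]
    )
    utility_remission: float = 0.88
    utility_recurrence: float = 0.68
    # policy / economics
    compliance: float = 0.4
    cost_cv: float = 0.05
    utility_sd: float = 0.05


def generate_bundle(spec: SyntheticBundleSpec) -> ParameterBundle:
    """Deterministically expand a spec into a validated parameter bundle."""
    rng = np.random.default_rng(spec.seed)

    def j(x: float) -> float:
        # jitter scale knobs multiplicatively, preserving monotone shapes
        return x * (1.0 + spec.jitter * rng.uniform(-1.0, 1.0)) if spec.jitter else x

    onset_scale = j(spec.onset_scale)
    cost_level = j(spec.cost_level)
    clin_base = j(spec.clinical_detection_base)
    mort_base = j(spec.bc_mortality_base)
    rec_base = j(spec.recurrence_base)
    om50 = j(spec.other_mortality_at_50)

    ages = range(spec.age_min, spec.age_max + 1)
    onset_rate: dict[int, float] = {}
    other_mortality: dict[int, float] = {}
    for a in ages:
        p_on = onset_scale / (1.0 + math.exp(-(a - spec.onset_midpoint) / spec.onset_width))
        if p_on > 1.0:
            raise SyntheticGenerationError(f"onset_rate at age {a} exceeds 1 ({p_on})")
        p_om = om50 * math.exp(spec.other_mortality_log_slope * (a - 50))
        if p_om > 1.0:
            raise SyntheticGenerationError(
                f"other_cause_mortality at age {a} exceeds 1 ({p_om})"
            )
        onset_rate[a] = p_on
        other_mortality[a] = p_om

    progression = []
    for s, dwell in enumerate(spec.stage_dwell_years):
        g = 1.0 / dwell
        if g > 1.0:
            raise SyntheticGenerationError(
                f"stage_progression for stage {s} exceeds 1 (dwell {dwell} < 1 year)"
            )
        progression.append(g)
    progression.append(0.0)

    def gradient(base: float, growth: float, label: str) -> list[float]:
        vals = [base * growth**s for s in range(N_STAGES)]
        for s, v in enumerate(vals):
            if v > 1.0:
                raise SyntheticGenerationError(f"{label} for stage {s} exceeds 1 ({v})")
        return vals

    nh = NaturalHistoryParams(
        onset_rate=onset_rate,
        stage_progression=progression,
        clinical_detection=gradient(
            clin_base, spec.clinical_detection_growth, "clinical_detection"
        ),
        recurrence_rate=gradient(rec_base, spec.recurrence_growth, "recurrence_rate"),
        bc_mortality_by_stage=gradient(
            mort_base, spec.bc_mortality_growth, "bc_mortality_by_stage"
        ),
        bc_mortality_recurrence=spec.bc_mortality_recurrence,
        other_cause_mortality=other_mortality,
    )

    conv, comp, stand = derive_scan_costs(
        spec.mammogram_base_cost, spec.radiologist_read_fee, spec.ai_fee
    )
    scan = {"conventional": conv, "companion": comp, "standalone": stand}
    strategies = {
        name: StrategyProfile(name, sens, specf, scan[name])
        for name, (sens, specf) in PUBLISHED_TEST_CHARACTERISTICS.items()
    }

    by_stage = [spec.stage_utility_start]
    for d in spec.stage_utility_decrements:
        by_stage.append(by_stage[-1] - d)

    bundle = ParameterBundle(
        strategies=strategies,
        policy=ScreeningPolicy(compliance=spec.compliance),
        economics=EconomicSettings(),
        natural_history=nh,
        costs=CostSet(
            treatment_cost=[cost_level * spec.cost_escalation**s for s in range(N_STAGES)],
            remission_fraction=spec.remission_fraction,
            recurrence_cost=spec.recurrence_cost,
            ultrasound_cost=spec.ultrasound_cost,
            biopsy_cost=spec.biopsy_cost,
            biopsy_fraction_of_recalls=spec.biopsy_fraction_of_recalls,
            mammogram_base_cost=spec.mammogram_base_cost,
            radiologist_read_fee=spec.radiologist_read_fee,
            ai_fee=spec.ai_fee,
        ),
        utilities=UtilitySet(
            healthy=spec.utility_healthy,
            undiagnosed=spec.utility_undiagnosed,
            by_stage=by_stage,
            remission=spec.utility_remission,
            recurrence=spec.utility_recurrence,
        ),
        uncertainty=UncertaintySettings(
            cost_cv=spec.cost_cv, utility_sd=spec.utility_sd
        ),
    )
    bundle.validate()
    return bundle


def reference_bundle() -> ParameterBundle:
    """The default reference scenario (a fresh copy each call)."""
    return generate_bundle(SyntheticBundleSpec())


# ---------------------------------------------------------------------------
# individual-level microsimulation (oracle for the cohort engine)
# ---------------------------------------------------------------------------


@dataclass
class MicrosimResult:
    """Tallies scaled to the cohort size, with Monte Carlo standard errors."""

    tallies: dict[str, float]
    standard_errors: dict[str, float]
    n_persons: int
    cohort_size: float


def microsimulate(
    bundle: ParameterBundle,
    strategy_name: str,
    n: int,
    seed: int,
    compliance: float | None = None,
) -> MicrosimResult:
    """Simulate ``n`` independent life histories with Bernoulli events.

    Events are drawn per cycle in exactly the composition order of the
    cohort engine's transition matrix (other-cause death, breast-cancer
    death, screening, clinical detection, progression, onset, then the
    treatment/remission/recurrence moves), including the one-year
    pre-screening burn-in, so the scaled tallies are an unbiased
    estimator of the cohort-engine expectations.
    """
    if n < 1:
        raise ValueError("microsimulate: n must be >= 1")
    policy = bundle.policy
    if compliance is not None:
        policy = replace(policy, compliance=compliance)
    strat = bundle.strategies[strategy_name]
    nh = bundle.natural_history
    rng = np.random.default_rng(seed)

    H = int(HealthState.HEALTHY)
    U0, U4 = int(HealthState.UNDX_0), int(HealthState.UNDX_IV)
    D0, D4 = int(HealthState.DX_0), int(HealthState.DX_IV)
    R0, R4 = int(HealthState.REM_0), int(HealthState.REM_IV)
    REC = int(HealthState.RECURRENCE)
    DBC, DOT = int(HealthState.DEAD_BC), int(HealthState.DEAD_OTHER)

    # state -> hazard lookups
    bc_haz = np.zeros(len(HealthState))
    bc_haz[U0 : U4 + 1] = nh.bc_mortality_by_stage
    bc_haz[D0 : D4 + 1] = nh.bc_mortality_by_stage
    bc_haz[REC] = nh.bc_mortality_recurrence
    clin_haz = np.zeros(len(HealthState))
    clin_haz[U0 : U4 + 1] = nh.clinical_detection
    prog_haz = np.zeros(len(HealthState))
    prog_haz[U0 : U4 + 1] = nh.stage_progression
    rec_haz = np.zeros(len(HealthState))
    rec_haz[R0 : R4 + 1] = nh.recurrence_rate

    states = np.full(n, H, dtype=np.int16)
    mammo = np.zeros(n, dtype=np.int32)
    tp = np.zeros(n, dtype=np.int32)
    fp = np.zeros(n, dtype=np.int32)
    tn = np.zeros(n, dtype=np.int32)
    fn = np.zeros(n, dtype=np.int32)
    screen_det = np.zeros((n, N_STAGES), dtype=np.int32)
    clin_det = np.zeros((n, N_STAGES), dtype=np.int32)
    onsets = np.zeros(n, dtype=np.int32)
    # deaths are tallied as events so the burn-in year (which seeds
    # prevalence but contributes no tallies) stays comparable with the
    # cohort engine's per-cycle death flows
    died_bc = np.zeros(n, dtype=np.int32)
    died_other = np.zeros(n, dtype=np.int32)

    attender = (
        rng.random(n) < policy.compliance if policy.fixed_attenders else None
    )

    def cycle(age: int, screening: bool, tally: bool) -> None:
        start = states.copy()
        alive = start < DBC
        # 1. other-cause death
        die_o = alive & (rng.random(n) < nh.other_cause_mortality[age])
        states[die_o] = DOT
        # 2. breast-cancer death
        die_b = (states < DBC) & (rng.random(n) < bc_haz[start])
        states[die_b] = DBC
        if tally:
            died_other[die_o] += 1
            died_bc[die_b] += 1
        live = states < DBC
        # 3. screening
        if screening:
            eligible = live & (start <= U4)  # Healthy or preclinical at cycle start
            if policy.fixed_attenders:
                attend = eligible & attender
            else:
                attend = eligible & (rng.random(n) < policy.compliance)
            result = rng.random(n)
            with_cancer = attend & (states >= U0) & (states <= U4)
            positive = with_cancer & (result < strat.sensitivity)
            missed = with_cancer & ~positive
            no_cancer = attend & (states == H)
            negative = no_cancer & (result < strat.specificity)
            recalled = no_cancer & ~negative
            if tally:
                mammo[attend] += 1
                tp[positive] += 1
                fn[missed] += 1
                tn[negative] += 1
                fp[recalled] += 1
                stages = states[positive] - U0
                np.add.at(screen_det, (np.flatnonzero(positive), stages), 1)
            states[positive] += D0 - U0
        # 4. clinical / interval detection
        undx = live & (states >= U0) & (states <= U4)
        detected = undx & (rng.random(n) < clin_haz[states])
        if tally:
            stages = states[detected] - U0
            np.add.at(clin_det, (np.flatnonzero(detected), stages), 1)
        states[detected] += D0 - U0
        # 5. stage progression (single draw; each person occupies one stage)
        undx = live & (states >= U0) & (states <= U4)
        prog = undx & (rng.random(n) < prog_haz[states])
        states[prog] += 1
        # 6. onset
        new = live & (states == H) & (rng.random(n) < nh.onset_rate[age])
        states[new] = U0
        if tally:
            onsets[new] += 1
        # 7. treatment -> remission, remission -> recurrence, recurrence -> remission(IV)
        treated = (start >= D0) & (start <= D4) & (states == start)
        states[treated] += R0 - D0
        in_rem = (start >= R0) & (start <= R4) & (states == start)
        relapse = in_rem & (rng.random(n) < rec_haz[start])
        states[relapse] = REC
        back = (start == REC) & (states == REC)
        states[back] = R4

    # burn-in year creates prevalence but contributes no tallies,
    # matching the cohort engine's seed_prevalence
    cycle(policy.start_age - 1, screening=False, tally=False)
    for t in range(policy.horizon):
        age = policy.start_age + t
        cycle(age, is_screening_cycle(age, policy) and policy.compliance > 0, True)

    scale = policy.cohort_size / n
    detected_total = screen_det + clin_det
    per_person: dict[str, np.ndarray] = {
        "mammograms": mammo,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "undiagnosed_cases": onsets,
        "deaths_bc": died_bc,
        "deaths_other": died_other,
        "screen_detected": screen_det.sum(axis=1),
        "clinical_detected": clin_det.sum(axis=1),
        "early_stage": detected_total[:, list(EARLY_STAGES)].sum(axis=1),
        "late_stage": detected_total[:, list(LATE_STAGES)].sum(axis=1),
    }
    for s in range(N_STAGES):
        per_person[f"screen_detected_stage_{s}"] = screen_det[:, s]
        per_person[f"clinical_detected_stage_{s}"] = clin_det[:, s]

    tallies = {k: float(v.sum()) * scale for k, v in per_person.items()}
    ses = {
        k: float(v.std(ddof=1)) * policy.cohort_size / math.sqrt(n)
        for k, v in per_person.items()
    }
    return MicrosimResult(tallies, ses, n, policy.cohort_size)
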