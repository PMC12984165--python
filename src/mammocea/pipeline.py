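"""Convenience drivers wiring burn-in, cohort propagation and economics."""
from __future__ import annotations

import dataclasses

from .economics import EconomicResult, IncrementalComparison, accumulate, incremental
from .natural_history import CohortTrace, run_cohort, seed_prevalence
from .parameters import ParameterBundle


def run_strategy(
    bundle: ParameterBundle,
    strategy_name: str,
    compliance: float | None = None,
) -> tuple[CohortTrace, EconomicResult]:
    """Burn-in, cohort run and economic accumulation for one strategy.

    ``compliance`` overrides the policy's attendance probability for
    scenario analysis; everything else comes from the bundle.
    """
    policy = bundle.policy
    if compliance is not None:
        policy = dataclasses.replace(policy, compliance=compliance)
    strategy = bundle.strategies[strategy_name]
    initial = seed_prevalence(
        bundle.natural_history, policy.cohort_size, policy.start_age - 1
    )
    trace = run_cohort(initial, policy, strategy, bundle.natural_history)
    econ = accumulate(
        trace,
        bundle.costs,
        bundle.utilities,
        bundle.economics,
        strategy,
        half_cycle_correction=policy.half_cycle_correction,
    )
    return trace, econ


def evaluate_all(
    bundle: ParameterBundle, compliance: float | None = None
) -> dict[str, tuple[CohortTrace, EconomicResult]]:
    """Run every strategy in the bundle on the identical cohort settings."""
    return {
        name: run_strategy(bundle, name, compliance) for name in bundle.strategies
    }


def compare_strategies(
    bundle: ParameterBundle,
    reference: str = "conventional",
    compliance: float | None = None,
) -> dict[str, IncrementalComparison]:
    """Incremental comparisons of every non-reference strategy vs the reference."""
    evals = evaluate_all(bundle, compliance)
    ref = evals[reference][1]
    wtp = bundle.economics.wtp_threshold
    return {
        name: incremental(ref, econ, wtp)
        for name, (_, econ) in evals.items()
        if name != reference
    }
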