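"""Discounting, accumulation, incremental analysis and net monetary benefit."""
import numpy as np
import pytest

import mammocea as m
from mammocea.economics import DOMINANCE_BY_COST, DOMINANT, EQUIVALENT


class TestDiscountFactor:
    def test_year_zero_is_one(self):
        assert m.discount_factor(0, 0.03) == pytest.approx(1.0)

    def test_closed_form_year_one(self):
        assert m.discount_factor(1, 0.03) == pytest.approx(1 / 1.03)

    def test_zero_rate_is_flat(self):
        assert np.allclose(m.discount_factor(np.arange(50), 0.0), 1.0)


@pytest.fixture(scope="module")
def zero_bundle():
    """A cancer-free, immortal world with utility weight 1."""
    spec = m.SyntheticBundleSpec(
        onset_scale=0.0,
        clinical_detection_base=0.0,
        bc_mortality_base=0.0,
        bc_mortality_recurrence=0.0,
        recurrence_base=0.0,
        other_mortality_at_50=0.0,
        utility_healthy=1.0,
        utility_undiagnosed=1.0,
    )
    return m.generate_bundle(spec)


@pytest.fixture(scope="module")
def healthy_trace(zero_bundle):
    """Immortal all-Healthy cohort trace (no screening)."""
    trace, _ = m.run_strategy(zero_bundle, "conventional", compliance=0.0)
    return trace


class TestAccumulate:
    def test_undiscounted_annuity(self, zero_bundle, healthy_trace):
        settings = m.EconomicSettings(discount_rate=0.0)
        res = m.accumulate(
            healthy_trace,
            zero_bundle.costs,
            zero_bundle.utilities,
            settings,
            zero_bundle.strategies["conventional"],
        )
        assert res.total_qalys == pytest.approx(10_000 * 50)

    def test_discounted_annuity(self, zero_bundle, healthy_trace):
        res = m.accumulate(
            healthy_trace,
            zero_bundle.costs,
            zero_bundle.utilities,
            zero_bundle.economics,
            zero_bundle.strategies["conventional"],
        )
        annuity = sum(1.03 ** (-t) for t in range(50))
        assert res.total_qalys == pytest.approx(10_000 * annuity)

    def test_matches_per_cycle_brute_force(self, bundle, evals):
        from mammocea.economics import utility_vector
        from mammocea.states import HealthState, dx, remission

        trace, result = evals["companion"]
        costs, u = bundle.costs, utility_vector(bundle.utilities)
        r = bundle.economics.discount_rate
        strat = bundle.strategies["companion"]
        total_cost = total_q = 0.0
        for t in range(trace.n_cycles):
            df = (1 + r) ** (-t)
            occ = trace.occupancy[t]
            recalls = trace.tp[t] + trace.fp[t]
            cost = trace.mammograms[t] * strat.cost_per_scan
            cost += recalls * (
                costs.ultrasound_cost
                + costs.biopsy_fraction_of_recalls * costs.biopsy_cost
            )
            for s in range(5):
                cost += occ[dx(s)] * costs.treatment_cost[s]
                cost += occ[remission(s)] * costs.remission_fraction * costs.treatment_cost[s]
            cost += occ[HealthState.RECURRENCE] * costs.recurrence_cost
            total_cost += df * cost
            total_q += df * float(occ @ u)
        assert result.total_cost == pytest.approx(total_cost)
        assert result.total_qalys == pytest.approx(total_q)

    def test_breakdown_sums_to_total(self, evals):
        for _, res in evals.values():
            assert sum(res.breakdown.values()) == pytest.approx(res.total_cost)

    def test_discounting_shrinks_totals(self, bundle, evals):
        trace, discounted = evals["conventional"]
        undiscounted = m.accumulate(
            trace,
            bundle.costs,
            bundle.utilities,
            m.EconomicSettings(discount_rate=0.0),
            bundle.strategies["conventional"],
        )
        assert discounted.total_cost < undiscounted.total_cost
        assert discounted.total_qalys < undiscounted.total_qalys

    def test_qaly_annuity_upper_bound(self, bundle, evals):
        annuity = sum(1.03 ** (-t) for t in range(50))
        for _, res in evals.values():
            assert res.total_qalys <= 10_000 * annuity

    def test_additive_over_cycle_ranges(self, bundle, evals):
        trace, full = evals["standalone"]
        args = (
            bundle.costs,
            bundle.utilities,
            bundle.economics,
            bundle.strategies["standalone"],
        )
        first = m.accumulate(trace, *args, cycles=(0, 20))
        second = m.accumulate(trace, *args, cycles=(20, trace.n_cycles))
        assert first.total_cost + second.total_cost == pytest.approx(full.total_cost)
        assert first.total_qalys + second.total_qalys == pytest.approx(full.total_qalys)

    def test_half_cycle_correction_halves_boundary_occupancy(self, bundle, evals):
        trace, base = evals["conventional"]
        corrected = m.accumulate(
            trace,
            bundle.costs,
            bundle.utilities,
            bundle.economics,
            bundle.strategies["conventional"],
            half_cycle_correction=True,
        )
        assert corrected.total_qalys < base.total_qalys
        # event-driven costs are untouched
        assert corrected.breakdown["screening"] == pytest.approx(
            base.breakdown["screening"]
        )


class TestIncremental:
    def test_self_comparison_is_equivalent(self, evals):
        res = evals["conventional"][1]
        cmp = m.incremental(res, res, 50_000.0)
        assert (cmp.delta_cost, cmp.delta_qalys, cmp.icer, cmp.nmb) == (0, 0, None, 0)
        assert cmp.label == EQUIVALENT

    def test_cost_saving_qaly_gaining_is_dominant(self):
        ref = m.EconomicResult(100.0, 10.0)
        cand = m.EconomicResult(90.0, 11.0)
        cmp = m.incremental(ref, cand, 50_000.0)
        assert cmp.icer == pytest.approx(-10.0)
        assert cmp.label == DOMINANT

    def test_equal_qalys_yields_cost_dominance_label(self):
        cmp = m.incremental(
            m.EconomicResult(100.0, 10.0), m.EconomicResult(90.0, 10.0), 50_000.0
        )
        assert cmp.icer is None
        assert cmp.label == DOMINANCE_BY_COST

    def test_nmb_linear_in_wtp(self, evals):
        ref, cand = evals["conventional"][1], evals["standalone"][1]
        n1 = m.incremental(ref, cand, 10_000.0).nmb
        n2 = m.incremental(ref, cand, 20_000.0).nmb
        n3 = m.incremental(ref, cand, 30_000.0).nmb
        assert n3 - n2 == pytest.approx(n2 - n1)
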