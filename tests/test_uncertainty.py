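"""Tornado DSA, Gamma/Beta PSA sampling, and acceptability curves."""
import logging

import numpy as np
import pandas as pd
import pytest

import mammocea as m
from mammocea.uncertainty import get_param, with_param

logger = logging.getLogger(__name__)

SMALL_GRID = np.arange(0.0, 100_001.0, 10_000.0)


class TestMethodOfMoments:
    def test_beta_symmetric_case(self):
        a, b = m.beta_moments(0.5, 0.05)
        assert a == pytest.approx(49.5)
        assert b == pytest.approx(49.5)

    def test_gamma_cost_case(self):
        shape, scale = m.gamma_moments(110.0, 5.5)
        assert shape == pytest.approx(400.0)
        assert scale == pytest.approx(0.275)

    @pytest.mark.parametrize("mean,sd", [(0.7, 0.05), (0.9, 0.02), (0.3, 0.1)])
    def test_beta_recovers_moments(self, mean, sd):
        a, b = m.beta_moments(mean, sd)
        assert a / (a + b) == pytest.approx(mean)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx(sd * sd)

    def test_beta_moment_condition_violation_named(self, bundle):
        rng = np.random.default_rng(0)
        b = with_param(bundle, "uncertainty.utility_sd", 0.5)
        with pytest.raises(m.ParameterValidationError, match="utilities.healthy"):
            m.sample_psa_draw(b, rng)


class TestSamplePsaDraw:
    def test_zero_dispersion_returns_base(self, bundle):
        b = with_param(
            with_param(bundle, "uncertainty.cost_cv", 0.0),
            "uncertainty.utility_sd",
            0.0,
        )
        drawn = m.sample_psa_draw(b, np.random.default_rng(1))
        assert drawn.costs.treatment_cost == bundle.costs.treatment_cost
        assert drawn.utilities.by_stage == bundle.utilities.by_stage
        assert drawn.strategies["companion"].cost_per_scan == 97.5

    def test_structural_parameters_held_fixed(self, bundle):
        drawn = m.sample_psa_draw(bundle, np.random.default_rng(2))
        for name in bundle.strategies:
            assert drawn.strategies[name].sensitivity == bundle.strategies[name].sensitivity
            assert drawn.strategies[name].specificity == bundle.strategies[name].specificity
        assert drawn.policy.compliance == bundle.policy.compliance
        assert drawn.costs.remission_fraction == bundle.costs.remission_fraction

    def test_sample_means_recover_base_values(self, bundle):
        """Monte Carlo means of perturbed parameters converge to the base."""
        n = 10_000
        rng_master = np.random.SeedSequence(11).spawn(n)
        paths = {
            "costs.biopsy_cost": [],
            "costs.treatment_cost.2": [],
            "utilities.recurrence": [],
            "utilities.by_stage.0": [],
        }
        for child in rng_master:
            drawn = m.sample_psa_draw(bundle, np.random.default_rng(child))
            for p in paths:
                paths[p].append(get_param(drawn, p))
        for p, values in paths.items():
            values = np.asarray(values)
            base = get_param(bundle, p)
            if p.startswith("costs."):
                sd = bundle.uncertainty.cost_cv * base
            else:
                sd = bundle.uncertainty.utility_sd
            assert abs(values.mean() - base) < 3 * sd / np.sqrt(n), p
            assert values.std() == pytest.approx(sd, rel=0.1)


class TestOneWayDsa:
    def test_zero_perturbation_gives_zero_widths(self, bundle):
        tt = m.one_way_dsa(bundle, parameters=["costs.biopsy_cost"], perturbation=0.0)
        assert (tt.table["width"] == 0.0).all()

    def test_duplicate_parameter_is_idempotent(self, bundle):
        tt = m.one_way_dsa(
            bundle, parameters=["costs.biopsy_cost", "costs.biopsy_cost"]
        )
        a, b = tt.table.iloc[0], tt.table.iloc[1]
        assert a["icer_low"] == b["icer_low"]
        assert a["icer_high"] == b["icer_high"]

    def test_sorted_by_descending_width(self, bundle):
        tt = m.one_way_dsa(bundle)
        widths = tt.table["width"].to_numpy()
        assert np.all(np.diff(widths) <= 1e-12)
        from mammocea.uncertainty import default_dsa_parameters

        assert sorted(tt.table["parameter"]) == sorted(default_dsa_parameters())

    def test_each_icer_matches_independent_rerun(self, bundle):
        """Rerun oracle: tabulated ICERs equal single-run recomputations."""
        params = ["costs.biopsy_cost", "strategies.companion.sensitivity"]
        tt = m.one_way_dsa(bundle, parameters=params, perturbation=0.1)
        wtp = bundle.economics.wtp_threshold
        for _, row in tt.table.iterrows():
            for side in ("low", "high"):
                perturbed = with_param(bundle, row["parameter"], row[f"{side}_value"])
                ref = m.run_strategy(perturbed, "conventional")[1]
                cand = m.run_strategy(perturbed, "companion")[1]
                expected = m.incremental(ref, cand, wtp).icer
                assert row[f"icer_{side}"] == pytest.approx(expected)

    def test_probabilities_clipped_with_warning(self, bundle, caplog):
        with caplog.at_level(logging.WARNING, logger="mammocea.uncertainty"):
            tt = m.one_way_dsa(
                bundle, parameters=["strategies.companion.specificity"]
            )
        assert tt.table.iloc[0]["high_value"] == 1.0
        assert any("clipped" in rec.message for rec in caplog.records)

    def test_specificity_parameters_widest(self, bundle):
        """On the reference set the specificity bars dominate the tornado;
        departure is logged rather than failed (synthetic natural history)."""
        tt = m.one_way_dsa(bundle)
        top2 = set(tt.table["parameter"].iloc[:2])
        expected = {
            "strategies.conventional.specificity",
            "strategies.companion.specificity",
        }
        if top2 != expected:
            logger.warning("tornado top-2 %s differ from specificity pair", top2)


class TestRunPsa:
    def test_single_draw_probabilities_are_indicator(self, bundle):
        res = m.run_psa(bundle, 1, wtp_grid=SMALL_GRID, seed=5)
        prob = res.surfaces[0].probability.to_numpy()
        assert set(np.unique(prob)) <= {0.0, 1.0}
        assert np.allclose(prob.sum(axis=1), 1.0)

    def test_zero_dispersion_gives_deterministic_step_function(self, bundle):
        b = with_param(
            with_param(bundle, "uncertainty.cost_cv", 0.0),
            "uncertainty.utility_sd",
            0.0,
        )
        res = m.run_psa(b, 10, wtp_grid=SMALL_GRID, seed=6)
        surf = res.surfaces[0]
        evals = m.evaluate_all(b)
        for wtp in SMALL_GRID:
            nmb = {
                name: wtp * econ.total_qalys - econ.total_cost
                for name, (_, econ) in evals.items()
            }
            best = max(nmb, key=nmb.get)
            assert surf.probability.loc[wtp, best] == 1.0

    def test_probabilities_sum_to_one_across_compliance_scenarios(self, bundle):
        res = m.run_psa(
            bundle,
            200,
            wtp_grid=SMALL_GRID,
            seed=7,
            compliance_scenarios=(0.2, 0.4, 0.8),
        )
        assert len(res.surfaces) == 3
        for surf in res.surfaces:
            sums = surf.probability.sum(axis=1).to_numpy()
            assert np.abs(sums - 1.0).max() <= 1.0 / surf.n_draws

    def test_rerun_with_same_seed_is_bit_identical(self, bundle):
        a = m.run_psa(bundle, 200, wtp_grid=SMALL_GRID, seed=8)
        b = m.run_psa(bundle, 200, wtp_grid=SMALL_GRID, seed=8)
        pd.testing.assert_frame_equal(a.surfaces[0].probability, b.surfaces[0].probability)
        pd.testing.assert_frame_equal(a.ledger, b.ledger)

    def test_different_seed_changes_draws(self, bundle):
        a = m.run_psa(bundle, 50, wtp_grid=SMALL_GRID, seed=1)
        b = m.run_psa(bundle, 50, wtp_grid=SMALL_GRID, seed=2)
        assert not a.ledger["cost"].equals(b.ledger["cost"])

    def test_ceac_reference_set_qualitative_shape(self, bundle):
        """Standalone AI acceptability is non-decreasing in WTP and
        conventional reading is never the most likely cost-effective
        choice; departures are logged, not failed."""
        res = m.run_psa(bundle, 300, wtp_grid=SMALL_GRID, seed=9)
        surf = res.surfaces[0].probability
        standalone = surf["standalone"].to_numpy()
        if not np.all(np.diff(standalone) >= -1.0 / res.n_draws):
            logger.warning("standalone CEAC is not non-decreasing on the grid")
        best = surf.to_numpy().argmax(axis=1)
        if (best == list(surf.columns).index("conventional")).any():
            logger.warning("conventional reading attained the highest probability")

    def test_invalid_grid_rejected(self, bundle):
        with pytest.raises(ValueError, match="wtp_grid"):
            m.run_psa(bundle, 10, wtp_grid=np.array([5.0, 1.0]), seed=0)
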