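import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oamarkov import engine
from oamarkov.engine import (ExpandedState, assemble_row, build_cycle_matrix,
                             build_state_space, collapse_decline,
                             count_surgeries, mortality_for, round_half_away,
                             run_arm, run_cohort)
from oamarkov.parameters import MortalityInputs
from oamarkov.states import STATE_NAMES, severity_index
from oamarkov.synthetic import synth_model


class TestCollapseDecline:
    def test_two_step_decline_folds_onto_one_step(self):
        row = collapse_decline({"KL_II": 0.1, "KL_III": 0.05}, "KL_I")
        assert row == {"KL_II": pytest.approx(0.15), "KL_III": 0.0}

    def test_row_without_multistep_mass_unchanged(self):
        row = {"KL_I": 0.7, "KL_II": 0.2, "TKR": 0.05}
        assert collapse_decline(row, "KL_I") == row

    def test_multiple_multistep_destinations(self):
        row = collapse_decline({"KL_II": 0.0, "KL_III": 0.2, "KL_IV": 0.1}, "KL_I")
        assert row == {"KL_II": pytest.approx(0.3), "KL_III": 0.0, "KL_IV": 0.0}

    def test_surgery_entries_exempt(self):
        row = collapse_decline({"KL_I": 0.5, "TKR": 0.2}, "Healthy")
        assert row["TKR"] == 0.2


class TestMortalityLayering:
    mort = MortalityInputs(background={60: 0.01})

    def test_background_only_for_mild_states(self):
        assert mortality_for("Healthy", 60, False, self.mort) == 0.01
        assert mortality_for("KL_I", 60, False, self.mort) == 0.01

    def test_drug_excess_for_symptomatic_states(self):
        assert mortality_for("KL_II", 60, False, self.mort) == pytest.approx(0.0112)
        assert mortality_for("KL_IV", 60, False, self.mort) == pytest.approx(0.0112)

    def test_operation_excess_first_cycle_only(self):
        assert mortality_for("TKR", 60, True, self.mort) == pytest.approx(0.012)
        assert mortality_for("TKR", 60, False, self.mort) == 0.01
        assert mortality_for("TKRR", 60, True, self.mort) == pytest.approx(0.012)

    def test_age_below_table_start_errors(self):
        with pytest.raises(ValueError):
            mortality_for("Healthy", 59, False, self.mort)

    def test_clamped_to_unit_interval(self):
        hot = MortalityInputs(background={60: 0.9995}, drug_excess=0.01)
        assert mortality_for("KL_II", 60, False, hot) == 1.0


class TestAssembleRow:
    def test_healthy_row_proportional_renormalisation(self, baseline):
        p = baseline()
        for a in p.mortality.background:
            p.mortality.background[a] = 0.0
        space = build_state_space(p)
        row = assemble_row(ExpandedState("Healthy"), 45, p, space)
        assert row[space.index[ExpandedState("Healthy")]] == pytest.approx(
            0.51103, abs=1e-4)
        assert row[space.index[ExpandedState("KL_I")]] == pytest.approx(
            0.48897, abs=1e-4)

    def test_death_row_is_absorbing(self, baseline):
        p = baseline()
        space = build_state_space(p)
        row = assemble_row(ExpandedState("Death"), 70, p, space)
        assert row[space.index[ExpandedState("Death")]] == 1.0
        assert row.sum() == 1.0

    def test_klii_row_scaled_by_row_sum(self, baseline):
        p = baseline()
        for a in p.mortality.background:
            p.mortality.background[a] = 0.0
        p.mortality.drug_excess = 0.0
        space = build_state_space(p)
        row = assemble_row(ExpandedState("KL_II"), 45, p, space)
        scale = 1.0 / 0.9663
        assert row[space.index[ExpandedState("KL_II")]] == pytest.approx(
            0.928 * scale)
        assert row[space.index[ExpandedState("TKR", tunnel_year=1)]] == \
            pytest.approx(0.0092 * scale)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), cycle=st.integers(0, 39),
           arm=st.sampled_from(["SoC", "hiMSC_auto"]),
           absolute=st.booleans())
    def test_rows_stochastic_for_random_models(self, seed, cycle, arm, absolute):
        p = synth_model(seed)
        p.config.arm = arm
        p.config.effectiveness_is_absolute = absolute
        space = build_state_space(p)
        mat = build_cycle_matrix(space, cycle, p)
        assert np.all(mat >= 0.0) and np.all(mat <= 1.0)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12, rtol=0.0)


class TestRunCohort:
    def test_single_step_matches_renormalised_row(self, baseline):
        p = baseline()
        p.config.horizon = 1
        for a in p.mortality.background:
            p.mortality.background[a] = 0.0
        p.mortality.drug_excess = 0.0
        trace = run_cohort("SoC", p)
        space = trace.space
        expected = assemble_row(ExpandedState("KL_II"), 45, p, space)
        assert np.allclose(trace.occupancy[1], expected)

    def test_mass_conserved_over_horizon(self, baseline):
        trace = run_cohort("SoC", baseline())
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(trace.agg_inflow >= 0.0)

    def test_progressive_only_under_standard_care(self, baseline):
        p = baseline()
        space = build_state_space(p)
        sev = np.array([severity_index(s.name) for s in space.states])
        death = STATE_NAMES.index("Death")
        for cycle in range(p.config.horizon):
            mat = build_cycle_matrix(space, cycle, p)
            for i in range(space.n):
                less_severe = (sev < sev[i]) & (sev < death)
                assert not np.any(mat[i, less_severe] > 0.0)

    def test_treatment_moves_mass_back_to_healthy(self, baseline):
        trace = run_cohort("hiMSC_auto", baseline("hospital", "hiMSC_auto"))
        healthy = trace.aggregate_index("Healthy")
        assert trace.agg_occupancy[1, healthy] > 0.5  # most entrants cured

    def test_null_treatment_equivalence_exact_renormalised(self, baseline):
        soc = run_arm("SoC", baseline("hospital", "SoC"))
        p = baseline("hospital", "hiMSC_auto")
        p.config.effectiveness = 0.0
        p.config.effectiveness_is_absolute = False
        p.costs.treatment_unit = 0.0
        null = run_arm("hiMSC_auto", p)
        assert null.total_cost == pytest.approx(soc.total_cost, rel=1e-12)
        assert null.total_qalys == pytest.approx(soc.total_qalys, rel=1e-12)
        assert (null.tkr_per_1000, null.tkrr_per_1000) == \
            (soc.tkr_per_1000, soc.tkrr_per_1000)

    def test_effectiveness_monotonicity(self, baseline):
        qalys, tkr = [], []
        for e in (0.0, 0.3, 0.69, 1.0):
            p = baseline("hospital", "hiMSC_auto")
            p.config.effectiveness = e
            trace = run_cohort("hiMSC_auto", p)
            out = engine.accrue(trace, p)
            qalys.append(out.total_qalys)
            tkr.append(trace.agg_inflow[:, trace.aggregate_index("TKR")].sum())
        assert all(a <= b + 1e-12 for a, b in zip(qalys, qalys[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(tkr, tkr[1:]))


class TestAccrue:
    def test_closed_form_qalys_without_death_or_discount(self, toy_params):
        p = toy_params(horizon=40, utility=1.0)
        out = run_arm("SoC", p)
        assert out.total_qalys == pytest.approx(40.0, abs=1e-9)

    def test_single_cycle_state_cost(self, toy_params):
        out = run_arm("SoC", toy_params(horizon=1))
        assert out.total_cost == pytest.approx(2569.73)

    def test_discounted_two_cycle_stream(self, toy_params):
        p = toy_params(state_cost=100.0, horizon=2, discount_cost=0.04)
        out = run_arm("SoC", p)
        assert out.total_cost == pytest.approx(196.15, abs=0.01)

    def test_event_costs_attach_to_inflow(self, toy_params):
        p = toy_params(state_cost=0.0, horizon=1, self_loop=False)
        p.costs.tkr_operation = 16565.05
        out = run_arm("SoC", p)  # half the cohort has the operation in cycle 1
        assert out.total_cost == pytest.approx(0.5 * 16565.05 / 1.0)
        assert out.tkr_per_1000 == 500


class TestSurgeryCounts:
    def test_zero_inflow(self, toy_params):
        trace = run_cohort("SoC", toy_params(horizon=5))
        assert count_surgeries(trace) == (0, 0)

    def test_hand_summed_inflow(self, toy_params):
        trace = run_cohort("SoC", toy_params(horizon=2))
        trace.agg_inflow[1, trace.aggregate_index("TKR")] = 0.1
        trace.agg_inflow[2, trace.aggregate_index("TKR")] = 0.2
        assert count_surgeries(trace) == (300, 0)

    @pytest.mark.parametrize("x,expected", [
        (426.1, 426), (426.5, 427), (0.0, 0), (-1.5, -2)])
    def test_rounding_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected
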