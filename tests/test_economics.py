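import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oamarkov.economics import (ArmOutcomes, compute_icer, discount_factor,
                                index_to_2024, round_unit_cost,
                                threshold_check, treatment_unit_cost)
from oamarkov.parameters import ManufacturingInputs


def outcomes(cost, qalys, perspective="hospital", arm="x"):
    return ArmOutcomes(arm=arm, perspective=perspective, total_cost=cost,
                       total_qalys=qalys, tkr_per_1000=0, tkrr_per_1000=0)


class TestUnitCost:
    def test_automated_msc_price(self):
        m = ManufacturingInputs(156864, 421814, 136697, 249238, 190000, 750)
        assert round_unit_cost(treatment_unit_cost(m)) == 1539

    def test_manual_msc_price(self):
        m = ManufacturingInputs(231775, 454955, 49646, 176656, 135000, 480)
        assert round_unit_cost(treatment_unit_cost(m)) == 2183

    def test_zero_components(self):
        assert treatment_unit_cost(
            ManufacturingInputs(0, 0, 0, 0, 0, 10)) == 0.0

    def test_zero_units_error(self):
        with pytest.raises(ValueError):
            treatment_unit_cost(ManufacturingInputs(1, 1, 1, 1, 1, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0),
           comp=st.lists(st.floats(0.0, 1e6), min_size=5, max_size=5),
           units=st.floats(1.0, 5000.0))
    def test_homogeneity(self, scale, comp, units):
        m = ManufacturingInputs(*comp, units)
        scaled = ManufacturingInputs(*[scale * c for c in comp], units)
        assert treatment_unit_cost(scaled) == pytest.approx(
            scale * treatment_unit_cost(m), rel=1e-9)
        divided = ManufacturingInputs(*comp, scale * units)
        assert treatment_unit_cost(divided) == pytest.approx(
            treatment_unit_cost(m) / scale, rel=1e-9)


class TestIndexation:
    def test_identity_for_2024(self):
        assert index_to_2024(100.0, 2024, {}) == 100.0

    def test_chained_product(self):
        # 100 x 1.03 x 1.02
        out = index_to_2024(100.0, 2022, {2022: 1.03, 2023: 1.02})
        assert out == pytest.approx(105.06, abs=0.01)

    def test_zero_amount(self):
        assert index_to_2024(0.0, 2019, {y: 1.1 for y in range(2019, 2024)}) == 0.0

    def test_missing_year_errors(self):
        with pytest.raises(KeyError):
            index_to_2024(100.0, 2022, {2023: 1.02})


class TestDiscounting:
    def test_cycle_zero_undiscounted(self):
        assert discount_factor(0.04, 0) == 1.0

    def test_one_cycle(self):
        assert discount_factor(0.04, 1) == pytest.approx(0.96154, abs=1e-5)

    def test_zero_rate(self):
        assert all(discount_factor(0.0, k) == 1.0 for k in range(40))

    def test_pathological_rate(self):
        with pytest.raises(ValueError):
            discount_factor(-1.5, 1)


class TestIcer:
    def test_cheaper_and_better_dominates(self):
        r = compute_icer(outcomes(100, 2), outcomes(200, 1))
        assert (r.delta_cost, r.delta_effect) == (-100, 1)
        assert r.icer == -100 and r.dominance == "dominant"

    def test_identical_outcomes_indifferent(self):
        r = compute_icer(outcomes(100, 2), outcomes(100, 2))
        assert r.icer is None and r.dominance == "indifferent"

    def test_quadrants(self):
        assert compute_icer(outcomes(200, 1), outcomes(100, 2)).dominance == \
            "dominated"
        assert compute_icer(outcomes(200, 2), outcomes(100, 1)).dominance == \
            "tradeoff_NE"
        assert compute_icer(outcomes(100, 1), outcomes(200, 2)).dominance == \
            "tradeoff_SW"

    def test_antisymmetric_in_swap(self):
        a, b = outcomes(120, 2.5), outcomes(80, 1.5)
        fwd, rev = compute_icer(a, b), compute_icer(b, a)
        assert fwd.delta_cost == -rev.delta_cost
        assert fwd.delta_effect == -rev.delta_effect
        assert fwd.icer == pytest.approx(rev.icer)

    def test_mixed_perspectives_rejected(self):
        with pytest.raises(ValueError):
            compute_icer(outcomes(1, 1, "hospital"), outcomes(1, 1, "societal"))


class TestThreshold:
    def test_dominant_passes(self):
        assert threshold_check(compute_icer(outcomes(100, 2), outcomes(200, 1)))

    def test_expensive_gain_fails(self):
        r = compute_icer(outcomes(125000, 6), outcomes(100000, 5))  # 25k/QALY
        assert not threshold_check(r)

    def test_boundary_inclusive(self):
        r = compute_icer(outcomes(120000, 6), outcomes(100000, 5))  # 20k/QALY
        assert threshold_check(r)

    def test_cost_saving_qaly_losing_fails(self):
        r = compute_icer(outcomes(100, 1), outcomes(200, 2))
        assert not threshold_check(r)
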