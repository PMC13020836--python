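import pandas as pd
import pytest

from oamarkov.analyses import (apply_scenario, one_way_sensitivity,
                               relative_reduction, run_all)
from oamarkov.parameters import ConfigurationError, to_yaml


class TestScenarios:
    def test_overrides(self, baseline):
        base = baseline("hospital", "hiMSC_auto")
        assert apply_scenario(1, base).config.redo_treatment is False
        assert apply_scenario(2, base).transitions.rows["Healthy"]["KL_I"] == \
            pytest.approx(0.04345)
        assert apply_scenario(3, base).config.effectiveness == 0.76
        assert apply_scenario(4, base).config.treatment_target_state == "KL_I"

    def test_pure_overrides_do_not_mutate_input(self, baseline):
        base = baseline("hospital", "hiMSC_auto")
        snapshot = to_yaml(base)
        for sid in (1, 2, 3, 4):
            apply_scenario(sid, base)
        assert to_yaml(base) == snapshot

    def test_unknown_id(self, baseline):
        with pytest.raises(ConfigurationError):
            apply_scenario(5, baseline())


class TestRunAll:
    def test_requires_comparator(self, baseline):
        with pytest.raises(ConfigurationError):
            run_all({"hiMSC_auto": baseline("hospital", "hiMSC_auto")})

    def test_mixed_perspectives_rejected(self, baseline):
        with pytest.raises(ConfigurationError):
            run_all({"SoC": baseline("hospital", "SoC"),
                     "hiMSC_auto": baseline("societal", "hiMSC_auto")})

    def test_base_case_table_shape(self, baseline):
        df = run_all({arm: baseline("hospital", arm)
                      for arm in ("SoC", "hiMSC_auto", "hiMSC_EV_auto")})
        assert len(df) == 3
        soc = df[df.arm == "SoC"].iloc[0]
        assert pd.isna(soc.icer_vs_soc)  # no comparator for SoC itself
        treated = df[df.arm != "SoC"]
        assert (treated.qalys > soc.qalys).all()
        assert (treated.tkr_per_1000 < soc.tkr_per_1000).all()

    def test_deterministic(self, baseline):
        args = {arm: baseline("hospital", arm) for arm in ("SoC", "hiMSC_auto")}
        assert run_all(args).equals(run_all(args))


class TestRelativeReduction:
    @pytest.mark.parametrize("treated,soc,expected", [
        (426, 609, 30.0), (19, 30, 36.7), (17, 17, 0.0)])
    def test_published_examples(self, treated, soc, expected):
        assert relative_reduction(treated, soc) == expected

    def test_zero_comparator_undefined(self):
        with pytest.raises(ZeroDivisionError):
            relative_reduction(5, 0)


@pytest.fixture(scope="module")
def small_tornado(_baseline_cache):
    params = _baseline_cache("hospital", "hiMSC_auto").copy()
    names = ["c_KLII", "c_KLI", "c_Healthy", "u_KLII", "p_KLII_KLII",
             "p_KLII_Healthy_MSC"]
    return one_way_sensitivity(params, "hiMSC_auto", "hospital",
                               parameter_names=names), names


class TestTornado:
    def test_output_is_permutation_of_inputs(self, small_tornado):
        table, names = small_tornado
        assert sorted(e.parameter for e in table.entries) == sorted(names)
        assert [r for r, _ in table.ranked()] == list(range(1, len(names) + 1))

    def test_sorted_by_range_descending(self, small_tornado):
        table, _ = small_tornado
        ranges = [e.range for e in table.entries]
        assert ranges == sorted(ranges, reverse=True)

    def test_zero_width_bounds_rank_last(self, small_tornado):
        table, _ = small_tornado
        # the Healthy state cost is pinned at zero, and utilities cannot
        # move a pure cost metric: both must fall to the bottom with range 0
        bottom = {e.parameter for e in table.entries if e.range == 0.0}
        assert {"c_Healthy", "u_KLII"} <= bottom

    def test_missing_bounds_error_names_parameter(self, baseline):
        with pytest.raises(ConfigurationError, match="c_unicorn"):
            one_way_sensitivity(baseline(), "SoC", "hospital",
                                parameter_names=["c_unicorn"])

    def test_deterministic_ranks(self, small_tornado, _baseline_cache):
        table, names = small_tornado
        again = one_way_sensitivity(_baseline_cache("hospital", "hiMSC_auto").copy(),
                                    "hiMSC_auto", "hospital",
                                    parameter_names=names)
        assert [e.parameter for e in again.entries] == \
            [e.parameter for e in table.entries]
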