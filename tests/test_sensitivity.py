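"""Tornado analysis and named scenario variants."""

import pytest

from tdmcost import incremental_cost, load_fixture, scenario_variant, tornado
from tdmcost.parameters import ConfigurationError
from tdmcost.sensitivity import _with_cost_mean, _with_transition_mean
from tdmcost.synthetic import GeneratorSpec, generate_scenario


def test_tornado_rows_match_direct_recomputation(base_configs, schedule):
    """Each row is re-derivable by perturbing the config and calling
    incremental_cost directly; the tornado must match that oracle exactly."""
    config = base_configs[2]
    rows = {r.variable_code: r for r in tornado(config, schedule)}
    for arm, transitions in config.transitions.items():
        for code, t in transitions.items():
            row = rows[code]
            for bound, got in ((t.low, row.incremental_at_low), (t.high, row.incremental_at_high)):
                want = incremental_cost(_with_transition_mean(config, arm, code, bound), schedule)
                assert got == want
    for code, c in config.costs.items():
        row = rows[code]
        for bound, got in ((c.low, row.incremental_at_low), (c.high, row.incremental_at_high)):
            assert got == incremental_cost(_with_cost_mean(config, code, bound), schedule)


def test_tornado_sorted_by_impact_with_alphabetical_ties(base_configs, schedule):
    rows = tornado(base_configs[1], schedule)
    spans = [r.span if r.span > 1e-9 else 0.0 for r in rows]
    assert spans == sorted(spans, reverse=True)
    flat = [r.variable_code for r in rows if r.span <= 1e-9]
    assert flat == sorted(flat)


def test_tornado_analysis1_reproduces_reference_rows(base_configs, schedule, reference):
    """The influential analysis-1 rows match the reference table to the
    printed euro."""
    rows = {r.variable_code: r for r in tornado(base_configs[1], schedule)}
    for code, (lo, hi) in reference["tornado_analysis1"].items():
        got = sorted((rows[code].incremental_at_low, rows[code].incremental_at_high))
        assert got[0] == pytest.approx(lo, abs=1.0), code
        assert got[1] == pytest.approx(hi, abs=1.0), code


def test_shared_and_inert_variables_leave_incremental_flat(base_configs, schedule):
    """Costs shared by both arms (CE1L, CDUCI) and second-stage transitions
    produce rows equal to the base incremental at both extremes."""
    config = base_configs[1]
    base = incremental_cost(config, schedule)
    rows = {r.variable_code: r for r in tornado(config, schedule)}
    for code in ("CE1L", "CDUCI", "CDHOSP", "CEFT", "CMCTDM", "CSSTDM", "FCCTDM", "FMSTDM"):
        assert rows[code].incremental_at_low == pytest.approx(base, abs=1e-9)
        assert rows[code].incremental_at_high == pytest.approx(base, abs=1e-9)


def test_analysis3_tornado_shows_savings_almost_everywhere(base_configs, schedule):
    """Analysis 3 saves money at every tornado extreme except the one the
    reference table itself prints positive: the cured-with-TDM stay cost at
    its upper bound (+€223)."""
    for row in tornado(base_configs[3], schedule):
        if row.variable_code == "CECT":
            assert row.incremental_at_low < 0
            assert row.incremental_at_high == pytest.approx(223, abs=1.0)
        else:
            assert row.incremental_at_low < 0
            assert row.incremental_at_high < 0


def test_cost_rows_are_affine(base_configs, schedule):
    """For every cost variable the incremental at the bounds' midpoint equals
    the mean of the two extreme incrementals."""
    config = base_configs[2]
    for code, c in config.costs.items():
        mid = incremental_cost(_with_cost_mean(config, code, (c.low + c.high) / 2), schedule)
        lo = incremental_cost(_with_cost_mean(config, code, c.low), schedule)
        hi = incremental_cost(_with_cost_mean(config, code, c.high), schedule)
        assert mid == pytest.approx((lo + hi) / 2, abs=0.01)


def test_tornado_of_identical_arms_is_symmetric(schedule):
    """With identical arms, shared variables are flat, CTDM alone shifts the
    incremental, and each arm-specific variable mirrors its counterpart in
    the other arm (equal span, opposite direction)."""
    scenario = generate_scenario(
        GeneratorSpec(seed=3, cure_advantage_range=(0.0, 0.0), equal_arm_costs=True),
        label="identical_arms",
    )
    rows = {r.variable_code: r for r in tornado(scenario, schedule)}
    for code in ("CE1L", "CEFST", "CEFT", "CDUCI"):
        assert rows[code].span == pytest.approx(0.0, abs=1e-9)
    assert rows["CTDM"].span > 0
    base = schedule.cycle_factor * schedule.tdm_weight * scenario.cost("CTDM").mean
    for with_code, without_code in (("ICCTDM", "ICSTDM"), ("IMCTDM", "IMSTDM"),
                                    ("CECT", "CECST")):
        w, wo = rows[with_code], rows[without_code]
        assert w.span == pytest.approx(wo.span, rel=1e-9)
        # perturbing one arm moves the incremental away from the base value
        # by the same amount, in opposite directions
        assert (w.incremental_at_low - base) == pytest.approx(
            -(wo.incremental_at_low - base), abs=1e-9)


def test_scenario_variant_base_is_identity(base_configs):
    assert scenario_variant(base_configs[1], "base") == base_configs[1]


def test_scenario_variant_unknown_raises(base_configs):
    with pytest.raises(ConfigurationError):
        scenario_variant(base_configs[1], "imipenem_2l")


@pytest.mark.parametrize("analysis,expected_sign", [(1, 1), (2, -1), (3, -1)])
@pytest.mark.parametrize("variant", ["base", "vancomycin_1l2l", "cefiderocol_2l", "betalactam_stay"])
def test_variants_preserve_result_direction(schedule, analysis, expected_sign, variant):
    """Extra expenditure in analysis 1, savings in analyses 2 and 3, under
    every scenario variant."""
    inc = incremental_cost(load_fixture(analysis, variant), schedule)
    assert inc * expected_sign > 0


@pytest.mark.parametrize(
    "analysis,variant,expected",
    [
        (3, "cefiderocol_2l", -1036),
        (1, "cefiderocol_2l", 27),
        (2, "cefiderocol_2l", -545),
        (1, "vancomycin_1l2l", 253),
        (2, "vancomycin_1l2l", -214),
        (1, "betalactam_stay", 350),
        (2, "betalactam_stay", -189),
        (3, "betalactam_stay", -666),
    ],
)
def test_variant_incrementals_match_reference(schedule, analysis, variant, expected):
    inc = incremental_cost(load_fixture(analysis, variant), schedule)
    assert inc == pytest.approx(expected, abs=1.5)
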