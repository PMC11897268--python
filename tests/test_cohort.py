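"""Cohort evaluation, accrual calibration, and the path-enumeration oracle."""

import numpy as np
import pytest

from tdmcost import (
    AccrualSchedule,
    calibrate_schedule,
    default_schedule,
    incremental_cost,
    reference_targets,
    run_cohort,
)
from tdmcost.cohort import second_line_drug_cost
from tdmcost.parameters import ARMS
from tdmcost.synthetic import GeneratorSpec, generate_scenario


def path_enumeration_cost(config, arm, schedule):
    """Independent oracle: enumerate every patient path through the two-stage
    tree and sum path probability x path cost.

    Paths: 1L->cure->{discharge,death}, 1L->failure->{cure,death}, 1L->death.
    Episode costs attach to the stage-1 destination (stay totals span the
    whole episode); every path accrues the 1L stay, 1L antibiotics and - in
    the with-TDM arm - the weighted TDM cost.
    """
    f = schedule.cycle_factor
    suffix = "CTDM" if arm == "with_tdm" else "STDM"
    cure = config.transition(arm, "IC" + suffix).mean
    death = config.transition(arm, "IM" + suffix).mean
    if schedule.failure_prob_mode == "complement":
        fail = max(1.0 - cure - death, 0.0)
    elif schedule.failure_prob_mode == "printed":
        fail = config.transition(arm, "IF" + suffix).mean
    else:
        total = cure + death + config.transition(arm, "IF" + suffix).mean
        cure, death = cure / total, death / total
        fail = 1.0 - cure - death
    cm = config.transition(arm, "CM" + suffix).mean
    fc = config.transition(arm, "FC" + suffix).mean

    shared = config.cost("CE1L").mean + config.first_line_drug_cost()
    tdm = schedule.tdm_weight * config.cost("CTDM").mean if arm == "with_tdm" else 0.0
    cure_stay = config.cost("CECT" if arm == "with_tdm" else "CECST").mean
    if schedule.failure_stay_shared:
        fail_stay = config.cost("CEFST").mean
    else:
        fail_stay = config.cost("CEFT" if arm == "with_tdm" else "CEFST").mean
    ab2 = second_line_drug_cost(config, schedule)
    death_extra = schedule.death_stay_weight * config.cost("CE1L").mean

    paths = [
        (cure * (1.0 - cm), shared + cure_stay),          # cure -> discharge
        (cure * cm, shared + cure_stay),                  # cure -> death
        (fail * fc, shared + fail_stay + ab2),            # failure -> cure
        (fail * (1.0 - fc), shared + fail_stay + ab2),    # failure -> death
        (death, shared + death_extra),                    # death during 1L
    ]
    return sum(p * (f * c + tdm * f) for p, c in paths)


def test_cohort_matches_path_enumeration_on_synthetic_scenarios(schedule):
    """Expected cost equals the brute-force path sum to 1e-9 on 100 random
    scenarios."""
    rng = np.random.default_rng(20240915)
    spec = GeneratorSpec(seed=1, cure_advantage_range=(0.0, 0.2))
    for _ in range(100):
        scenario = generate_scenario(spec, rng=rng)
        for arm in ARMS:
            got = run_cohort(scenario, arm, schedule).expected_cost
            want = path_enumeration_cost(scenario, arm, schedule)
            assert got == pytest.approx(want, abs=1e-9)


def test_occupancy_conserved_and_breakdown_sums(base_configs, schedule):
    for config in base_configs.values():
        for arm in ARMS:
            ev = run_cohort(config, arm, schedule)
            # as-printed analysis-3 first-line row deviates from the simplex;
            # the complement closure restores conservation at stage 1
            assert sum(ev.state_occupancy[0].values()) == pytest.approx(1.0, abs=1e-12)
            assert sum(ev.state_occupancy[1].values()) == pytest.approx(1.0, abs=1e-12)
            assert ev.expected_cost == pytest.approx(sum(ev.cost_breakdown.values()), abs=1e-9)
            assert (ev.cost_breakdown["tdm"] > 0) == (arm == "with_tdm")


def test_identical_arms_and_zero_tdm_has_zero_incremental(schedule):
    scenario = generate_scenario(
        GeneratorSpec(seed=5, cure_advantage_range=(0.0, 0.0),
                      equal_arm_costs=True, tdm_unit_cost=1e-9),
        label="identical_arms",
    )
    assert incremental_cost(scenario, schedule) == pytest.approx(0.0, abs=1e-6)


def test_expected_cost_is_homogeneous_in_costs(base_configs, schedule):
    """Doubling every cost parameter and every vial price doubles the
    expected cost exactly."""
    config = base_configs[1]
    costs = {c.code: c.model_copy(update={"mean": 2 * c.mean, "low": 2 * c.low,
                                          "high": 2 * c.high})
             for c in config.costs.values()}
    double = config.model_copy(update={
        "costs": costs,
        "regimens_1l": [r.model_copy(update={"vial_price": 2 * r.vial_price})
                        for r in config.regimens_1l],
        "second_line_options": [
            [r.model_copy(update={"vial_price": 2 * r.vial_price}) for r in opt]
            for opt in config.second_line_options
        ],
    })
    for arm in ARMS:
        assert run_cohort(double, arm, schedule).expected_cost == pytest.approx(
            2 * run_cohort(config, arm, schedule).expected_cost, rel=1e-9)


def test_shifting_cure_to_failure_never_cheapens_an_arm(base_configs, schedule):
    """With failure accruing more than cure, moving probability mass from
    cure to failure increases that arm's expected cost."""
    config = base_configs[1]
    base_cost = run_cohort(config, "with_tdm", schedule).expected_cost
    transitions = {a: dict(ts) for a, ts in config.transitions.items()}
    icc = transitions["with_tdm"]["ICCTDM"]
    transitions["with_tdm"]["ICCTDM"] = icc.model_copy(update={"mean": icc.mean - 0.05})
    shifted = config.model_copy(update={"transitions": transitions})
    assert run_cohort(shifted, "with_tdm", schedule).expected_cost > base_cost


def test_calibration_selects_documented_schedule(base_configs, reference):
    result = calibrate_schedule(list(base_configs.values()), reference_targets(reference))
    assert result.schedule == default_schedule()
    assert result.max_residual < 0.5
    assert len(result.residuals) == 6
    assert result.n_candidates > 50


def test_calibration_reports_residuals_for_imperfect_targets(base_configs):
    """Unreachable targets still return the best candidate, with residuals."""
    targets = [(1, "with_tdm", 1.0), (1, "without_tdm", 1.0)]
    result = calibrate_schedule([base_configs[1]], targets)
    assert result.max_residual > 1000
    assert set(result.residuals) == {"analysis1:with_tdm", "analysis1:without_tdm"}


def test_failure_prob_modes_differ_only_where_tables_deviate(base_configs):
    """Analyses 1-2 store exact simplexes, so printed and complement modes
    agree; the analysis-3 without-TDM row differs by its printed deficit."""
    printed = AccrualSchedule(failure_prob_mode="printed")
    comp = AccrualSchedule(failure_prob_mode="complement")
    for aid in (1, 2):
        assert incremental_cost(base_configs[aid], printed) == pytest.approx(
            incremental_cost(base_configs[aid], comp), abs=1e-9)
    c3 = base_configs[3]
    gap = (run_cohort(c3, "without_tdm", comp).expected_cost
           - run_cohort(c3, "without_tdm", printed).expected_cost)
    assert gap > 500  # 0.0384 of the cohort re-costed as failure
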