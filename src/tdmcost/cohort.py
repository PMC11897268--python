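"""Deterministic two-stage Markov cohort evaluation.

The whole cohort starts first-line (1L) antibiotic treatment.  Stage one
distributes it over cure, treatment failure (second line, 2L) and death;
stage two resolves cure into hospital discharge or death (background
mortality) and failure into cure after second-line treatment or death.
Discharge and death are absorbing.

Cost accrual is governed by an explicit :class:`AccrualSchedule` rather than
hard-coded, because a state-transition cost model of this kind has several
defensible accrual conventions (half-cycle correction, whether the failure
stay is costed per arm or from a single tariff, whether the failure share of
the first-line cohort is read from the table or closed as the simplex
complement).  :func:`calibrate_schedule` searches the documented finite grid
of such conventions against reference arm costs and reports residuals; the
packaged default is the calibrated optimum, which reproduces the reference
deterministic results within half a euro.

Stay costs in the tables are episode totals, not per-cycle increments, so
each stage-one destination accrues its full episode cost once; stage-two
survivors of failure accrue nothing further (the failure stay already spans
the whole episode).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .parameters import (
    ARMS,
    Arm,
    HealthState,
    ScenarioConfig,
)

FailureProbMode = Literal["complement", "printed", "normalized"]


class EvaluationError(ValueError):
    """Scenario cannot be evaluated under the requested schedule."""


class AccrualSchedule(BaseModel):
    """Which costs accrue in which state, and with what weight.

    cycle_factor
        Global weight applied to every accrued cost (0.5 = half-cycle
        correction applied uniformly; the calibrated value).
    tdm_weight
        Weight of the TDM unit cost inside the cycle factor (with-TDM arm
        only); effective weight = cycle_factor * tdm_weight.
    second_line_blend
        Weight of the first second-line regimen option; remaining weight is
        spread uniformly over the other options.
    failure_stay_shared
        If true, both arms accrue the without-TDM failure-stay tariff
        (CEFST); otherwise each arm uses its own (CEFT / CEFST).
    failure_prob_mode
        How the failure share of the first-line cohort is obtained:
        ``complement`` = 1 - P(cure) - P(death) (exact simplex closure),
        ``printed`` = the stored table value, ``normalized`` = stored values
        rescaled to sum to one.
    death_stay_weight
        Extra fraction of the first-line stay cost accrued by stage-one
        deaths on top of the cohort-wide 1L stay (0 = deaths accrue only the
        shared 1L episode cost).
    """

    model_config = ConfigDict(frozen=True)

    cycle_factor: float = Field(default=0.5, ge=0.0, le=1.0)
    tdm_weight: float = Field(default=1.0, ge=0.0, le=1.0)
    second_line_blend: float = Field(default=0.5, ge=0.0, le=1.0)
    failure_stay_shared: bool = True
    failure_prob_mode: FailureProbMode = "complement"
    death_stay_weight: float = Field(default=0.0, ge=0.0, le=1.0)


def default_schedule() -> AccrualSchedule:
    """The calibrated accrual schedule (see :func:`calibrate_schedule`)."""
    return AccrualSchedule()


class ArmEvaluation(BaseModel):
    """Expected cost and state occupancy for one arm of one scenario."""

    model_config = ConfigDict(frozen=True)

    arm: Arm
    expected_cost: float
    state_occupancy: list[dict[str, float]]
    cost_breakdown: dict[str, float]


def _stage1_shares(
    config: ScenarioConfig, arm: Arm, schedule: AccrualSchedule,
    overrides: Mapping[str, float] | None = None,
) -> tuple[float, float, float]:
    """(cure, death, failure) shares of the first-line cohort."""
    cure, death, failure = config.stage1_means(arm)
    if overrides:
        suffix = "CTDM" if arm == "with_tdm" else "STDM"
        cure = overrides.get("IC" + suffix, cure)
        death = overrides.get("IM" + suffix, death)
        failure = overrides.get("IF" + suffix, failure)
    if schedule.failure_prob_mode == "complement":
        # Clip at zero: independent beta draws of cure and death can, very
        # rarely, sum above one; the truncation bias is negligible at the
        # fixture dispersions (affected fraction ~1e-4).
        failure = np.maximum(1.0 - cure - death, 0.0)
        if np.ndim(failure) == 0:
            failure = float(failure)
    elif schedule.failure_prob_mode == "normalized":
        total = cure + death + failure
        if total <= 0:
            raise EvaluationError(f"{arm}: degenerate stage-1 probabilities")
        cure, death, failure = cure / total, death / total, failure / total
    return cure, death, failure


def second_line_drug_cost(config: ScenarioConfig, schedule: AccrualSchedule) -> float:
    """Blended acquisition cost of second-line treatment."""
    options = config.second_line_option_costs()
    if len(options) == 1:
        return options[0]
    w = schedule.second_line_blend
    rest = (1.0 - w) / (len(options) - 1)
    return w * options[0] + rest * sum(options[1:])


def arm_cost_components(
    config: ScenarioConfig, arm: Arm, schedule: AccrualSchedule,
    values: Mapping[str, float] | None = None,
):
    """Cost breakdown for one arm; the single source of truth for accrual.

    ``values`` optionally overrides parameter values by code (scalars or
    numpy arrays — the arithmetic broadcasts), which is how the PSA and the
    tornado reuse the deterministic accrual unchanged.
    """
    values = values or {}

    def cost_of(code: str) -> float:
        return values.get(code, config.cost(code).mean)

    cure, death, failure = _stage1_shares(config, arm, schedule, overrides=values)
    cure_stay = cost_of("CECT" if arm == "with_tdm" else "CECST")
    if schedule.failure_stay_shared:
        fail_stay = cost_of("CEFST")
    else:
        fail_stay = cost_of("CEFT" if arm == "with_tdm" else "CEFST")
    ab2 = values.get("AB2L", second_line_drug_cost(config, schedule))
    f = schedule.cycle_factor
    breakdown = {
        "stay_1L": f * cost_of("CE1L"),
        "antibiotics_1L": f * config.first_line_drug_cost(),
        "stay_cure": f * cure * cure_stay,
        "stay_failure": f * failure * fail_stay,
        "antibiotics_2L": f * failure * ab2,
        "stay_death": f * death * schedule.death_stay_weight * cost_of("CE1L"),
        "tdm": f * schedule.tdm_weight * cost_of("CTDM") if arm == "with_tdm" else 0.0,
    }
    return breakdown, (cure, death, failure)


def run_cohort(
    config: ScenarioConfig, arm: Arm, schedule: AccrualSchedule | None = None
) -> ArmEvaluation:
    """Evaluate one arm deterministically at the parameter means."""
    schedule = schedule or default_schedule()
    breakdown, (cure, death, failure) = arm_cost_components(config, arm, schedule)
    suffix = "CTDM" if arm == "with_tdm" else "STDM"
    cure_death = config.transition(arm, "CM" + suffix).mean
    fail_cure = config.transition(arm, "FC" + suffix).mean
    occupancy = [
        {
            HealthState.CURE.value: cure,
            HealthState.FAILURE_2L.value: failure,
            HealthState.DEATH.value: death,
        },
        {
            HealthState.DISCHARGE.value: cure * (1.0 - cure_death),
            HealthState.CURE.value: failure * fail_cure,
            HealthState.DEATH.value: death + cure * cure_death + failure * (1.0 - fail_cure),
        },
    ]
    return ArmEvaluation(
        arm=arm,
        expected_cost=float(sum(breakdown.values())),
        state_occupancy=occupancy,
        cost_breakdown={k: float(v) for k, v in breakdown.items()},
    )


def incremental_cost(config: ScenarioConfig, schedule: AccrualSchedule | None = None) -> float:
    """Expected with-TDM cost minus without-TDM cost; negative = savings."""
    schedule = schedule or default_schedule()
    return (
        run_cohort(config, "with_tdm", schedule).expected_cost
        - run_cohort(config, "without_tdm", schedule).expected_cost
    )


class CalibrationResult(BaseModel):
    """Outcome of the schedule grid search, residuals included."""

    model_config = ConfigDict(frozen=True)

    schedule: AccrualSchedule
    residuals: dict[str, float]
    max_residual: float
    n_candidates: int


def candidate_schedules() -> list[AccrualSchedule]:
    """The documented finite grid of accrual conventions."""
    grid = itertools.product(
        (0.5, 1.0),            # cycle_factor
        (0.5, 1.0),            # tdm_weight
        (0.0, 0.5, 1.0),       # second_line_blend
        (True, False),         # failure_stay_shared
        ("complement", "printed"),  # failure_prob_mode
        (0.0, 0.5, 1.0),       # death_stay_weight
    )
    return [
        AccrualSchedule(
            cycle_factor=c, tdm_weight=t, second_line_blend=b,
            failure_stay_shared=s, failure_prob_mode=m, death_stay_weight=d,
        )
        for c, t, b, s, m, d in grid
    ]


def calibrate_schedule(
    configs: Sequence[ScenarioConfig],
    targets: Iterable[tuple[int, Arm, float]],
) -> CalibrationResult:
    """Pick the candidate schedule minimizing the max deviation from targets.

    ``targets`` are (analysis_id, arm, expected_cost) triples, typically the
    six reference deterministic arm costs.  Always returns the best candidate
    together with its per-target residuals; nothing is hidden when the fit is
    imperfect.
    """
    by_analysis = {c.analysis_id: c for c in configs}
    targets = list(targets)
    best: CalibrationResult | None = None
    candidates = candidate_schedules()
    for schedule in candidates:
        residuals: dict[str, float] = {}
        for analysis_id, arm, expected in targets:
            got = run_cohort(by_analysis[analysis_id], arm, schedule).expected_cost
            residuals[f"analysis{analysis_id}:{arm}"] = got - expected
        worst = max((abs(v) for v in residuals.values()), default=0.0)
        if best is None or worst < best.max_residual:
            best = CalibrationResult(
                schedule=schedule, residuals=residuals,
                max_residual=worst, n_candidates=len(candidates),
            )
    assert best is not None
    return best


def reference_targets(reference: Mapping) -> list[tuple[int, Arm, float]]:
    """Flatten the packaged reference deterministic arm costs into targets."""
    out: list[tuple[int, Arm, float]] = []
    for aid, row in reference["deterministic"].items():
        for arm in ARMS:
            out.append((int(aid), arm, float(row[arm])))
    return out
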