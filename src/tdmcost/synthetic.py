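"""Random, internally coherent scenarios for property testing.

The generator emulates the statistical structure the cost model assumes —
per-source-state probability vectors on the simplex with beta-feasible
standard deviations, and positive, mildly skewed costs with gamma-compatible
coefficients of variation — without copying any real parameter table.  The
default dispersion and effect-size ranges are chosen to resemble a plausible
ICU antimicrobial episode: cure probabilities around one half to two thirds,
an ICU episode costing on the order of ten thousand euros, failure episodes
costing about twice a cured episode, and a TDM advantage on the cure rate of
a few to twenty percentage points.

Scenarios can be generated with qualitative labels attached at construction
time ("tdm_dominant", "identical_arms"), so downstream checks can assert the
sign of the incremental cost against a property that is true by construction
rather than inferred after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    AntibioticRegimen,
    CostParameter,
    ScenarioConfig,
    StayParameter,
    StayRole,
    TransitionProbability,
)


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    """Knobs of the scenario generator.

    probability_concentration scales the Dirichlet draws for the stage-one
    simplex (larger = tighter around the prior shares); sd_fraction sets each
    probability's SD as a fraction of its beta-feasibility bound
    sqrt(mean*(1-mean)), guaranteeing feasibility by construction.
    """

    seed: int = 0
    n_scenarios: int = 1
    probability_concentration: float = 12.0
    cost_cv_range: tuple[float, float] = (0.05, 0.15)
    cure_advantage_range: tuple[float, float] = (0.03, 0.20)
    stay_cost_ordering: bool = True
    sd_fraction: float = 0.3
    tdm_unit_cost: float | None = None
    equal_arm_costs: bool = False

    def __post_init__(self) -> None:
        if self.probability_concentration <= 0:
            raise GenerationError("probability_concentration must be positive")
        for lo, hi in (self.cost_cv_range, self.cure_advantage_range):
            if lo > hi:
                raise GenerationError("range bounds out of order")
        if self.cure_advantage_range[1] >= 0.95:
            raise GenerationError("cure advantage range forces probabilities out of [0,1]")


@dataclass(frozen=True)
class LabelledScenario:
    scenario: ScenarioConfig
    label: str
    details: dict = field(default_factory=dict)


def _beta_sd(mean: float, fraction: float, rng: np.random.Generator) -> float:
    bound = np.sqrt(mean * (1.0 - mean))
    return float(fraction * rng.uniform(0.5, 1.0) * bound)


def _transition(code, frm, to, mean, sd) -> TransitionProbability:
    half = min(1.96 * sd, mean, 1.0 - mean) if 0 < mean < 1 else 0.0
    return TransitionProbability(
        code=code, from_state=frm, to_state=to, mean=mean,
        low=max(mean - half, 0.0), high=min(mean + half, 1.0), sd=sd,
    )


def _cost(code, mean, cv) -> CostParameter:
    sd = mean * cv
    r2 = lambda x: round(x, 2) if x >= 0.01 else x  # noqa: E731 - keep tiny means exact
    return CostParameter(
        code=code, mean=r2(mean),
        low=r2(max(mean - 1.96 * sd, mean * 0.2)),
        high=r2(mean + 1.96 * sd),
        sd=r2(sd) if sd > 0 else None,
    )


def generate_scenario(
    spec: GeneratorSpec,
    rng: np.random.Generator | None = None,
    label: str = "unconstrained",
) -> ScenarioConfig:
    """One coherent random scenario; same spec and seed => same scenario."""
    rng = rng or np.random.default_rng(spec.seed)
    conc = spec.probability_concentration

    # Stage-1 simplex for the without-TDM arm: (cure, death, failure).
    prior = np.array([0.45, 0.2, 0.35]) if label == "tdm_dominant" else np.array([0.5, 0.25, 0.25])
    p_wo = rng.dirichlet(conc * prior)
    advantage = float(rng.uniform(*spec.cure_advantage_range))
    cure_wo, death_wo, fail_wo = map(float, p_wo)
    if label == "identical_arms":
        cure_w, death_w, fail_w = cure_wo, death_wo, fail_wo
    elif label == "tdm_dominant":
        # Entire cure advantage comes out of treatment failure, so with
        # failure costlier than cure the dominance sign holds by construction.
        advantage = min(advantage, 0.8 * fail_wo)
        cure_w = cure_wo + advantage
        death_w = death_wo
        fail_w = fail_wo - advantage
    else:
        cure_w = cure_wo + advantage
        cap = 0.995
        if cure_w > cap:
            if cap - advantage <= 0:
                raise GenerationError("cure advantage leaves no room for the without-TDM arm")
            cure_wo = cap - advantage
            rest = 1.0 - cure_wo
            total = death_wo + fail_wo
            death_wo, fail_wo = rest * death_wo / total, rest * fail_wo / total
            cure_w = cap
        rest_w = 1.0 - cure_w
        total = death_wo + fail_wo
        death_w, fail_w = rest_w * death_wo / total, rest_w * fail_wo / total

    # Stage-2: cure -> death (background mortality), failure -> cure.
    cm = float(rng.uniform(0.002, 0.01))
    fc = float(rng.uniform(0.6, 0.9))

    def arm_transitions(suffix, cure, death, fail):
        frac = spec.sd_fraction
        sd_cure = _beta_sd(cure, frac, rng)
        sd_death = _beta_sd(death, frac, rng)
        # Keep five joint SDs of headroom below the simplex boundary so the
        # failure complement 1 - cure - death stays positive in essentially
        # every PSA draw (constructive feasibility, not rejection).
        allowed = fail / 5.0
        if sd_cure + sd_death > allowed > 0:
            scale = allowed / (sd_cure + sd_death)
            sd_cure *= scale
            sd_death *= scale
        return {
            "IC" + suffix: _transition("IC" + suffix, "treatment_1L", "cure",
                                       cure, sd_cure),
            "IM" + suffix: _transition("IM" + suffix, "treatment_1L", "death",
                                       death, sd_death),
            "IF" + suffix: _transition("IF" + suffix, "treatment_1L", "failure_2L",
                                       fail, _beta_sd(fail, frac, rng)),
            "CM" + suffix: _transition("CM" + suffix, "cure", "death",
                                       cm, _beta_sd(cm, frac, rng)),
            "CS" + suffix: _transition("CS" + suffix, "cure", "discharge",
                                       1.0 - cm, _beta_sd(1.0 - cm, frac, rng)),
            "FC" + suffix: _transition("FC" + suffix, "failure_2L", "cure",
                                       fc, _beta_sd(fc, frac, rng)),
            "FM" + suffix: _transition("FM" + suffix, "failure_2L", "death",
                                       1.0 - fc, _beta_sd(1.0 - fc, frac, rng)),
        }

    without = arm_transitions("STDM", cure_wo, death_wo, fail_wo)
    if label == "identical_arms":
        # Clone the without-TDM arm (same means, SDs and bounds) so the two
        # arms differ only in parameter codes.
        with_arm = {
            code[:2] + "CTDM": t.model_copy(update={"code": code[:2] + "CTDM"})
            for code, t in without.items()
        }
    else:
        with_arm = arm_transitions("CTDM", cure_w, death_w, fail_w)
    transitions = {"with_tdm": with_arm, "without_tdm": without}

    cv = float(rng.uniform(*spec.cost_cv_range))
    unit = float(rng.uniform(900.0, 1900.0))
    days_1l = float(rng.uniform(6.0, 12.0))
    days_cure_w = days_1l * float(rng.uniform(1.0, 1.6))
    days_cure_wo = days_cure_w if spec.equal_arm_costs else days_1l * float(rng.uniform(1.0, 1.6))
    lo_mult, hi_mult = (1.9, 3.2) if spec.stay_cost_ordering else (0.8, 3.2)
    days_fail = days_1l * float(rng.uniform(lo_mult, hi_mult))
    if spec.stay_cost_ordering:
        days_fail = max(days_fail, 1.05 * max(days_cure_w, days_cure_wo))
    tdm_cost = spec.tdm_unit_cost if spec.tdm_unit_cost is not None else float(rng.uniform(80.0, 260.0))
    tdm_cost = max(tdm_cost, 1e-9)

    costs = {
        "CE1L": _cost("CE1L", days_1l * unit, cv),
        "CECT": _cost("CECT", days_cure_w * unit, cv),
        "CECST": _cost("CECST", days_cure_wo * unit, cv),
        "CEFT": _cost("CEFT", days_fail * unit, cv),
        "CEFST": _cost("CEFST", days_fail * unit * (1.0 if spec.equal_arm_costs else float(rng.uniform(1.0, 1.01))), cv),
        "CTDM": _cost("CTDM", tdm_cost, cv if tdm_cost > 0 else 0.0),
        "CDUCI": _cost("CDUCI", unit, cv),
    }

    def regimen(drug, price):
        return AntibioticRegimen(drug=drug, dose_mg=1000.0, interval_h=8.0,
                                 duration_days=round(float(rng.uniform(7, 12)), 1),
                                 vial_price=round(price, 2))

    first_line = [regimen("synthetic-drug-1L", float(rng.uniform(20, 150)))]
    second_line = [[regimen("synthetic-drug-2L", float(rng.uniform(40, 300)))]]

    stays = [
        StayParameter(state_role=StayRole.STAY_1L, days_mean=days_1l,
                      days_low=days_1l * 0.7, days_high=days_1l * 1.5,
                      unit_cost_per_day=unit, cost_code="CE1L"),
    ]

    return ScenarioConfig(
        analysis_id=1,
        variant="base",
        source=f"synthetic ({label})",
        transitions=transitions,
        costs=costs,
        regimens_1l=first_line,
        second_line_options=second_line,
        stays=stays,
        background_mortality=cm,
    )


def generate_suite(spec: GeneratorSpec) -> list[LabelledScenario]:
    """Scenarios pre-labelled by construction, for use as oracles.

    - ``tdm_dominant``: the with-TDM arm has a strictly higher cure
      probability, both arms share identical cost tables and the TDM unit
      cost is zero; with failure costing more than cure, the incremental is
      non-positive by construction.
    - ``identical_arms``: both arms identical and a positive TDM cost; the
      incremental equals exactly the accrued TDM cost.
    - ``unconstrained``: no label-specific constraint.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[LabelledScenario] = []
    labels = ["tdm_dominant", "identical_arms", "unconstrained"]
    for i in range(spec.n_scenarios):
        label = labels[i % len(labels)]
        if label == "tdm_dominant":
            sub = GeneratorSpec(
                seed=spec.seed, n_scenarios=1,
                probability_concentration=spec.probability_concentration,
                cost_cv_range=(0.04, 0.08),
                cure_advantage_range=(max(spec.cure_advantage_range[0], 0.15),
                                      max(spec.cure_advantage_range[1], 0.25)),
                stay_cost_ordering=True, sd_fraction=0.05,
                tdm_unit_cost=1e-6, equal_arm_costs=True,
            )
        elif label == "identical_arms":
            sub = GeneratorSpec(
                seed=spec.seed, n_scenarios=1,
                probability_concentration=spec.probability_concentration,
                cost_cv_range=spec.cost_cv_range,
                cure_advantage_range=(0.0, 0.0),
                stay_cost_ordering=spec.stay_cost_ordering,
                sd_fraction=spec.sd_fraction, equal_arm_costs=True,
            )
        else:
            sub = spec
        out.append(LabelledScenario(
            scenario=generate_scenario(sub, rng=rng, label=label),
            label=label,
            details={"index": i},
        ))
    return out
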