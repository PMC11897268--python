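"""Domain types and packaged fixtures for the cost-minimization model.

The model compares two strategies of dosing antimicrobials in critically ill
ICU patients — with and without therapeutic drug monitoring (TDM) — across
three scenarios ("analyses"), each parameterized from a different published
meta-analysis of TDM effectiveness.  All inputs are small printed tables:
per-arm transition probabilities between five health states, antibiotic
regimen acquisition costs, ICU-stay costs, and the unit cost of TDM itself
(2024 euros).

Fixtures ship as versioned JSON files under ``tdmcost/data`` (one per
analysis, plus a shared variants file) and are validated on load.
"""

from __future__ import annotations

import json
from enum import Enum
from importlib import resources
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

FIXTURE_SCHEMA_VERSION = "1.0"

Arm = Literal["with_tdm", "without_tdm"]
ARMS: tuple[Arm, Arm] = ("with_tdm", "without_tdm")

#: Tolerance on the sum of outgoing transition means per source state.  The
#: analysis-3 without-TDM first-line row sums to 0.9616 as printed, so the
#: validator reports deviations up to this size as warnings, not failures.
SIMPLEX_TOLERANCE = 0.04


class ConfigurationError(KeyError):
    """Unknown analysis, variant or parameter code."""


class HealthState(str, Enum):
    """The five health states of the single-transition Markov structure."""

    TREATMENT_1L = "treatment_1L"
    CURE = "cure"
    FAILURE_2L = "failure_2L"
    DISCHARGE = "discharge"
    DEATH = "death"


ABSORBING_STATES = frozenset({HealthState.DISCHARGE, HealthState.DEATH})


class TransitionProbability(BaseModel):
    """One beta-distributed transition between two named health states.

    ``low``/``high`` are stored orientation-normalized (low <= high);
    ``printed_reversed`` records when the source table printed them in the
    opposite order.
    """

    model_config = ConfigDict(frozen=True)

    code: str
    from_state: HealthState
    to_state: HealthState
    mean: float = Field(ge=0.0, le=1.0)
    low: float = Field(ge=0.0, le=1.0)
    high: float = Field(ge=0.0, le=1.0)
    sd: float = Field(ge=0.0)
    printed_reversed: bool = False

    @model_validator(mode="after")
    def _check_bounds(self) -> "TransitionProbability":
        if self.low > self.high:
            raise ValueError(f"{self.code}: bounds not orientation-normalized")
        if self.sd > 0 and self.sd**2 >= self.mean * (1.0 - self.mean):
            raise ValueError(f"{self.code}: sd^2 >= mean*(1-mean), not beta-fittable")
        return self


class CostParameter(BaseModel):
    """One gamma-distributed cost item in 2024 euros.

    ``sd`` is ``None`` for items reported without dispersion (they are held
    fixed in the PSA); ``sd_inferred`` marks an SD this package derived rather
    than transcribed (range/4 for the TDM unit cost).
    """

    model_config = ConfigDict(frozen=True)

    code: str
    description: str = ""
    mean: float = Field(gt=0.0)
    low: float = Field(gt=0.0)
    high: float = Field(gt=0.0)
    sd: float | None = Field(default=None, ge=0.0)
    sd_inferred: bool = False

    @model_validator(mode="after")
    def _check_bounds(self) -> "CostParameter":
        if self.low > self.high:
            raise ValueError(f"{self.code}: bounds not orientation-normalized")
        return self


class AntibioticRegimen(BaseModel):
    """A dosing regimen priced from its ex-factory vial price."""

    model_config = ConfigDict(frozen=True)

    drug: str
    dose_mg: float = Field(gt=0.0)
    interval_h: float = Field(gt=0.0)
    duration_days: float = Field(ge=0.0)
    vial_price: float = Field(gt=0.0)
    vials_per_dose: int = Field(default=1, ge=1)
    price_inferred: bool = False

    @property
    def doses_per_day(self) -> float:
        return 24.0 / self.interval_h

    def cost(self) -> float:
        return regimen_cost(self)


def regimen_cost(regimen: AntibioticRegimen) -> float:
    """Acquisition cost of a full course, rounded to euro cents.

    doses/day x duration x vials/dose x vial price.
    """
    if regimen.duration_days < 0:
        raise ValueError("duration must be non-negative")
    doses_per_day = 24.0 / regimen.interval_h
    if doses_per_day <= 0:
        raise ValueError("interval must divide the day into a positive dose count")
    total = doses_per_day * regimen.duration_days * regimen.vials_per_dose * regimen.vial_price
    return round(total, 2)


class StayRole(str, Enum):
    STAY_1L = "stay_1L"
    CURE_WITH_TDM = "cure_with_TDM"
    CURE_WITHOUT_TDM = "cure_without_TDM"
    FAILURE_WITH_TDM = "failure_with_TDM"
    FAILURE_WITHOUT_TDM = "failure_without_TDM"


class StayParameter(BaseModel):
    """ICU length of stay for one Markov state, with the daily unit cost.

    ``days_mean`` is stored at the precision implied by the printed euro total
    divided by the unit cost; ``days_display`` keeps the rounded printed value.
    """

    model_config = ConfigDict(frozen=True)

    state_role: StayRole
    days_mean: float = Field(gt=0.0)
    days_low: float = Field(gt=0.0)
    days_high: float = Field(gt=0.0)
    days_display: float | None = None
    unit_cost_per_day: float = Field(gt=0.0)
    cost_code: str

    @model_validator(mode="after")
    def _check_order(self) -> "StayParameter":
        if not self.days_low <= self.days_mean <= self.days_high:
            raise ValueError(f"{self.state_role}: days not ordered low<=mean<=high")
        return self

    @property
    def total_cost(self) -> float:
        return self.days_mean * self.unit_cost_per_day


VARIANTS = ("base", "vancomycin_1l2l", "cefiderocol_2l", "betalactam_stay")


class ScenarioConfig(BaseModel):
    """A complete, validated parameter set for one analysis and one variant."""

    model_config = ConfigDict(frozen=True)

    schema_version: str = FIXTURE_SCHEMA_VERSION
    analysis_id: int
    variant: str = "base"
    source: str = ""
    transitions: dict[Arm, dict[str, TransitionProbability]]
    costs: dict[str, CostParameter]
    regimens_1l: list[AntibioticRegimen]
    second_line_options: list[list[AntibioticRegimen]]
    stays: list[StayParameter]
    background_mortality: float = 0.0035

    @model_validator(mode="after")
    def _check_complete(self) -> "ScenarioConfig":
        if self.analysis_id not in (1, 2, 3):
            raise ValueError(f"analysis_id must be 1, 2 or 3, got {self.analysis_id}")
        for arm in ARMS:
            if arm not in self.transitions:
                raise ValueError(f"missing arm {arm!r}")
        if not self.second_line_options:
            raise ValueError("at least one second-line regimen option required")
        return self

    # -- convenience accessors -------------------------------------------------

    def transition(self, arm: Arm, code: str) -> TransitionProbability:
        try:
            return self.transitions[arm][code]
        except KeyError as exc:
            raise ConfigurationError(f"unknown transition {code!r} in arm {arm!r}") from exc

    def cost(self, code: str) -> CostParameter:
        try:
            return self.costs[code]
        except KeyError as exc:
            raise ConfigurationError(f"unknown cost code {code!r}") from exc

    def first_line_drug_cost(self) -> float:
        return round(sum(regimen_cost(r) for r in self.regimens_1l), 2)

    def second_line_option_costs(self) -> list[float]:
        return [round(sum(regimen_cost(r) for r in opt), 2) for opt in self.second_line_options]

    def stage1_means(self, arm: Arm) -> tuple[float, float, float]:
        """(cure, death, failure) first-line transition means as stored."""
        suffix = "CTDM" if arm == "with_tdm" else "STDM"
        return (
            self.transition(arm, "IC" + suffix).mean,
            self.transition(arm, "IM" + suffix).mean,
            self.transition(arm, "IF" + suffix).mean,
        )


class Finding(BaseModel):
    """One validator finding; ``level`` is 'warn' or 'fail'."""

    model_config = ConfigDict(frozen=True)

    level: Literal["warn", "fail"]
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.level}: [{self.code}] {self.message}"


def validate_scenario(config: ScenarioConfig) -> list[Finding]:
    """Coherence report for a scenario: one finding per violated invariant.

    Returns an empty list for a fully coherent scenario.  Violations that the
    printed source tables themselves contain (first-line rows not summing to
    one, cost bounds excluding the mean) are reported as warnings so the
    as-printed fixtures remain usable; genuine impossibilities are failures.
    """
    findings: list[Finding] = []
    for arm in ARMS:
        outgoing: dict[HealthState, float] = {}
        for t in config.transitions[arm].values():
            if not 0.0 <= t.mean <= 1.0:
                findings.append(Finding(level="fail", code=t.code,
                                        message=f"probability {t.mean} out of [0,1]"))
            if t.sd > 0 and t.sd**2 >= t.mean * (1.0 - t.mean):
                findings.append(Finding(level="fail", code=t.code,
                                        message="sd not beta-fittable"))
            if not min(t.low, t.high) <= t.mean <= max(t.low, t.high):
                findings.append(Finding(level="warn", code=t.code,
                                        message=f"mean {t.mean} outside ({t.low}, {t.high})"))
            if t.printed_reversed:
                findings.append(Finding(level="warn", code=t.code,
                                        message="low/high printed in reversed order"))
            outgoing[t.from_state] = outgoing.get(t.from_state, 0.0) + t.mean
        for state, total in outgoing.items():
            dev = abs(total - 1.0)
            if dev > SIMPLEX_TOLERANCE:
                findings.append(Finding(level="fail", code=f"{arm}:{state.value}",
                                        message=f"outgoing probabilities sum {total:.4f}"))
            elif dev > 1e-9:
                findings.append(Finding(level="warn", code=f"{arm}:{state.value}",
                                        message=f"outgoing probabilities sum {total:.4f}"))
    for c in config.costs.values():
        if not min(c.low, c.high) <= c.mean <= max(c.low, c.high):
            findings.append(Finding(level="warn", code=c.code,
                                    message=f"mean {c.mean} outside printed range ({c.low}, {c.high})"))
    for s in config.stays:
        cost = config.cost(s.cost_code)
        if abs(s.total_cost - cost.mean) > 0.15:
            findings.append(Finding(level="fail", code=s.cost_code,
                                    message=f"days x unit cost {s.total_cost:.2f} != {cost.mean:.2f}"))
    return findings


# -- fixture loading ----------------------------------------------------------


def _data_text(name: str) -> str:
    return resources.files("tdmcost.data").joinpath(name).read_text()


def _parse_regimen(d: dict) -> AntibioticRegimen:
    return AntibioticRegimen(**d)


def _scenario_from_dict(raw: dict) -> ScenarioConfig:
    transitions = {
        arm: {
            t["code"]: TransitionProbability(**t)
            for t in raw["arms"][arm]["transitions"]
        }
        for arm in ARMS
    }
    return ScenarioConfig(
        schema_version=raw.get("schema_version", FIXTURE_SCHEMA_VERSION),
        analysis_id=raw["analysis_id"],
        variant=raw.get("variant", "base"),
        source=raw.get("source", ""),
        transitions=transitions,
        costs={c["code"]: CostParameter(**c) for c in raw["costs"]},
        regimens_1l=[_parse_regimen(r) for r in raw["regimens"]["first_line"]],
        second_line_options=[
            [_parse_regimen(r) for r in opt] for opt in raw["regimens"]["second_line"]
        ],
        stays=[StayParameter(**s) for s in raw.get("stays", [])],
        background_mortality=raw.get("background_mortality", 0.0035),
    )


def scenario_to_dict(config: ScenarioConfig) -> dict:
    """JSON-serializable form using the packaged fixture schema."""
    return {
        "schema_version": config.schema_version,
        "analysis_id": config.analysis_id,
        "variant": config.variant,
        "source": config.source,
        "background_mortality": config.background_mortality,
        "arms": {
            arm: {"transitions": [t.model_dump(mode="json") for t in config.transitions[arm].values()]}
            for arm in ARMS
        },
        "costs": [c.model_dump(mode="json") for c in config.costs.values()],
        "regimens": {
            "first_line": [r.model_dump(mode="json") for r in config.regimens_1l],
            "second_line": [
                [r.model_dump(mode="json") for r in opt] for opt in config.second_line_options
            ],
        },
        "stays": [s.model_dump(mode="json") for s in config.stays],
    }


def scenario_from_json(text: str) -> ScenarioConfig:
    return _scenario_from_dict(json.loads(text))


def _apply_variant(config: ScenarioConfig, variant: str) -> ScenarioConfig:
    if variant == "base":
        return config
    spec = json.loads(_data_text("variants.json"))
    try:
        vdata = spec[variant]
    except KeyError as exc:
        raise ConfigurationError(
            f"unknown variant {variant!r}; supported: {', '.join(VARIANTS)}"
        ) from exc
    update: dict = {"variant": variant}
    if "replace_drug" in vdata:
        target = vdata["replace_drug"]
        repl = _parse_regimen(vdata["replacement"])
        update["regimens_1l"] = [repl if r.drug == target else r for r in config.regimens_1l]
        update["second_line_options"] = [
            [repl if r.drug == target else r for r in opt] for opt in config.second_line_options
        ]
    if "second_line" in vdata:
        update["second_line_options"] = [
            [_parse_regimen(r) for r in opt] for opt in vdata["second_line"]
        ]
    if "stay_cost_means" in vdata:
        costs = dict(config.costs)
        for code, mean in vdata["stay_cost_means"].items():
            old = costs[code]
            scale = mean / old.mean
            costs[code] = old.model_copy(
                update={"mean": mean, "low": round(old.low * scale, 2),
                        "high": round(old.high * scale, 2),
                        "sd": None if old.sd is None else round(old.sd * scale, 2)}
            )
        update["costs"] = costs
        stays = []
        days = vdata.get("stay_days", {})
        for s in config.stays:
            if s.cost_code in vdata["stay_cost_means"]:
                d = days.get(s.state_role.value, s.days_mean)
                scale = d / s.days_mean
                stays.append(s.model_copy(update={
                    "days_mean": d, "days_low": s.days_low * scale,
                    "days_high": s.days_high * scale, "days_display": None}))
            else:
                stays.append(s)
        update["stays"] = stays
    return config.model_copy(update=update)


def load_fixture(analysis_id: int, variant: str = "base") -> ScenarioConfig:
    """Load the packaged scenario for one analysis (1-3) and one variant.

    Numbers match the source tables bit-for-bit; variants apply their regimen
    or stay substitutions on top of the base fixture, leaving everything else
    untouched.
    """
    if analysis_id not in (1, 2, 3):
        raise ConfigurationError(f"unknown analysis_id {analysis_id!r}; expected 1, 2 or 3")
    if variant not in VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; supported: {', '.join(VARIANTS)}"
        )
    config = scenario_from_json(_data_text(f"analysis{analysis_id}.json"))
    return _apply_variant(config, variant)


def load_reference_results() -> dict:
    """Published reference results (arm costs, PSA summaries, variant and
    tornado tables) used by calibration and the comparison report."""
    return json.loads(_data_text("reference_results.json"))
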