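"""Second-order Monte Carlo probabilistic sensitivity analysis.

Each iteration draws one value per named uncertain parameter — transition
probabilities from moment-fitted beta distributions, costs from moment-fitted
gammas — and re-evaluates both arms of the cohort model on those draws.
A parameter that appears in both arms (the shared stay tariffs, the 1L stay)
is drawn once per iteration and reused in both, i.e. common random numbers:
this is what makes the paired incremental-cost SD an order of magnitude
smaller than either arm's own SD.  Arm-specific parameters (the two arms'
transition probabilities, the arm-specific cure-stay tariffs) draw
independently.

Random streams are named: the root seed expands into one independent
substream per parameter code, so adding or removing an unrelated parameter
does not perturb the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AccrualSchedule, arm_cost_components, default_schedule
from .moments import Distribution, MomentError, fit_distribution, sample
from .parameters import Arm, ScenarioConfig


class PSAError(ValueError):
    pass


@dataclass(frozen=True)
class PSAResult:
    """Paired per-iteration arm costs with the summaries derived from them."""

    n_iterations: int
    seed: int
    per_arm: dict[str, dict[str, float]]
    incremental: dict[str, float]
    p_saving_with_tdm: float
    p_saving_without_tdm: float
    iteration_costs: pd.DataFrame = field(repr=False)
    parameter_draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_summary_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "per_arm": self.per_arm,
            "incremental": self.incremental,
            "p_saving_with_tdm": self.p_saving_with_tdm,
            "p_saving_without_tdm": self.p_saving_without_tdm,
        }


def _sampled_parameters(
    config: ScenarioConfig, schedule: AccrualSchedule
) -> dict[str, Distribution]:
    """Moment-fitted distribution per sampled parameter code.

    Raises before any iteration runs if any beta fit is infeasible.
    """
    specs: dict[str, Distribution] = {}
    for arm in ("with_tdm", "without_tdm"):
        for t in config.transitions[arm].values():
            if schedule.failure_prob_mode == "complement" and t.code.startswith("IF"):
                continue  # closed as 1 - cure - death, never drawn
            if t.code.startswith(("CS", "FM")):
                continue  # complements of CM*/FC* within their source state
            try:
                specs[t.code] = fit_distribution("beta", t.mean, t.sd, name=t.code)
            except MomentError as exc:
                raise PSAError(f"cannot moment-fit transition {t.code}: {exc}") from exc
    cost_codes = ["CE1L", "CECT", "CECST", "CTDM"]
    cost_codes += ["CEFST"] if schedule.failure_stay_shared else ["CEFT", "CEFST"]
    for code in cost_codes:
        c = config.cost(code)
        sd = c.sd or 0.0
        try:
            specs[code] = fit_distribution("gamma", c.mean, sd, name=code)
        except MomentError as exc:
            raise PSAError(f"cannot moment-fit cost {code}: {exc}") from exc
    return specs


def draw_parameters(
    config: ScenarioConfig,
    schedule: AccrualSchedule,
    n_iterations: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """One vector of ``n_iterations`` draws per parameter code."""
    specs = _sampled_parameters(config, schedule)
    codes = sorted(specs)
    streams = np.random.SeedSequence(seed).spawn(len(codes))
    return {
        code: np.asarray(sample(specs[code], np.random.default_rng(ss), size=n_iterations))
        for code, ss in zip(codes, streams)
    }


def _arm_costs(
    config: ScenarioConfig, arm: Arm, schedule: AccrualSchedule,
    draws: dict[str, np.ndarray],
) -> np.ndarray:
    breakdown, _ = arm_cost_components(config, arm, schedule, values=draws)
    return sum(breakdown.values())


def run_psa(
    config: ScenarioConfig,
    schedule: AccrualSchedule | None = None,
    n_iterations: int = 1000,
    seed: int = 20240301,
) -> PSAResult:
    """Run the PSA and summarize it.

    Identical (config, schedule, n_iterations, seed) reproduce the result
    bit for bit.
    """
    if n_iterations < 1:
        raise PSAError("n_iterations must be >= 1")
    schedule = schedule or default_schedule()
    draws = draw_parameters(config, schedule, n_iterations, seed)
    cost_with = np.asarray(_arm_costs(config, "with_tdm", schedule, draws), dtype=float)
    cost_without = np.asarray(_arm_costs(config, "without_tdm", schedule, draws), dtype=float)
    cost_with = np.broadcast_to(cost_with, (n_iterations,)).copy()
    cost_without = np.broadcast_to(cost_without, (n_iterations,)).copy()
    summary = summarize(cost_with, cost_without) if n_iterations >= 2 else _degenerate_summary(
        cost_with, cost_without
    )
    frame = pd.DataFrame(
        {
            "iteration": np.arange(1, n_iterations + 1),
            "cost_with_tdm": cost_with,
            "cost_without_tdm": cost_without,
            "incremental": cost_with - cost_without,
        }
    )
    return PSAResult(
        n_iterations=n_iterations,
        seed=seed,
        per_arm=summary["per_arm"],
        incremental=summary["incremental"],
        p_saving_with_tdm=summary["p_saving_with_tdm"],
        p_saving_without_tdm=summary["p_saving_without_tdm"],
        iteration_costs=frame,
        parameter_draws=draws,
    )


def _p_saving(cost_with: np.ndarray, cost_without: np.ndarray) -> tuple[float, float]:
    # Ties count toward the without-TDM arm (conservative toward intervention).
    p_with = float(np.mean(cost_with < cost_without))
    return p_with, 1.0 - p_with


def _degenerate_summary(cw: np.ndarray, cwo: np.ndarray) -> dict:
    p_with, p_without = _p_saving(cw, cwo)
    return {
        "per_arm": {
            "with_tdm": {"mean": float(cw.mean()), "sd": 0.0,
                         "ci95_low": float(cw.mean()), "ci95_high": float(cw.mean())},
            "without_tdm": {"mean": float(cwo.mean()), "sd": 0.0,
                            "ci95_low": float(cwo.mean()), "ci95_high": float(cwo.mean())},
        },
        "incremental": {"mean": float((cw - cwo).mean()), "se": 0.0},
        "p_saving_with_tdm": p_with,
        "p_saving_without_tdm": p_without,
    }


def summarize(cost_with: np.ndarray, cost_without: np.ndarray) -> dict:
    """Per-arm mean, SD and normal 95% CI of the mean; paired incremental.

    The CI convention is mean +/- 1.96 * SD / sqrt(n).  The incremental
    ``se`` is the standard error of the mean paired difference, which is the
    only reading of a "+/-" an order of magnitude below the per-arm SDs.
    """
    cw = np.asarray(cost_with, dtype=float)
    cwo = np.asarray(cost_without, dtype=float)
    if cw.shape != cwo.shape or cw.ndim != 1:
        raise PSAError("expected two equal-length 1-D cost vectors")
    n = cw.size
    if n < 2:
        raise PSAError("need at least 2 iterations to summarize")
    out: dict = {"per_arm": {}}
    for name, x in (("with_tdm", cw), ("without_tdm", cwo)):
        mean, sd = float(x.mean()), float(x.std(ddof=1))
        half = 1.96 * sd / np.sqrt(n)
        out["per_arm"][name] = {
            "mean": mean, "sd": sd,
            "ci95_low": mean - half, "ci95_high": mean + half,
        }
    diff = cw - cwo
    out["incremental"] = {
        "mean": float(diff.mean()),
        "se": float(diff.std(ddof=1) / np.sqrt(n)),
    }
    p_with, p_without = _p_saving(cw, cwo)
    out["p_saving_with_tdm"] = p_with
    out["p_saving_without_tdm"] = p_without
    return out
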