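"""One-way (tornado) deterministic sensitivity analysis and scenario variants.

Each model variable is set to its low and then its high bound while every
other variable stays at base, and the deterministic incremental cost is
recomputed.  A cost shared by both arms moves both simultaneously and so
leaves the incremental unchanged — those variables produce flat rows, as do
the second-stage transition probabilities, which carry no cost in the
calibrated accrual.

Scenario variants swap regimens (vancomycin for linezolid; cefiderocol as
the single second-line option) or the length-of-stay table (beta-lactam
stays) on top of a base analysis, leaving all other parameters untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import AccrualSchedule, default_schedule, incremental_cost
from .parameters import ScenarioConfig, _apply_variant


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class TornadoRow:
    variable_code: str
    low_value: float
    base_value: float
    high_value: float
    incremental_at_low: float
    incremental_at_high: float

    @property
    def span(self) -> float:
        return abs(self.incremental_at_high - self.incremental_at_low)


def _with_transition_mean(config: ScenarioConfig, arm: str, code: str, value: float) -> ScenarioConfig:
    transitions = {a: dict(ts) for a, ts in config.transitions.items()}
    transitions[arm][code] = transitions[arm][code].model_copy(update={"mean": value})
    return config.model_copy(update={"transitions": transitions})


def _with_cost_mean(config: ScenarioConfig, code: str, value: float) -> ScenarioConfig:
    costs = dict(config.costs)
    costs[code] = costs[code].model_copy(update={"mean": value})
    return config.model_copy(update={"costs": costs})


def tornado(
    config: ScenarioConfig, schedule: AccrualSchedule | None = None
) -> list[TornadoRow]:
    """One row per model variable, sorted by impact (descending span,
    alphabetical code on ties)."""
    schedule = schedule or default_schedule()
    base = incremental_cost(config, schedule)
    rows: list[TornadoRow] = []
    for arm, transitions in config.transitions.items():
        for code, t in transitions.items():
            if t.low is None or t.high is None:  # pragma: no cover - schema guarantees
                raise SensitivityError(f"missing bounds for {code}")
            inc = [
                incremental_cost(_with_transition_mean(config, arm, code, v), schedule)
                for v in (t.low, t.high)
            ]
            rows.append(TornadoRow(code, t.low, t.mean, t.high, inc[0], inc[1]))
    for code, c in config.costs.items():
        inc = [
            incremental_cost(_with_cost_mean(config, code, v), schedule)
            for v in (c.low, c.high)
        ]
        rows.append(TornadoRow(code, c.low, c.mean, c.high, inc[0], inc[1]))
    # Quantize the span so float-noise spans (shared costs cancelling to a
    # few ulps) sort as exact ties, broken alphabetically.
    rows.sort(key=lambda r: (-(r.span if r.span > 1e-9 else 0.0), r.variable_code))
    _ = base  # base incremental is implied by flat rows; kept for clarity
    return rows


def scenario_variant(config: ScenarioConfig, variant: str) -> ScenarioConfig:
    """Base config with the variant's substitutions applied (identity for
    ``base``)."""
    if config.variant not in ("base", variant):
        raise SensitivityError(
            f"cannot layer variant {variant!r} on top of {config.variant!r}"
        )
    return _apply_variant(config, variant)


def plot_tornado(rows, path, title: str = "One-way sensitivity analysis") -> None:
    """Horizontal-bar tornado diagram; variables sorted by impact."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = [r for r in rows if r.span > 1e-9] or rows[:1]
    # Flat rows all equal the base incremental; fall back to the widest
    # row's midpoint when every variable moves the result.
    flat = [r for r in rows if r.span <= 1e-9]
    if flat:
        base = flat[0].incremental_at_low
    else:
        base = 0.5 * (shown[0].incremental_at_low + shown[0].incremental_at_high)
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(shown) + 1.5))
    labels = [r.variable_code for r in shown][::-1]
    for i, r in enumerate(shown[::-1]):
        lo, hi = sorted((r.incremental_at_low, r.incremental_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", height=0.6)
    ax.axvline(base, color="black", lw=1)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("Incremental cost, with TDM minus without TDM (EUR)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
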