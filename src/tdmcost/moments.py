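"""Method-of-moments parameterization of beta and gamma distributions.

The probabilistic sensitivity analysis assigns each uncertain model input a
parametric distribution whose analytic mean and standard deviation equal the
reported ones: gamma for costs (support on the positive reals) and beta for
probabilities (support on the unit interval).  The gamma distribution is held
internally as (shape ``alpha``, rate ``lambda``), matching the conventional
health-economics parameterization; public entry points accept (mean, sd).

Lengths of stay reported as a median with a range are converted to a mean with
the standard (low + 2*median + high)/4 estimator used in meta-analytic
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MomentError(ValueError):
    """Raised when requested moments cannot be matched by the distribution."""


@dataclass(frozen=True)
class GammaSpec:
    """Gamma distribution with shape/rate parameterization.

    mean = shape/rate, variance = shape/rate**2.
    """

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise MomentError(
                f"gamma parameters must be positive, got shape={self.shape}, rate={self.rate}"
            )

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def sd(self) -> float:
        return self.shape**0.5 / self.rate


@dataclass(frozen=True)
class BetaSpec:
    """Beta distribution; mean = alpha/(alpha+beta)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise MomentError(
                f"beta parameters must be positive, got alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        n = self.alpha + self.beta
        return (self.alpha * self.beta / (n * n * (n + 1.0))) ** 0.5


@dataclass(frozen=True)
class PointMass:
    """Degenerate distribution at a single value.

    Used for inputs reported without uncertainty (sd = 0), so the PSA collapses
    to the deterministic evaluation in the zero-dispersion limit.
    """

    value: float

    @property
    def mean(self) -> float:
        return self.value

    @property
    def sd(self) -> float:
        return 0.0


Distribution = GammaSpec | BetaSpec | PointMass


def fit_gamma_moments(mean: float, sd: float) -> GammaSpec:
    """Gamma spec whose analytic mean and SD equal the inputs.

    shape = (mean/sd)**2, rate = mean/sd**2.
    """
    if not mean > 0:
        raise MomentError(f"gamma mean must be positive, got {mean}")
    if not sd > 0:
        raise MomentError(f"gamma sd must be positive, got {sd}")
    return GammaSpec(shape=(mean / sd) ** 2, rate=mean / sd**2)


def fit_beta_moments(mean: float, sd: float, name: str = "") -> BetaSpec:
    """Beta spec whose analytic mean and SD equal the inputs.

    With nu = mean*(1-mean)/sd**2 - 1: alpha = mean*nu, beta = (1-mean)*nu.
    The variance of any distribution on [0, 1] with the given mean is bounded
    by mean*(1-mean); an sd at or above that bound is infeasible.
    """
    label = f" for {name!r}" if name else ""
    if not 0 < mean < 1:
        raise MomentError(f"beta mean must lie strictly in (0, 1), got {mean}{label}")
    if not sd > 0:
        raise MomentError(f"beta sd must be positive, got {sd}{label}")
    bound = mean * (1.0 - mean)
    if sd * sd >= bound:
        raise MomentError(
            f"sd^2 = {sd * sd:.6g} >= mean*(1-mean) = {bound:.6g}: "
            f"no beta distribution matches these moments{label}"
        )
    nu = bound / (sd * sd) - 1.0
    return BetaSpec(alpha=mean * nu, beta=(1.0 - mean) * nu)


def fit_distribution(kind: str, mean: float, sd: float, name: str = "") -> Distribution:
    """Moment-fit helper that degrades gracefully to a point mass at sd = 0."""
    if sd == 0:
        return PointMass(mean)
    if kind == "gamma":
        return fit_gamma_moments(mean, sd)
    if kind == "beta":
        return fit_beta_moments(mean, sd, name=name)
    raise ValueError(f"unknown distribution kind {kind!r}")


def median_range_to_mean(low: float, median: float, high: float) -> float:
    """Estimate a mean from a median and its range: (low + 2*median + high)/4."""
    if not low <= median <= high:
        raise ValueError(
            f"expected low <= median <= high, got ({low}, {median}, {high})"
        )
    return (low + 2.0 * median + high) / 4.0


def sample(spec: Distribution, rng: np.random.Generator, size: int | None = None):
    """Draw from a fitted distribution using the supplied generator.

    Identical generator state yields identical draws; this is the
    reproducibility contract the PSA builds on.
    """
    if isinstance(spec, PointMass):
        if size is None:
            return spec.value
        return np.full(size, spec.value)
    if isinstance(spec, GammaSpec):
        return rng.gamma(shape=spec.shape, scale=1.0 / spec.rate, size=size)
    if isinstance(spec, BetaSpec):
        return rng.beta(spec.alpha, spec.beta, size=size)
    raise TypeError(f"cannot sample from {type(spec).__name__}")
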