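"""Transforming and combining effect priors.

A log-scale normal effect prior (log odds or log hazard ratio) is turned
into a distribution over an absolute parameter of a decision model — here
an annual recurrence probability — by applying the exponentiated effect to
a known baseline.  Utilities are provided to moment-match gamma
distributions, to combine two normal priors by Bayesian (precision
weighted) updating, and to pool several priors as a weighted mixture
(linear opinion pooling).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

CONVENTIONS = ("multiply_probability", "multiply_rate")


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior on a log relative-effect scale."""

    mean: float
    sd: float
    scale: str = "log_hr"  # "log_or" | "log_hr"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")

    def to_json(self) -> str:
        return json.dumps({"family": "normal", "mean": self.mean, "sd": self.sd, "scale": self.scale})


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior, e.g. on an annual event rate."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("shape and rate must be > 0")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def variance(self) -> float:
        return self.shape / self.rate**2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(self.shape, 1.0 / self.rate, size=n)

    def to_json(self) -> str:
        return json.dumps({"family": "gamma", "shape": self.shape, "rate": self.rate})


@dataclass(frozen=True)
class InducedDistribution:
    """Distribution over an absolute probability induced by a log-effect prior."""

    baseline_prob: float
    convention: str
    median: float
    samples: np.ndarray
    intervals: tuple[tuple[float, float, float], ...]  # (level, lo, hi)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def variance(self) -> float:
        return float(self.samples.var(ddof=1))


def apply_log_effect_prior(
    prior: NormalPrior,
    baseline_prob: float,
    convention: str = "multiply_probability",
    n_samples: int = 100_000,
    seed: int = 0,
    levels: Sequence[float] = (0.95,),
) -> InducedDistribution:
    """Apply a log-scale effect prior to a known baseline probability.

    ``multiply_probability`` scales the annual probability directly,
    ``p_new = p0 * exp(theta)``; ``multiply_rate`` applies the effect on
    the rate scale, ``r_new = -ln(1 - p0) * exp(theta)`` with
    ``p_new = 1 - exp(-r_new)``.  Median and intervals come from the
    closed-form log-normal quantiles of the transformed variable; the
    returned samples are for downstream distribution fitting.
    """
    if not 0.0 < baseline_prob < 1.0:
        raise ValueError("baseline_prob must be in (0, 1)")
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    rng = np.random.default_rng(seed)
    theta = prior.mean + prior.sd * rng.standard_normal(n_samples)

    if convention == "multiply_probability":
        # p_new is log-normal: log p_new ~ N(log p0 + mean, sd^2)
        log_p0 = np.log(baseline_prob)
        median = float(np.exp(log_p0 + prior.mean))
        intervals = tuple(
            (
                lvl,
                float(np.exp(stats.norm.ppf((1 - lvl) / 2, log_p0 + prior.mean, prior.sd))),
                float(np.exp(stats.norm.ppf((1 + lvl) / 2, log_p0 + prior.mean, prior.sd))),
            )
            for lvl in levels
        )
        samples = baseline_prob * np.exp(theta)
        over = float(np.mean(samples >= 1.0))
        if over > 0.001:
            warnings.warn(
                f"{100 * over:.2f}% of induced probability mass is >= 1 under "
                "multiply_probability; samples truncated to 1 - 1e-12"
            )
            logger.warning("apply_log_effect_prior: truncated %.4f of mass at 1", over)
        samples = np.minimum(samples, 1.0 - 1e-12)
    else:
        base_rate = -np.log1p(-baseline_prob)
        # r_new is log-normal, and p = 1 - exp(-r) is monotone in r, so
        # quantiles of p are the transform of the quantiles of r.
        log_r = np.log(base_rate) + prior.mean
        median = float(-np.expm1(-np.exp(log_r)))
        intervals = tuple(
            (
                lvl,
                float(-np.expm1(-np.exp(stats.norm.ppf((1 - lvl) / 2, log_r, prior.sd)))),
                float(-np.expm1(-np.exp(stats.norm.ppf((1 + lvl) / 2, log_r, prior.sd)))),
            )
            for lvl in levels
        )
        samples = -np.expm1(-base_rate * np.exp(theta))
    return InducedDistribution(
        baseline_prob=baseline_prob,
        convention=convention,
        median=median,
        samples=samples,
        intervals=intervals,
    )


def fit_gamma_moments(mean: float, variance: float) -> GammaPrior:
    """Gamma(shape, rate) matching a mean and variance exactly.

    shape = mean^2 / variance, rate = mean / variance.
    """
    if mean <= 0 or variance <= 0:
        raise ValueError("mean and variance must be > 0")
    return GammaPrior(shape=mean**2 / variance, rate=mean / variance)


def fit_gamma_mle(samples: np.ndarray) -> GammaPrior:
    """Maximum-likelihood gamma fit to samples (scipy, location pinned at 0)."""
    shape, _, scale = stats.gamma.fit(np.asarray(samples, dtype=float), floc=0)
    return GammaPrior(shape=float(shape), rate=1.0 / float(scale))


def bayes_combine_normals(a: NormalPrior, b: NormalPrior) -> NormalPrior:
    """Combine two independent normal sources by precision weighting.

    The combined precision is the sum of precisions, so the result is
    never more diffuse than either input.
    """
    if a.scale != b.scale:
        raise ValueError(f"cannot combine priors on different scales: {a.scale} vs {b.scale}")
    prec = 1.0 / a.sd**2 + 1.0 / b.sd**2
    mean = (a.mean / a.sd**2 + b.mean / b.sd**2) / prec
    return NormalPrior(mean=mean, sd=prec**-0.5, scale=a.scale)


@dataclass(frozen=True)
class PooledPrior:
    """Weighted mixture of normal priors (linear opinion pool)."""

    components: tuple[NormalPrior, ...]
    weights: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(sum(w * c.mean for c, w in zip(self.components, self.weights)))

    @property
    def variance(self) -> float:
        m = self.mean
        return float(
            sum(w * (c.sd**2 + (c.mean - m) ** 2) for c, w in zip(self.components, self.weights))
        )

    @property
    def sd(self) -> float:
        return self.variance**0.5

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(
            w * stats.norm.pdf(x, c.mean, c.sd) for c, w in zip(self.components, self.weights)
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.components), size=n, p=self.weights)
        means = np.array([c.mean for c in self.components])
        sds = np.array([c.sd for c in self.components])
        return means[idx] + sds[idx] * rng.standard_normal(n)


def linear_pool(priors: Sequence[NormalPrior], weights: Sequence[float] | None = None) -> PooledPrior:
    """Linear opinion pool: a normalized weighted mixture of the priors.

    Pooling does not sharpen: the pooled variance is at least the weighted
    mean of the component variances.
    """
    priors = tuple(priors)
    if not priors:
        raise ValueError("need at least one prior to pool")
    scales = {p.scale for p in priors}
    if len(scales) > 1:
        raise ValueError(f"cannot pool priors on different scales: {sorted(scales)}")
    if weights is None:
        weights = [1.0] * len(priors)
    weights = np.asarray(list(weights), dtype=float)
    if len(weights) != len(priors):
        raise ValueError("weights must match priors")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be >= 0 with positive sum")
    weights = weights / weights.sum()
    return PooledPrior(components=priors, weights=tuple(float(w) for w in weights))
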