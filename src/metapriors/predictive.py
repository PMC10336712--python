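"""Predictive priors for the effect in a future trial.

Given posterior draws of the hierarchy, the predictive distribution of the
true effect in a new study integrates over posterior uncertainty:

* for a disease area represented in the data, one draw of
  ``theta_pred ~ N(mu_A, tau_A^2)`` per posterior draw (plus the
  comparison-type shift ``B`` for active-vs-active comparisons under
  model 2);
* for an unrepresented ("other/unknown") area, three levels: first
  ``mu_pred ~ N(M, eta^2)`` and ``tau_pred^2 ~ pi(kappa, nu)`` per
  posterior draw, then ``theta_pred ~ N(mu_pred, tau_pred^2)``.

Predictive distributions are summarized as normals on the log odds/hazard
ratio scale (moment matching, sample sd with denominator n-1), the form in
which they are meant to be plugged into downstream analyses as log-normal
effect priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy import PosteriorDraws

NEW_AREA = "new_area"
_COMPARISONS = ("any", "active_vs_active", "active_vs_inactive")

#: 95% intervals use the conventional z = 1.96 rather than the exact normal
#: quantile; other levels use exact quantiles.
Z_95 = 1.96


@dataclass(frozen=True)
class PredictivePrior:
    """Normal summary (log scale) of the predicted effect in a future trial."""

    label: str
    comparison: str
    mean: float
    sd: float
    intervals: tuple[tuple[float, float, float], ...] = ()  # (level, lo, hi)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.sd == 0:
            warnings.warn(f"predictive prior {self.label!r} is degenerate (sd = 0)")
        for level, lo, hi in self.intervals:
            if not (lo <= hi):
                raise ValueError("interval endpoints must satisfy lo <= hi")

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        for lvl, lo, hi in self.intervals:
            if abs(lvl - level) < 1e-12:
                return lo, hi
        return normal_interval(self.mean, self.sd, level)


def _family_sample(family: str, kappa: np.ndarray, nu: np.ndarray, rng) -> np.ndarray:
    """Vectorized draw of tau^2 from pi(kappa, nu), one per posterior draw."""
    if family == "lognormal":
        return np.exp(kappa + nu * rng.standard_normal(kappa.shape))
    if family == "gamma":
        # rng.gamma(shape, scale); guard against numerically zero shapes
        return rng.gamma(np.maximum(kappa, 1e-12), np.maximum(nu, 1e-300))
    return kappa + np.abs(nu * rng.standard_normal(kappa.shape))


def predictive_samples(
    draws: PosteriorDraws,
    target: str,
    comparison: str = "any",
    model=None,
    seed: int = 0,
) -> np.ndarray:
    """One predicted future-trial effect per retained posterior draw.

    ``target`` is a disease-area label from the fitted dataset or
    ``"new_area"`` for an area not represented in the data.  Under model 2
    the ``comparison`` selects the covariate value (``active_vs_active``
    adds the shift ``B``); ``"any"`` takes the active-vs-inactive baseline.
    Sampling uses common random numbers across comparisons at the same
    seed, so paired active/inactive samples differ by the ``B`` draws
    exactly.
    """
    if comparison not in _COMPARISONS:
        raise ValueError(f"comparison must be one of {_COMPARISONS}")
    spec = model if model is not None else draws.spec
    if comparison != "any" and not spec.has_covariate:
        raise ValueError("comparison-specific prediction requires model 2 draws")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))

    if target == NEW_AREA:
        M = draws.stacked("M")
        eta = draws.stacked("eta")
        kappa = draws.stacked("kappa")
        nu = draws.stacked("nu")
        mu_pred = M + eta * rng.standard_normal(M.shape)
        tau2_pred = _family_sample(spec.variance_family, kappa, nu, rng)
    else:
        if target not in draws.area_index:
            raise KeyError(
                f"unknown disease area {target!r}; known areas: {draws.areas} "
                f"(use {NEW_AREA!r} for an unrepresented area)"
            )
        k = draws.area_index[target]
        mu_pred = draws.stacked("mu")[:, k]
        tau2_pred = draws.stacked("tau2")[:, k]

    shift = 0.0
    if comparison == "active_vs_active":
        shift = draws.stacked("B")
    theta = mu_pred + shift + np.sqrt(tau2_pred) * rng.standard_normal(mu_pred.shape)
    return theta


def summarize_to_normal(samples: np.ndarray) -> tuple[float, float]:
    """Moment-matched normal summary (mean, sd) of predictive samples.

    The sd uses the n-1 denominator.  Constant samples give sd = 0 with a
    warning rather than an error.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples to summarize")
    mean = float(samples.mean())
    sd = float(samples.std(ddof=1))
    if sd == 0:
        warnings.warn("predictive samples have zero variance; summary sd is 0")
    return mean, sd


def normal_interval(mean: float, sd: float, level: float = 0.95) -> tuple[float, float]:
    """Central normal interval; z = 1.96 at the 95% level, exact otherwise."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = Z_95 if abs(level - 0.95) < 1e-12 else float(stats.norm.ppf((1 + level) / 2))
    return mean - z * sd, mean + z * sd


def to_ratio_scale(prior: PredictivePrior, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Median and interval on the odds/hazard-ratio scale (log-normal summary)."""
    lo, hi = prior.interval(level)
    return float(np.exp(prior.mean)), (float(np.exp(lo)), float(np.exp(hi)))


def prior_from_draws(
    draws: PosteriorDraws,
    target: str,
    comparison: str = "any",
    seed: int = 0,
    levels: Sequence[float] = (0.95,),
) -> PredictivePrior:
    """Predictive prior for one area x comparison, summarized as a normal."""
    samples = predictive_samples(draws, target, comparison=comparison, seed=seed)
    mean, sd = summarize_to_normal(samples)
    label = "other/unknown" if target == NEW_AREA else target
    intervals = tuple((lvl, *normal_interval(mean, sd, lvl)) for lvl in levels)
    return PredictivePrior(label=label, comparison=comparison, mean=mean, sd=sd, intervals=intervals)


def export_prior_table(
    draws: PosteriorDraws,
    areas: Sequence[str] | None = None,
    model=None,
    seed: int = 0,
    split_areas: Sequence[str] = (),
    include_new_area: bool = True,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predictive-prior table: one row per disease area (plus splits).

    Produces the reporting layout used for such analyses: a normal
    predictive distribution per represented area, optional per-comparison
    rows for areas in ``split_areas`` (model 2 draws only), and an
    "other/unknown" row from the three-level new-area prediction.  Each
    row's interval equals ``normal_interval(mean, sd)`` of that row
    exactly, and ``median_ratio`` is the exponentiated mean.
    """
    spec = model if model is not None else draws.spec
    if areas is None:
        areas = draws.areas
    split_areas = list(split_areas)
    if split_areas and not spec.has_covariate:
        raise ValueError("split_areas requires model 2 draws")
    rows = []

    def add_row(target: str, comparison: str) -> None:
        prior = prior_from_draws(draws, target, comparison=comparison, seed=seed, levels=(level,))
        lo, hi = prior.interval(level)
        rows.append(
            {
                "label": prior.label,
                "comparison": comparison,
                "model": spec.label(),
                "mean_log": prior.mean,
                "sd_log": prior.sd,
                f"lo{100 * level:g}": lo,
                f"hi{100 * level:g}": hi,
                "median_ratio": float(np.exp(prior.mean)),
            }
        )

    for area in areas:
        add_row(area, "any")
        if area in split_areas:
            add_row(area, "active_vs_active")
            add_row(area, "active_vs_inactive")
    if include_new_area:
        add_row(NEW_AREA, "any")
    return pd.DataFrame(rows)


def plot_prior_table(table: pd.DataFrame, ax=None):
    """Interval plot of a prior table on the odds/hazard-ratio scale."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * len(table) + 1.5))
    lo_col = next(c for c in table.columns if c.startswith("lo"))
    hi_col = next(c for c in table.columns if c.startswith("hi"))
    labels = [
        f"{r.label}" + (f" ({r.comparison})" if r.comparison != "any" else "")
        for r in table.itertuples()
    ]
    y = np.arange(len(table))[::-1]
    ax.hlines(y, np.exp(table[lo_col]), np.exp(table[hi_col]), color="0.4")
    ax.plot(np.exp(table["mean_log"]), y, "o", color="C0")
    ax.axvline(1.0, color="0.7", linestyle="--", linewidth=1)
    ax.set_yticks(y)
    ax.set_yticklabels(labels)
    ax.set_xscale("log")
    ax.set_xlabel("odds / hazard ratio (log scale)")
    return ax
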