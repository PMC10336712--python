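"""Minimal Markov decision model and nested-Monte-Carlo EVSI engine.

The case study is a three-state cohort model of high-grade non-muscle-
invasive bladder cancer (states: recurrence-free, recurrence/failure,
dead) used to value a proposed two-arm trial whose primary outcome is the
annual recurrence rate in each arm.  The control-arm rate is treated as
known (-ln(0.75) per year, i.e. 75% one-year failure-free survival under
an exponential model); the experimental-arm rate carries a gamma prior
that the trial would update through a conjugate Poisson-gamma pair.

Expected value of sample information (EVSI) is computed by nested Monte
Carlo: outer draws of the true rate and simulated trial data, an exact
conjugate posterior update, and inner probabilistic draws of costs,
utilities and the posterior rate to estimate each arm's expected net
benefit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .priors import GammaPrior

logger = logging.getLogger(__name__)

STATES = ("recurrence_free", "failure", "dead")


@dataclass(frozen=True)
class DecisionModelInputs:
    """Inputs of the bladder-cancer Markov model.

    Costs are US dollars per year; utilities are per year of occupancy;
    ``(mean, se)`` pairs drive the probabilistic draws (gamma for costs,
    beta for utilities).  The default horizon runs from cohort age 68 to a
    cap at age 100 in 1-year cycles.
    """

    ctrl_failure_free_1y: float = 0.75
    survival_5y_post_failure: float = 0.79
    cost_added_experimental: float = 147.18
    cost_surveillance_mean: float = 5_585.0
    cost_surveillance_se: float = 1_117.0
    cost_recurrent_mean: float = 17_727.0
    cost_recurrent_se: float = 3_545.0
    utility_failure_free_mean: float = 0.997
    utility_failure_free_se: float = 0.05
    utility_recurrent_mean: float = 0.96
    utility_recurrent_se: float = 0.192
    wtp: float = 150_000.0
    age: float = 68.0
    max_age: float = 100.0
    cycle_years: float = 1.0
    discount: float = 0.03
    #: all-cause (non-disease) mortality rate per year, applied in every
    #: alive state on top of the post-failure disease-specific rate.  Off by
    #: default: the reference input table lists no life-table input.
    background_mortality_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.ctrl_failure_free_1y < 1.0:
            raise ValueError("ctrl_failure_free_1y must be in (0, 1)")
        if not 0.0 < self.survival_5y_post_failure < 1.0:
            raise ValueError("survival_5y_post_failure must be in (0, 1)")
        if self.wtp <= 0:
            raise ValueError("wtp must be > 0")
        if self.max_age <= self.age:
            raise ValueError("max_age must exceed cohort age")
        if self.cycle_years <= 0:
            raise ValueError("cycle_years must be > 0")

    @property
    def control_rate(self) -> float:
        """Annual recurrence rate in the control arm (exponential model)."""
        return -math.log(self.ctrl_failure_free_1y)

    @property
    def post_failure_mortality_rate(self) -> float:
        """Annual disease-specific mortality rate after failure."""
        return -math.log(self.survival_5y_post_failure) / 5.0

    @property
    def horizon_years(self) -> float:
        return self.max_age - self.age

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_years))


@dataclass(frozen=True)
class TrialDesign:
    """Proposed two-arm trial: total size, accrual and follow-up."""

    n_total: int = 616
    accrual_years: float = 3.0
    followup_years: float = 2.5
    n_arms: int = 2

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise ValueError("n_total must be >= 0")
        if self.n_arms < 2:
            raise ValueError("n_arms must be >= 2")

    @property
    def per_arm(self) -> float:
        return self.n_total / self.n_arms

    @property
    def person_years(self) -> float:
        """Exposure in one arm: per-arm size times mean follow-up."""
        return self.per_arm * self.followup_years


@dataclass(frozen=True)
class PopulationInputs:
    """Population projection for scaling per-person value."""

    patients_per_year: float = 25_900.0
    horizon_years: int = 10
    discount: float = 0.03


@dataclass(frozen=True)
class ParameterSet:
    """One probabilistic draw (or vector of draws) of the uncertain inputs."""

    cost_surveillance: np.ndarray | float
    cost_recurrent: np.ndarray | float
    utility_failure_free: np.ndarray | float
    utility_recurrent: np.ndarray | float


@dataclass(frozen=True)
class EVSIResult:
    """Per-person and population EVSI with Monte-Carlo error and provenance."""

    per_person: float
    population: float
    mc_se: float
    n_outer: int
    n_inner: int
    seed: int
    prior: GammaPrior
    effective_population: float
    prior_expected_nb: tuple[float, float]  # (control, experimental)

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_person": self.per_person,
                "population": self.population,
                "mc_se": self.mc_se,
                "n_outer": self.n_outer,
                "n_inner": self.n_inner,
                "seed": self.seed,
                "prior": {"shape": self.prior.shape, "rate": self.prior.rate},
                "effective_population": self.effective_population,
                "prior_expected_nb": list(self.prior_expected_nb),
            },
            indent=2,
        )


# --------------------------------------------------------------------------
# probabilistic parameter draws
# --------------------------------------------------------------------------
def _draw_gamma(mean: float, se: float, rng, size) -> np.ndarray | float:
    if se <= 0:
        return mean if size is None else np.full(size, mean)
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return rng.gamma(shape, scale, size=size)


def _draw_beta(mean: float, se: float, rng, size, label: str) -> np.ndarray | float:
    if se <= 0:
        return mean if size is None else np.full(size, mean)
    var = se**2
    bound = mean * (1 - mean)
    if var >= bound:
        logger.warning(
            "utility %s: se %.3f infeasible for a beta with mean %.3f; "
            "falling back to a [0, 1]-truncated normal", label, se, mean,
        )
        draws = mean + se * rng.standard_normal(size if size is not None else ())
        return np.clip(draws, 0.0, 1.0)
    nu0 = bound / var - 1.0
    return rng.beta(mean * nu0, (1 - mean) * nu0, size=size)


def draw_psa_parameters(
    inputs: DecisionModelInputs, rng: np.random.Generator, size=None
) -> ParameterSet:
    """Draw costs (gamma) and utilities (beta), moment-matched to (mean, se)."""
    return ParameterSet(
        cost_surveillance=_draw_gamma(inputs.cost_surveillance_mean, inputs.cost_surveillance_se, rng, size),
        cost_recurrent=_draw_gamma(inputs.cost_recurrent_mean, inputs.cost_recurrent_se, rng, size),
        utility_failure_free=_draw_beta(
            inputs.utility_failure_free_mean, inputs.utility_failure_free_se, rng, size, "failure-free"
        ),
        utility_recurrent=_draw_beta(
            inputs.utility_recurrent_mean, inputs.utility_recurrent_se, rng, size, "recurrent"
        ),
    )


# --------------------------------------------------------------------------
# Markov model
# --------------------------------------------------------------------------
def markov_trace(
    recurrence_rate_ctrl: float,
    recurrence_rate_trt: float,
    params: ParameterSet | None,
    inputs: DecisionModelInputs,
    horizon: float | None = None,
    cycle: float | None = None,
) -> dict[str, np.ndarray]:
    """State-occupancy traces for both arms.

    Returns ``{"control": trace, "experimental": trace}`` where each trace
    has shape ``(n_cycles + 1, 3)`` over states (recurrence-free, failure,
    dead); row ``t`` is the occupancy at the start of cycle ``t``.  The
    per-cycle failure probability is ``1 - exp(-rate * cycle)`` and the
    dead state is absorbing.  ``params`` is accepted for interface
    symmetry; occupancy depends only on the rates.
    """
    if recurrence_rate_ctrl < 0 or recurrence_rate_trt < 0:
        raise ValueError("recurrence rates must be >= 0")
    cycle = inputs.cycle_years if cycle is None else cycle
    horizon = inputs.horizon_years if horizon is None else horizon
    if horizon < cycle:
        raise ValueError("horizon must cover at least one cycle")
    n_cycles = int(round(horizon / cycle))
    bg = inputs.background_mortality_rate
    p_die_fail = -math.expm1(-(inputs.post_failure_mortality_rate + bg) * cycle)
    out = {}
    for arm, rate in (("control", recurrence_rate_ctrl), ("experimental", recurrence_rate_trt)):
        # competing exits from recurrence-free: failure at `rate`, death at `bg`
        p_leave = -math.expm1(-(rate + bg) * cycle)
        w_fail = rate / (rate + bg) if rate + bg > 0 else 0.0
        p_fail = p_leave * w_fail
        p_die_free = p_leave * (1.0 - w_fail)
        trace = np.zeros((n_cycles + 1, 3))
        trace[0] = (1.0, 0.0, 0.0)
        for t in range(n_cycles):
            free, fail, dead = trace[t]
            trace[t + 1, 0] = free * (1 - p_fail - p_die_free)
            trace[t + 1, 1] = fail * (1 - p_die_fail) + free * p_fail
            trace[t + 1, 2] = dead + fail * p_die_fail + free * p_die_free
        out[arm] = trace
    return out


def _discounted_occupancy(rates: np.ndarray, inputs: DecisionModelInputs) -> tuple:
    """Vectorized discounted occupancy-year sums (S_free, S_fail) per rate.

    Start-of-cycle occupancy accrues that cycle's payoffs, discounted at
    ``(1 + d)^-t`` (no half-cycle correction), matching the scalar
    :func:`markov_trace` + :func:`expected_outcomes` path exactly.
    """
    rates = np.asarray(rates, dtype=float)
    cycle = inputs.cycle_years
    n_cycles = inputs.n_cycles
    bg = inputs.background_mortality_rate
    with np.errstate(invalid="ignore"):
        w_fail = np.where(rates + bg > 0, rates / np.where(rates + bg > 0, rates + bg, 1.0), 0.0)
    p_leave = -np.expm1(-(rates + bg) * cycle)
    p_fail = p_leave * w_fail
    p_stay_free = 1.0 - p_leave
    p_die_fail = -math.expm1(-(inputs.post_failure_mortality_rate + bg) * cycle)
    disc = (1.0 + inputs.discount) ** (-cycle * np.arange(n_cycles))
    free = np.ones_like(rates)
    fail = np.zeros_like(rates)
    s_free = np.zeros_like(rates)
    s_fail = np.zeros_like(rates)
    for t in range(n_cycles):
        s_free += disc[t] * free
        s_fail += disc[t] * fail
        fail = fail * (1 - p_die_fail) + free * p_fail
        free = free * p_stay_free
    return s_free * cycle, s_fail * cycle


def expected_outcomes(
    trace: np.ndarray,
    params: ParameterSet,
    inputs: DecisionModelInputs,
    discount: float | None = None,
    arm: str = "control",
    cycle: float | None = None,
) -> tuple[float, float]:
    """Discounted (cost, QALYs) for one arm's trace.

    Costs accumulate surveillance / recurrent-state spending by occupancy
    (plus the experimental arm's added annual cost while alive); QALYs
    accumulate state utilities.  Start-of-cycle occupancy accrues the
    cycle's payoffs; flows in cycle ``t`` are discounted by ``(1+d)^-t``.
    """
    discount = inputs.discount if discount is None else discount
    cycle = inputs.cycle_years if cycle is None else cycle
    n_cycles = trace.shape[0] - 1
    disc = (1.0 + discount) ** (-cycle * np.arange(n_cycles))
    free = trace[:-1, 0]
    fail = trace[:-1, 1]
    s_free = float(np.sum(disc * free)) * cycle
    s_fail = float(np.sum(disc * fail)) * cycle
    cost = params.cost_surveillance * s_free + params.cost_recurrent * s_fail
    if arm == "experimental":
        cost = cost + inputs.cost_added_experimental * (s_free + s_fail)
    qaly = params.utility_failure_free * s_free + params.utility_recurrent * s_fail
    return float(cost), float(qaly)


def net_benefit(cost, qaly, wtp: float):
    """Net monetary benefit: wtp * QALYs - cost."""
    return wtp * np.asarray(qaly, dtype=float) - np.asarray(cost, dtype=float)


def _arm_net_benefit(rates, params: ParameterSet, inputs: DecisionModelInputs, experimental: bool):
    """Vectorized net benefit for one arm at given recurrence rates."""
    s_free, s_fail = _discounted_occupancy(rates, inputs)
    cost = params.cost_surveillance * s_free + params.cost_recurrent * s_fail
    if experimental:
        cost = cost + inputs.cost_added_experimental * (s_free + s_fail)
    qaly = params.utility_failure_free * s_free + params.utility_recurrent * s_fail
    return net_benefit(cost, qaly, inputs.wtp)


# --------------------------------------------------------------------------
# trial simulation and conjugate updating
# --------------------------------------------------------------------------
def simulate_trial(true_rate, design: TrialDesign, rng: np.random.Generator):
    """Simulate the treatment arm's recurrence count.

    Exposure is per-arm size times mean follow-up; events are Poisson with
    mean ``rate * exposure``.  ``true_rate`` may be an array.
    """
    rates = np.asarray(true_rate, dtype=float)
    if np.any(rates < 0):
        raise ValueError("true_rate must be >= 0")
    person_years = design.person_years
    events = rng.poisson(rates * person_years)
    return events, person_years


def posterior_update(prior: GammaPrior, events, person_years) -> GammaPrior:
    """Conjugate Poisson-gamma update: (shape + events, rate + exposure)."""
    if np.any(np.asarray(events) < 0) or np.any(np.asarray(person_years) < 0):
        raise ValueError("events and person_years must be >= 0")
    return GammaPrior(shape=prior.shape + float(events), rate=prior.rate + float(person_years))


# --------------------------------------------------------------------------
# value of information
# --------------------------------------------------------------------------
def _rng_streams(seed: int, *keys: int):
    return [np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,))) for k in keys]


def _prior_expected_nb(
    prior: GammaPrior, inputs: DecisionModelInputs, n_sims: int, rng
) -> tuple[float, float, float, float]:
    """(E[NB_control], E[NB_experimental], se_ctrl, se_trt) under the prior."""
    rates = prior.sample(n_sims, rng)
    params = draw_psa_parameters(inputs, rng, size=n_sims)
    nb_ctrl = _arm_net_benefit(np.full(n_sims, inputs.control_rate), params, inputs, False)
    nb_trt = _arm_net_benefit(rates, params, inputs, True)
    return (
        float(nb_ctrl.mean()),
        float(nb_trt.mean()),
        float(nb_ctrl.std(ddof=1) / math.sqrt(n_sims)),
        float(nb_trt.std(ddof=1) / math.sqrt(n_sims)),
    )


def evpi(prior: GammaPrior, inputs: DecisionModelInputs, n_sims: int = 10_000, seed: int = 0) -> float:
    """Per-person expected value of perfect information on all uncertain inputs.

    ``E[max_arm NB] - max_arm E[NB]`` by plain Monte Carlo over the prior
    and the probabilistic cost/utility draws.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    (rng,) = _rng_streams(seed, 1)
    rates = prior.sample(n_sims, rng)
    params = draw_psa_parameters(inputs, rng, size=n_sims)
    nb_ctrl = _arm_net_benefit(np.full(n_sims, inputs.control_rate), params, inputs, False)
    nb_trt = _arm_net_benefit(rates, params, inputs, True)
    return float(np.maximum(nb_ctrl, nb_trt).mean() - max(nb_ctrl.mean(), nb_trt.mean()))


def evsi_nested(
    prior: GammaPrior,
    inputs: DecisionModelInputs,
    design: TrialDesign,
    population: PopulationInputs | None = None,
    n_outer: int = 1_000,
    n_inner: int = 1_000,
    seed: int = 0,
) -> EVSIResult:
    """Nested-Monte-Carlo EVSI of the proposed trial.

    Outer loop: draw a true treatment-arm rate from the prior, simulate
    the trial's Poisson recurrence count, and update the prior by exact
    conjugacy.  Inner loop: draw costs/utilities and posterior rates to
    estimate each arm's expected net benefit (cost and utility draws are
    held common across arms within an inner draw).  EVSI is the outer mean
    of the max-arm posterior expected net benefit minus the max-arm prior
    expected net benefit.
    """
    if n_outer < 10 or n_inner < 10:
        raise ValueError("n_outer and n_inner must be >= 10")
    population = population or PopulationInputs()
    rng_outer, rng_inner, rng_prior = _rng_streams(seed, 1, 2, 3)

    true_rates = prior.sample(n_outer, rng_outer)
    events, person_years = simulate_trial(true_rates, design, rng_outer)
    post_shape = prior.shape + events
    post_rate = prior.rate + person_years

    # inner probabilistic draws: posterior rates and common cost/utility draws
    post_rates = rng_inner.gamma(post_shape[:, None], 1.0 / post_rate, size=(n_outer, n_inner))
    params = draw_psa_parameters(inputs, rng_inner, size=(n_outer, n_inner))
    nb_trt = _arm_net_benefit(post_rates, params, inputs, True)
    nb_ctrl = _arm_net_benefit(np.full((n_outer, n_inner), inputs.control_rate), params, inputs, False)
    if not (np.all(np.isfinite(nb_trt)) and np.all(np.isfinite(nb_ctrl))):
        raise FloatingPointError("non-finite net benefit encountered in the inner loop")
    post_enb_trt = nb_trt.mean(axis=1)
    post_enb_ctrl = nb_ctrl.mean(axis=1)
    post_max = np.maximum(post_enb_trt, post_enb_ctrl)

    enb_ctrl, enb_trt, se_ctrl, se_trt = _prior_expected_nb(
        prior, inputs, n_outer * n_inner, rng_prior
    )
    prior_max = max(enb_ctrl, enb_trt)
    per_person = float(post_max.mean() - prior_max)
    se_outer = float(post_max.std(ddof=1) / math.sqrt(n_outer))
    se_prior = se_trt if enb_trt >= enb_ctrl else se_ctrl
    mc_se = math.hypot(se_outer, se_prior)

    eff_pop = effective_population(population)
    logger.info(
        "EVSI: per-person %.0f (MC se %.0f); effective population %.0f = "
        "sum_t %.0f/(1+%.2f)^t over %d years",
        per_person, mc_se, eff_pop, population.patients_per_year,
        population.discount, population.horizon_years,
    )
    return EVSIResult(
        per_person=per_person,
        population=per_person * eff_pop,
        mc_se=mc_se,
        n_outer=n_outer,
        n_inner=n_inner,
        seed=seed,
        prior=prior,
        effective_population=eff_pop,
        prior_expected_nb=(enb_ctrl, enb_trt),
    )


def effective_population(population: PopulationInputs) -> float:
    """Discounted number of patients the information would serve.

    ``sum_{t=0}^{h-1} patients_per_year * (1 + discount)^-t`` — the incident
    cohort in each year of the information horizon, discounted to decision
    time.
    """
    t = np.arange(population.horizon_years)
    return float(np.sum(population.patients_per_year * (1.0 + population.discount) ** (-t)))


def population_scale(per_person: float, population: PopulationInputs) -> float:
    """Scale a per-person value to the population over the information horizon."""
    if per_person < 0:
        raise ValueError("per_person must be >= 0")
    return per_person * effective_population(population)
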