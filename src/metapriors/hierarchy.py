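"""Bayesian hierarchical models for trial effects across disease areas.

Model 1 (no covariate):

    y_i     ~ N(theta_i, se_i^2)          (within-study, known SE)
    theta_i ~ N(mu_A, tau_A^2)            (between studies, within area)
    mu_A    ~ N(M, eta^2)                 (between areas)
    tau_A^2 ~ pi(kappa, nu)               (shared heterogeneity family)

Model 2 adds a common comparison-type shift: theta_i ~ N(mu_A + B*X_i,
tau_A^2) with X = 1 for active-vs-active comparisons.

Three families are supported for pi: log-normal (log tau^2 normal with
mean kappa, sd nu), gamma (shape kappa, scale nu), and a shifted
half-normal (location kappa, spread nu, support tau^2 >= kappa).
Vague hyperpriors follow the reference analysis: M ~ N(0, 1000^2),
eta ~ U(0, 5), B ~ N(0, 1000^2); log-normal kappa ~ N(0, 1000^2) and
nu ~ U(0, 5); gamma kappa, nu ~ U(0, 50); half-normal kappa ~
half-normal(0, 1000^2) truncated to [0, 100] and nu ~ U(0, 5).

Fitting is by a seeded Metropolis-within-Gibbs sampler: conjugate normal
updates for theta, mu, M and B; slice sampling for eta, kappa and nu; and
adaptive log-scale random-walk Metropolis for the tau_A^2 (adaptation
frozen after burn-in).  The contract is the posterior density, the seeds,
the array shapes and the diagnostics — not the sampling algorithm.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._mcmc import StepAdapter, slice_sample
from .dataset import TrialDataset

logger = logging.getLogger(__name__)

_VAGUE_SD = 1000.0  # sd of the vague normal hyperpriors on M, B and lognormal kappa
_ETA_UPPER = 5.0
_GAMMA_UPPER = 50.0
_HN_LOC_UPPER = 100.0
_LOG2PI = math.log(2.0 * math.pi)

VARIANCE_FAMILIES = ("lognormal", "gamma", "halfnormal")


# --------------------------------------------------------------------------
# specification containers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ModelSpec:
    """Which hierarchical model to fit and with which heterogeneity family.

    ``fixed`` pins named parameters (``M``, ``eta``, ``B``, ``kappa``,
    ``nu``, ``tau2``, ``mu``) to constants instead of sampling them; it is
    the mechanism behind the deterministic-oracle tests and behind
    single-area fits, where the area hierarchy is not identified.
    """

    model: str = "model1"  # "model1" | "model2"
    variance_family: str = "gamma"  # lognormal (a) | gamma (b) | halfnormal (c)
    fixed: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("model1", "model2"):
            raise ValueError("model must be 'model1' or 'model2'")
        if self.variance_family not in VARIANCE_FAMILIES:
            raise ValueError(f"variance_family must be one of {VARIANCE_FAMILIES}")

    @property
    def has_covariate(self) -> bool:
        return self.model == "model2"

    def label(self) -> str:
        suffix = {"lognormal": "a", "gamma": "b", "halfnormal": "c"}[self.variance_family]
        return ("1" if self.model == "model1" else "2") + suffix


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings.

    Defaults are the reference analysis' production scale: 3 chains and
    150,000 retained draws in total after 50,000 burn-in iterations per
    chain.  :meth:`test_scale` gives the reduced settings used throughout
    the test suite (3 chains x 5,000 draws after 2,000 burn-in).
    ``n_samples`` counts retained draws summed over chains.
    """

    n_chains: int = 3
    n_burn_in: int = 50_000
    n_samples: int = 150_000
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.05
    store_theta: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_burn_in < 0 or self.n_samples < self.n_chains:
            raise ValueError("iteration counts must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return self.n_samples // self.n_chains

    @classmethod
    def test_scale(cls, seed: int = 0, **kwargs) -> "McmcSettings":
        kwargs.setdefault("n_burn_in", 2_000)
        kwargs.setdefault("n_samples", 15_000)
        return cls(seed=seed, **kwargs)


# --------------------------------------------------------------------------
# heterogeneity-family log densities (pi and its hyperpriors)
# --------------------------------------------------------------------------
def _log_pi(tau2: np.ndarray, kappa: float, nu: float, family: str) -> np.ndarray:
    """Elementwise log pi(tau^2; kappa, nu); -inf outside support."""
    t = np.asarray(tau2, dtype=float)
    out = np.full(t.shape, -np.inf)
    if family == "lognormal":
        if nu <= 0:
            return out
        ok = t > 0
        lt = np.log(t[ok])
        out[ok] = -lt - math.log(nu) - 0.5 * _LOG2PI - (lt - kappa) ** 2 / (2 * nu**2)
    elif family == "gamma":
        if kappa <= 0 or nu <= 0:
            return out
        ok = t > 0
        out[ok] = (
            (kappa - 1) * np.log(t[ok])
            - t[ok] / nu
            - kappa * math.log(nu)
            - gammaln(kappa)
        )
    else:  # shifted half-normal, support t >= kappa
        if nu <= 0 or kappa < 0:
            return out
        ok = t >= kappa
        out[ok] = 0.5 * math.log(2.0 / math.pi) - math.log(nu) - (t[ok] - kappa) ** 2 / (2 * nu**2)
    return out


_LOG_NORM_VAGUE = -math.log(_VAGUE_SD) - 0.5 * _LOG2PI  # N(0, 1000^2) at its mode
_LOG_HN_VAGUE = 0.5 * math.log(2.0 / math.pi) - math.log(_VAGUE_SD)
# truncation mass of half-normal(0, 1000^2) on [0, 100]
_LOG_HN_TRUNC = math.log(math.erf(_HN_LOC_UPPER / (_VAGUE_SD * math.sqrt(2.0))))


def _log_hyper(kappa: float, nu: float, eta: float, family: str) -> float:
    """Log of the vague hyperpriors on (kappa, nu) plus eta; -inf off support.

    Fully normalized, so :func:`log_posterior` can be compared directly
    against independently coded densities.
    """
    if not (0.0 < eta < _ETA_UPPER):
        return -np.inf
    lp = -math.log(_ETA_UPPER)  # eta ~ U(0, 5)
    if family == "lognormal":
        if not (0.0 < nu < _ETA_UPPER):
            return -np.inf
        return lp - math.log(_ETA_UPPER) + _LOG_NORM_VAGUE - 0.5 * (kappa / _VAGUE_SD) ** 2
    if family == "gamma":
        if not (0.0 < kappa < _GAMMA_UPPER and 0.0 < nu < _GAMMA_UPPER):
            return -np.inf
        return lp - 2.0 * math.log(_GAMMA_UPPER)
    if not (0.0 <= kappa <= _HN_LOC_UPPER and 0.0 < nu < _ETA_UPPER):
        return -np.inf
    return (
        lp
        - math.log(_ETA_UPPER)
        + _LOG_HN_VAGUE
        - _LOG_HN_TRUNC
        - 0.5 * (kappa / _VAGUE_SD) ** 2
    )


# --------------------------------------------------------------------------
# joint log posterior (the model's contract)
# --------------------------------------------------------------------------
def log_posterior(spec: ModelSpec, data: TrialDataset, point: Mapping[str, object]) -> float:
    """Log joint density (up to a constant) at a full parameter point.

    ``point`` carries scalars ``M``, ``eta``, ``kappa``, ``nu`` (and ``B``
    under model 2) plus arrays ``mu`` and ``tau2`` of length ``n_areas``
    and ``theta`` of length ``len(data)``.  Points outside the support
    return ``-inf``.
    """
    y, se, a = data.y, data.se, data.area_codes
    n_areas = data.n_areas
    mu = np.asarray(point["mu"], dtype=float)
    tau2 = np.asarray(point["tau2"], dtype=float)
    theta = np.asarray(point["theta"], dtype=float)
    if mu.shape != (n_areas,) or tau2.shape != (n_areas,):
        raise ValueError(f"mu/tau2 must have shape ({n_areas},)")
    if theta.shape != (len(data),):
        raise ValueError(f"theta must have shape ({len(data)},)")
    M = float(point["M"])
    eta = float(point["eta"])
    kappa = float(point["kappa"])
    nu = float(point["nu"])
    B = float(point.get("B", 0.0)) if spec.has_covariate else 0.0

    lp = _log_hyper(kappa, nu, eta, spec.variance_family)
    if not np.isfinite(lp):
        return -np.inf
    if np.any(tau2 <= 0) and spec.variance_family != "halfnormal":
        return -np.inf
    log_pi_terms = _log_pi(tau2, kappa, nu, spec.variance_family)
    if not np.all(np.isfinite(log_pi_terms)):
        return -np.inf
    lp += float(np.sum(log_pi_terms))
    lp += _LOG_NORM_VAGUE - 0.5 * (M / _VAGUE_SD) ** 2
    if spec.has_covariate:
        lp += _LOG_NORM_VAGUE - 0.5 * (B / _VAGUE_SD) ** 2
    # areas: mu_A ~ N(M, eta^2)
    lp += float(np.sum(-0.5 * _LOG2PI - math.log(eta) - (mu - M) ** 2 / (2 * eta**2)))
    # studies: theta_i ~ N(mu_A + B x_i, tau_A^2)
    x = data.x if spec.has_covariate else np.zeros(len(data))
    if spec.has_covariate and np.any(np.isnan(x)):
        raise ValueError("model2 requires comparison_type on every record")
    mean_i = mu[a] + B * x
    t_i = tau2[a]
    if np.any(t_i <= 0):
        return -np.inf
    lp += float(
        np.sum(-0.5 * _LOG2PI - 0.5 * np.log(t_i) - (theta - mean_i) ** 2 / (2 * t_i))
    )
    # likelihood: y_i ~ N(theta_i, se_i^2)
    lp += float(
        np.sum(-0.5 * _LOG2PI - np.log(se) - (y - theta) ** 2 / (2 * se**2))
    )
    return lp


def residual_deviance(data: TrialDataset, theta: np.ndarray) -> float:
    """Sum of squared standardized residuals, sum_i (y_i - theta_i)^2 / se_i^2.

    The additive log(2*pi*se^2) constant is omitted; it cancels in model
    comparison.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != len(data):
        raise ValueError("theta length must equal the record count")
    return float(np.sum((data.y - theta) ** 2 / data.se**2, axis=-1))


# --------------------------------------------------------------------------
# posterior draws and diagnostics containers
# --------------------------------------------------------------------------
@dataclass
class PosteriorDraws:
    """Joint MCMC samples with chain structure (chains x draws [x dim])."""

    M: np.ndarray
    eta: np.ndarray
    kappa: np.ndarray
    nu: np.ndarray
    mu: np.ndarray
    tau2: np.ndarray
    B: np.ndarray | None
    theta: np.ndarray | None
    deviance: np.ndarray  # residual deviance per draw
    theta_mean: np.ndarray  # running posterior mean of theta
    area_index: dict[str, int]
    spec: ModelSpec
    seed: int

    @property
    def n_chains(self) -> int:
        return self.M.shape[0]

    @property
    def n_draws(self) -> int:
        return self.M.shape[1]

    @property
    def areas(self) -> list[str]:
        return [a for a, _ in sorted(self.area_index.items(), key=lambda kv: kv[1])]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains flattened into the first axis."""
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"{name} draws were not stored")
        return arr.reshape(-1, *arr.shape[2:])

    def monitored(self) -> dict[str, np.ndarray]:
        """Name -> (chains, draws) array for every scalar monitored quantity."""
        out = {"M": self.M, "eta": self.eta, "kappa": self.kappa, "nu": self.nu}
        if self.B is not None:
            out["B"] = self.B
        for k, area in enumerate(self.areas):
            out[f"mu[{area}]"] = self.mu[:, :, k]
            out[f"tau2[{area}]"] = self.tau2[:, :, k]
        return out

    def to_arviz(self):
        """Convert to an ``arviz.InferenceData`` (requires arviz)."""
        import arviz as az

        data = {"M": self.M, "eta": self.eta, "kappa": self.kappa, "nu": self.nu,
                "mu": self.mu, "tau2": self.tau2}
        if self.B is not None:
            data["B"] = self.B
        return az.from_dict(posterior=data, coords={"area": self.areas},
                            dims={"mu": ["area"], "tau2": ["area"]})

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "area_index": self.area_index,
            "spec": {"model": self.spec.model, "variance_family": self.spec.variance_family,
                     "fixed": {k: np.asarray(v).tolist() for k, v in self.spec.fixed.items()}},
            "seed": self.seed,
        }
        arrays = {
            "M": self.M, "eta": self.eta, "kappa": self.kappa, "nu": self.nu,
            "mu": self.mu, "tau2": self.tau2, "deviance": self.deviance,
            "theta_mean": self.theta_mean,
            "meta_json": np.array(json.dumps(meta)),
        }
        if self.B is not None:
            arrays["B"] = self.B
        if self.theta is not None:
            arrays["theta"] = self.theta
        np.savez_compressed(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta_json"]))
            spec = ModelSpec(
                model=meta["spec"]["model"],
                variance_family=meta["spec"]["variance_family"],
                fixed=meta["spec"]["fixed"],
            )
            return cls(
                M=z["M"], eta=z["eta"], kappa=z["kappa"], nu=z["nu"],
                mu=z["mu"], tau2=z["tau2"],
                B=z["B"] if "B" in z else None,
                theta=z["theta"] if "theta" in z else None,
                deviance=z["deviance"], theta_mean=z["theta_mean"],
                area_index={k: int(v) for k, v in meta["area_index"].items()},
                spec=spec, seed=int(meta["seed"]),
            )


@dataclass(frozen=True)
class FitDiagnostics:
    """Convergence and fit summaries for one MCMC run."""

    rhat: dict[str, float]
    dbar: float
    p_d: float
    dic: float
    converged: bool
    rhat_threshold: float
    accept_tau2: float

    def __post_init__(self) -> None:
        if not math.isclose(self.dic, self.dbar + self.p_d, rel_tol=0, abs_tol=1e-9):
            raise ValueError("DIC must equal Dbar + pD")

    def to_json(self) -> str:
        return json.dumps(
            {
                "rhat": self.rhat,
                "dbar": self.dbar,
                "p_d": self.p_d,
                "dic": self.dic,
                "converged": self.converged,
                "rhat_threshold": self.rhat_threshold,
                "accept_tau2": self.accept_tau2,
            },
            indent=2,
        )


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for a (chains, draws) array."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    n_chains, n_draws = x.shape
    if n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    if n_draws < 10:
        raise ValueError("Gelman-Rubin diagnostic needs at least 10 draws per chain")
    half = n_draws // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        return np.nan  # constant chains: diagnostic undefined
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def gelman_rubin(draws: PosteriorDraws, parameter: str) -> float:
    """Split-R̂ for one monitored parameter (e.g. ``"M"`` or ``"mu[oncology]"``)."""
    monitored = draws.monitored()
    if parameter not in monitored:
        raise KeyError(f"unknown parameter {parameter!r}; monitored: {sorted(monitored)}")
    return split_rhat(monitored[parameter])


def compute_dic(draws: PosteriorDraws, data: TrialDataset) -> tuple[float, float, float]:
    """Deviance information criterion from the study-effect focus.

    Dbar is the posterior mean residual deviance, pD = Dbar - D(theta_hat)
    with theta_hat the posterior mean of the study effects, and
    DIC = Dbar + pD.
    """
    if draws.theta is not None:
        dev = np.array([residual_deviance(data, th) for th in draws.stacked("theta")])
        dbar = float(dev.mean())
        theta_hat = draws.stacked("theta").mean(axis=0)
    else:
        dbar = float(draws.deviance.mean())
        theta_hat = draws.theta_mean
    d_hat = residual_deviance(data, theta_hat)
    p_d = dbar - d_hat
    return dbar, p_d, dbar + p_d


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------
class _ChainState:
    """Mutable per-chain parameter state."""

    __slots__ = ("M", "eta", "kappa", "nu", "B", "mu", "tau2", "theta")

    def __init__(self, M, eta, kappa, nu, B, mu, tau2, theta):
        self.M, self.eta, self.kappa, self.nu, self.B = M, eta, kappa, nu, B
        self.mu, self.tau2, self.theta = mu, tau2, theta


class HierarchicalEffectsModel:
    """Hierarchical model over a :class:`TrialDataset`, statsmodels-style.

    Build from a dataset (or :meth:`from_dataframe`), then :meth:`fit`
    returns a :class:`HierarchicalEffectsResults` carrying the posterior
    draws, convergence/DIC diagnostics, a ``summary()`` table and the
    predictive-prior exports.

    Examples
    --------
    >>> from metapriors import GeneratorConfig, simulate_dataset
    >>> data, truth = simulate_dataset(GeneratorConfig(seed=1))
    >>> model = HierarchicalEffectsModel(data, variance_family="gamma")
    >>> res = model.fit(McmcSettings.test_scale(seed=1))   # doctest: +SKIP
    """

    def __init__(
        self,
        data: TrialDataset,
        spec: ModelSpec | None = None,
        *,
        model: str = "model1",
        variance_family: str = "gamma",
        fixed: Mapping[str, object] | None = None,
    ):
        if spec is None:
            spec = ModelSpec(model=model, variance_family=variance_family, fixed=dict(fixed or {}))
        self.spec = spec
        self.data = data
        if len(data) == 0:
            raise ValueError("cannot model an empty dataset")
        if np.any(data.area_codes < 0):
            raise ValueError(
                "dataset has records with a missing disease area; run filter_for_analysis first"
            )
        hierarchy_pinned = "tau2" in spec.fixed and ("eta" in spec.fixed or "mu" in spec.fixed)
        if data.n_areas < 2 and not hierarchy_pinned:
            raise ValueError(
                "hierarchical sharing across areas is undefined with fewer than 2 areas; "
                "either add areas or pin the hyperparameters via ModelSpec(fixed=...)"
            )
        if spec.has_covariate and np.any(np.isnan(data.x)):
            raise ValueError("model2 requires comparison_type on every record")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "HierarchicalEffectsModel":
        return cls(TrialDataset.from_frame(frame), **kwargs)

    # -- density ----------------------------------------------------------
    def log_posterior(self, point: Mapping[str, object]) -> float:
        return log_posterior(self.spec, self.data, point)

    # -- initial values ---------------------------------------------------
    def _initial_state(self, rng: np.random.Generator) -> _ChainState:
        data, spec = self.data, self.spec
        y, se, a = data.y, data.se, data.area_codes
        n_areas = data.n_areas
        fixed = spec.fixed
        area_n = np.bincount(a, minlength=n_areas).astype(float)
        area_mean = np.bincount(a, weights=y, minlength=n_areas) / area_n

        mu = np.asarray(fixed["mu"], dtype=float).copy() if "mu" in fixed else (
            area_mean + 0.1 * rng.standard_normal(n_areas)
        )
        if "tau2" in fixed:
            tau2 = np.broadcast_to(np.asarray(fixed["tau2"], dtype=float), (n_areas,)).copy()
        else:
            resid2 = np.bincount(a, weights=(y - area_mean[a]) ** 2, minlength=n_areas) / area_n
            tau2 = np.clip(resid2 - np.bincount(a, weights=se**2, minlength=n_areas) / area_n, 0.01, None)
            tau2 *= np.exp(0.3 * rng.standard_normal(n_areas))
        M = float(fixed.get("M", float(np.mean(area_mean)) + 0.1 * rng.standard_normal()))
        eta = float(fixed.get("eta", np.clip(np.std(area_mean) + 0.05, 0.05, _ETA_UPPER - 0.1)))
        if "eta" not in fixed:
            eta = float(np.clip(eta * np.exp(0.3 * rng.standard_normal()), 0.02, _ETA_UPPER - 0.05))
        B = float(fixed.get("B", 0.05 * rng.standard_normal())) if spec.has_covariate else 0.0

        family = spec.variance_family
        if family == "lognormal":
            kappa = float(fixed.get("kappa", np.mean(np.log(tau2))))
            nu = float(fixed.get("nu", np.clip(np.std(np.log(tau2)) + 0.2, 0.1, _ETA_UPPER - 0.1)))
        elif family == "gamma":
            m, v = float(np.mean(tau2)), float(np.var(tau2) + 1e-4)
            kappa = float(fixed.get("kappa", np.clip(m**2 / v, 0.1, _GAMMA_UPPER - 1)))
            nu = float(fixed.get("nu", np.clip(v / m, 1e-3, _GAMMA_UPPER - 1)))
        else:
            kappa = float(fixed.get("kappa", 0.0))
            nu = float(fixed.get("nu", np.clip(np.std(tau2) + 0.1, 0.05, _ETA_UPPER - 0.1)))
            tau2 = np.maximum(tau2, kappa + 1e-6)
        theta = y + 0.01 * rng.standard_normal(len(y))
        return _ChainState(M, eta, kappa, nu, B, mu, tau2, theta)

    # -- fit --------------------------------------------------------------
    def fit(self, settings: McmcSettings | None = None, **kwargs) -> "HierarchicalEffectsResults":
        """Run the sampler and return a results object.

        Any :class:`McmcSettings` field may be passed as a keyword instead
        of a full settings object.
        """
        if settings is None:
            settings = McmcSettings(**kwargs)
        elif kwargs:
            raise TypeError("pass either a settings object or keyword overrides, not both")
        data, spec = self.data, self.spec
        n_areas, n = data.n_areas, len(data)
        draws_per_chain = settings.draws_per_chain
        root = np.random.SeedSequence(settings.seed)
        chain_seeds = root.spawn(settings.n_chains)

        chains: list[dict[str, np.ndarray]] = []
        accept_rates = []
        for c in range(settings.n_chains):
            rng = np.random.default_rng(chain_seeds[c])
            state = self._initial_state(rng)
            store, acc = self._run_chain(state, rng, settings, draws_per_chain)
            chains.append(store)
            accept_rates.append(acc)

        def stack(name):
            return np.stack([ch[name] for ch in chains])

        draws = PosteriorDraws(
            M=stack("M"), eta=stack("eta"), kappa=stack("kappa"), nu=stack("nu"),
            mu=stack("mu"), tau2=stack("tau2"),
            B=stack("B") if spec.has_covariate else None,
            theta=stack("theta") if settings.store_theta else None,
            deviance=stack("deviance"),
            theta_mean=np.mean([ch["theta_sum"] / draws_per_chain for ch in chains], axis=0),
            area_index=dict(data.area_index),
            spec=spec,
            seed=settings.seed,
        )
        diagnostics = self._diagnose(draws, settings, float(np.mean(accept_rates)))
        return HierarchicalEffectsResults(self, draws, diagnostics, settings)

    def _run_chain(self, state, rng, settings, draws_per_chain):
        data, spec = self.data, self.spec
        fixed = spec.fixed
        family = spec.variance_family
        y, se, a = data.y, data.se, data.area_codes
        x = np.nan_to_num(data.x) if spec.has_covariate else np.zeros(len(y))
        has_x1 = spec.has_covariate and np.any(x > 0)
        n_areas, n = data.n_areas, len(y)
        inv_se2 = 1.0 / se**2
        y_prec = y * inv_se2
        area_n = np.bincount(a, minlength=n_areas).astype(float)
        sample = {p: p not in fixed for p in ("M", "eta", "kappa", "nu", "B", "mu", "tau2")}
        if not spec.has_covariate:
            sample["B"] = False
        adapter = StepAdapter(n_areas)
        n_accept = 0
        n_prop = 0

        total = settings.n_burn_in + draws_per_chain * settings.thin
        store = {
            "M": np.empty(draws_per_chain), "eta": np.empty(draws_per_chain),
            "kappa": np.empty(draws_per_chain), "nu": np.empty(draws_per_chain),
            "B": np.empty(draws_per_chain),
            "mu": np.empty((draws_per_chain, n_areas)),
            "tau2": np.empty((draws_per_chain, n_areas)),
            "deviance": np.empty(draws_per_chain),
            "theta_sum": np.zeros(n),
        }
        if settings.store_theta:
            store["theta"] = np.empty((draws_per_chain, n))
        kept = 0
        for it in range(total):
            burn = it < settings.n_burn_in
            # θ_i | rest (conjugate)
            mean_i = state.mu[a] + state.B * x
            prec = inv_se2 + 1.0 / state.tau2[a]
            m = (y_prec + mean_i / state.tau2[a]) / prec
            state.theta = m + rng.standard_normal(n) / np.sqrt(prec)
            # μ_A | rest (conjugate)
            if sample["mu"]:
                resid = state.theta - state.B * x
                s_a = np.bincount(a, weights=resid, minlength=n_areas)
                prec_a = area_n / state.tau2 + 1.0 / state.eta**2
                m_a = (s_a / state.tau2 + state.M / state.eta**2) / prec_a
                state.mu = m_a + rng.standard_normal(n_areas) / np.sqrt(prec_a)
            # B | rest (conjugate)
            if sample["B"] and has_x1:
                w_i = x / state.tau2[a]
                prec_b = float(np.sum(w_i * x)) + 1.0 / _VAGUE_SD**2
                m_b = float(np.sum(w_i * (state.theta - state.mu[a]))) / prec_b
                state.B = m_b + rng.standard_normal() / math.sqrt(prec_b)
            # M | rest (conjugate)
            if sample["M"]:
                prec_m = n_areas / state.eta**2 + 1.0 / _VAGUE_SD**2
                m_m = float(np.sum(state.mu)) / state.eta**2 / prec_m
                state.M = m_m + rng.standard_normal() / math.sqrt(prec_m)
            # η | rest (slice, U(0,5) prior)
            if sample["eta"]:
                ss_mu = float(np.sum((state.mu - state.M) ** 2))

                def logf_eta(e, _ss=ss_mu, _A=n_areas):
                    if not 0.0 < e < _ETA_UPPER:
                        return -np.inf
                    return -_A * math.log(e) - _ss / (2 * e * e)

                state.eta = slice_sample(logf_eta, state.eta, 0.5, rng, 1e-8, _ETA_UPPER)
            # τ²_A | rest (log-scale Metropolis, vectorized over areas)
            if sample["tau2"]:
                resid2 = (state.theta - state.mu[a] - state.B * x) ** 2
                ssr = np.bincount(a, weights=resid2, minlength=n_areas)
                logt = np.log(state.tau2)
                prop = logt + adapter.step * rng.standard_normal(n_areas)
                t_new = np.exp(prop)

                def tau2_logpost(t, lt):
                    return (
                        -0.5 * area_n * lt
                        - ssr / (2 * t)
                        + _log_pi(t, state.kappa, state.nu, family)
                        + lt  # Jacobian of the log transform
                    )

                log_acc = tau2_logpost(t_new, prop) - tau2_logpost(state.tau2, logt)
                accept = np.log(rng.uniform(size=n_areas) + 1e-300) < log_acc
                state.tau2 = np.where(accept, t_new, state.tau2)
                if burn:
                    adapter.update(accept)
                else:
                    n_accept += int(accept.sum())
                    n_prop += n_areas
            # κ, ν | τ² (slice)
            if sample["kappa"] or sample["nu"]:
                self._update_family(state, rng, family, sample)
            if not burn and (it - settings.n_burn_in) % settings.thin == 0:
                store["M"][kept] = state.M
                store["eta"][kept] = state.eta
                store["kappa"][kept] = state.kappa
                store["nu"][kept] = state.nu
                store["B"][kept] = state.B
                store["mu"][kept] = state.mu
                store["tau2"][kept] = state.tau2
                store["deviance"][kept] = float(np.sum((y - state.theta) ** 2 * inv_se2))
                store["theta_sum"] += state.theta
                if settings.store_theta:
                    store["theta"][kept] = state.theta
                kept += 1
        acc_rate = n_accept / n_prop if n_prop else float("nan")
        return store, acc_rate

    @staticmethod
    def _update_family(state, rng, family, sample):
        t = state.tau2
        A = len(t)
        if family == "lognormal":
            lt = np.log(t)
            s1, s2 = float(lt.sum()), float((lt**2).sum())
            if sample["kappa"]:

                def logf_k(k):
                    return -(s2 - 2 * k * s1 + A * k * k) / (2 * state.nu**2) - 0.5 * (k / _VAGUE_SD) ** 2

                state.kappa = slice_sample(logf_k, state.kappa, 1.0, rng)
            if sample["nu"]:
                ss = float(((lt - state.kappa) ** 2).sum())

                def logf_n(v):
                    if not 0.0 < v < _ETA_UPPER:
                        return -np.inf
                    return -A * math.log(v) - ss / (2 * v * v)

                state.nu = slice_sample(logf_n, state.nu, 0.5, rng, 1e-8, _ETA_UPPER)
        elif family == "gamma":
            slog, s = float(np.log(t).sum()), float(t.sum())
            if sample["kappa"]:

                def logf_k(k):
                    if not 0.0 < k < _GAMMA_UPPER:
                        return -np.inf
                    return (k - 1) * slog - A * (k * math.log(state.nu) + gammaln(k))

                state.kappa = slice_sample(logf_k, state.kappa, 1.0, rng, 1e-8, _GAMMA_UPPER)
            if sample["nu"]:

                def logf_n(v):
                    if not 0.0 < v < _GAMMA_UPPER:
                        return -np.inf
                    return -s / v - A * state.kappa * math.log(v)

                state.nu = slice_sample(logf_n, state.nu, max(0.2, state.nu), rng, 1e-8, _GAMMA_UPPER)
        else:  # halfnormal
            t_min = float(t.min())
            if sample["kappa"]:

                def logf_k(k):
                    if not 0.0 <= k <= min(_HN_LOC_UPPER, t_min):
                        return -np.inf
                    return -float(((t - k) ** 2).sum()) / (2 * state.nu**2) - 0.5 * (k / _VAGUE_SD) ** 2

                state.kappa = slice_sample(
                    logf_k, min(state.kappa, t_min), 0.2, rng, 0.0, min(_HN_LOC_UPPER, t_min)
                )
            if sample["nu"]:
                ss = float(((t - state.kappa) ** 2).sum())

                def logf_n(v):
                    if not 0.0 < v < _ETA_UPPER:
                        return -np.inf
                    return -A * math.log(v) - ss / (2 * v * v)

                state.nu = slice_sample(logf_n, state.nu, 0.5, rng, 1e-8, _ETA_UPPER)

    def _diagnose(self, draws: PosteriorDraws, settings: McmcSettings, accept_tau2: float) -> FitDiagnostics:
        rhat: dict[str, float] = {}
        fixed = self.spec.fixed
        for name, arr in draws.monitored().items():
            base = name.split("[")[0]
            if base in fixed or (settings.n_chains < 2):
                continue
            rhat[name] = split_rhat(arr)
        dbar, p_d, dic = compute_dic(draws, self.data)
        finite = [v for v in rhat.values() if np.isfinite(v)]
        converged = bool(all(v <= settings.rhat_threshold for v in finite)) if finite else True
        if not converged:
            worst = max(rhat, key=lambda k: rhat[k] if np.isfinite(rhat[k]) else -np.inf)
            logger.warning(
                "fit flagged as non-converged: max rhat %.3f (%s) > %.3f",
                rhat[worst], worst, settings.rhat_threshold,
            )
        return FitDiagnostics(
            rhat=rhat, dbar=dbar, p_d=p_d, dic=dic,
            converged=converged, rhat_threshold=settings.rhat_threshold,
            accept_tau2=accept_tau2,
        )


def fit_model(
    data: TrialDataset, spec: ModelSpec, settings: McmcSettings
) -> tuple[PosteriorDraws, FitDiagnostics]:
    """Functional wrapper: fit and return (draws, diagnostics)."""
    res = HierarchicalEffectsModel(data, spec).fit(settings)
    return res.draws, res.diagnostics


class HierarchicalEffectsResults:
    """Posterior draws, diagnostics and derived outputs of one fit."""

    def __init__(
        self,
        model: HierarchicalEffectsModel,
        draws: PosteriorDraws,
        diagnostics: FitDiagnostics,
        settings: McmcSettings,
    ):
        self.model = model
        self.draws = draws
        self.diagnostics = diagnostics
        self.settings = settings

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def converged(self) -> bool:
        return self.diagnostics.converged

    def posterior_mean(self, name: str) -> np.ndarray | float:
        arr = self.draws.stacked(name)
        out = arr.mean(axis=0)
        return float(out) if np.ndim(out) == 0 else out

    def summary(self, credible_level: float = 0.95) -> pd.DataFrame:
        """Posterior summary table: mean, sd, equal-tail interval, rhat."""
        lo_q = (1 - credible_level) / 2
        rows = []
        for name, arr in self.draws.monitored().items():
            flat = arr.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    f"{100 * lo_q:g}%": np.quantile(flat, lo_q),
                    f"{100 * (1 - lo_q):g}%": np.quantile(flat, 1 - lo_q),
                    "rhat": self.diagnostics.rhat.get(name, np.nan),
                }
            )
        rows.append(
            {
                "parameter": "deviance",
                "mean": self.diagnostics.dbar,
                "sd": self.draws.deviance.std(ddof=1),
                f"{100 * lo_q:g}%": np.quantile(self.draws.deviance, lo_q),
                f"{100 * (1 - lo_q):g}%": np.quantile(self.draws.deviance, 1 - lo_q),
                "rhat": np.nan,
            }
        )
        return pd.DataFrame(rows).set_index("parameter")

    def credible_interval(self, name: str, level: float = 0.95) -> tuple:
        flat = self.draws.stacked(name)
        lo = np.quantile(flat, (1 - level) / 2, axis=0)
        hi = np.quantile(flat, (1 + level) / 2, axis=0)
        return lo, hi

    # predictive exports live in the predictive module; thin delegates here
    def predictive_samples(self, target, comparison="any", seed=0) -> np.ndarray:
        from .predictive import predictive_samples

        return predictive_samples(self.draws, target, comparison=comparison, seed=seed)

    def predictive_prior(self, target, comparison="any", seed=0, levels=(0.95,)):
        from .predictive import prior_from_draws

        return prior_from_draws(self.draws, target, comparison=comparison, seed=seed, levels=levels)

    def prior_table(self, seed: int = 0, **kwargs) -> pd.DataFrame:
        from .predictive import export_prior_table

        return export_prior_table(self.draws, seed=seed, **kwargs)

    def plot_priors(self, seed: int = 0, ax=None):
        from .predictive import plot_prior_table

        return plot_prior_table(self.prior_table(seed=seed), ax=ax)
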