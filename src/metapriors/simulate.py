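"""Synthetic trial-effect datasets drawn from the hierarchical model itself.

The generator mirrors the generative structure assumed by the analysis:
area means are exchangeable around an overall mean, between-study variances
are drawn from a log-normal / gamma / half-normal family, each study's true
effect is normal around its area mean (shifted by the comparison-type
coefficient), and the observed estimate adds known-SE sampling noise:

    mu_A   ~ N(M, eta^2)
    tau_A^2 ~ pi(kappa, nu)
    theta_i ~ N(mu_A + B * X_i, tau_A^2)
    y_i     ~ N(theta_i, se_i^2)

Standard errors are drawn independently of the effects (the model treats
them as fixed and known).  Every draw is reproducible from a single integer
seed, which fans out to one named substream per area so that adding an area
does not perturb the records of existing areas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .dataset import ACTIVE_VS_ACTIVE, ACTIVE_VS_INACTIVE, EffectRecord, TrialDataset

VARIANCE_FAMILIES = ("lognormal", "gamma", "halfnormal")


@dataclass(frozen=True)
class GeneratorConfig:
    """True parameter values and sampling layout for one synthetic dataset.

    Defaults are sized like the illustrative historical dataset on its
    analysis scale: an overall mean effect slightly favouring new
    treatments (M = -0.1 on the log OR/HR scale), moderate between-area
    spread (eta = 0.2), gamma-distributed between-study variances with mean
    0.06 (typical heterogeneity tau around 0.25), a small positive
    active-vs-active shift (B = 0.035), and study standard errors
    log-uniform on [0.05, 0.5].
    """

    M_true: float = -0.1
    eta_true: float = 0.2
    variance_family: str = "gamma"
    family_params: tuple[float, float] = (2.0, 0.03)  # (kappa, nu)
    B_true: float = 0.035
    area_sizes: Mapping[str, int] | Sequence[int] | int = 9
    records_per_area: int = 30
    prop_active: float | Mapping[str, float] = 0.5
    se_law: tuple = ("loguniform", 0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta_true < 0:
            raise ValueError("eta_true must be >= 0")
        if self.variance_family not in VARIANCE_FAMILIES:
            raise ValueError(f"variance_family must be one of {VARIANCE_FAMILIES}")
        sizes = self.resolved_area_sizes()
        if any(n <= 0 for n in sizes.values()):
            raise ValueError("area_sizes must be positive integers")
        for p in self._prop_active_map(sizes):
            if not 0.0 <= p <= 1.0:
                raise ValueError("prop_active must lie in [0, 1]")

    def resolved_area_sizes(self) -> dict[str, int]:
        if isinstance(self.area_sizes, int):
            return {f"area_{k + 1:02d}": int(self.records_per_area) for k in range(self.area_sizes)}
        if isinstance(self.area_sizes, Mapping):
            return {str(a): int(n) for a, n in self.area_sizes.items()}
        return {f"area_{k + 1:02d}": int(n) for k, n in enumerate(self.area_sizes)}

    def _prop_active_map(self, sizes: dict[str, int]) -> list[float]:
        if isinstance(self.prop_active, Mapping):
            return [float(self.prop_active.get(a, 0.5)) for a in sizes]
        return [float(self.prop_active)] * len(sizes)


@dataclass(frozen=True)
class TruthRecord:
    """All latent draws behind one synthetic dataset (for recovery tests)."""

    M: float
    eta: float
    variance_family: str
    family_params: tuple[float, float]
    B: float
    areas: tuple[str, ...]
    mu: tuple[float, ...]
    tau2: tuple[float, ...]
    theta: tuple[float, ...]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "M": self.M,
                "eta": self.eta,
                "variance_family": self.variance_family,
                "family_params": list(self.family_params),
                "B": self.B,
                "areas": list(self.areas),
                "mu": list(self.mu),
                "tau2": list(self.tau2),
                "theta": list(self.theta),
                "seed": self.seed,
            },
            indent=2,
        )


def _draw_tau2(family: str, kappa: float, nu: float, rng: np.random.Generator) -> float:
    """One between-study variance from the chosen family (support [0, inf))."""
    if family == "lognormal":
        # log tau^2 ~ N(kappa, nu^2); nu = 0 degenerates to exp(kappa)
        return float(np.exp(kappa + nu * rng.standard_normal())) if nu > 0 else float(np.exp(kappa))
    if family == "gamma":
        # shape kappa, scale nu
        return float(rng.gamma(kappa, nu)) if kappa > 0 and nu > 0 else 0.0
    # shifted half-normal: location kappa >= 0, spread nu
    if kappa < 0:
        raise ValueError("half-normal location must be >= 0 for a variance")
    return float(kappa + abs(nu * rng.standard_normal()))


def _draw_se(se_law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = se_law[0]
    if kind == "loguniform":
        lo, hi = float(se_law[1]), float(se_law[2])
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    if kind == "constant":
        return np.full(n, float(se_law[1]))
    raise ValueError(f"unknown se law {se_law!r}")


def _area_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_dataset(config: GeneratorConfig) -> tuple[TrialDataset, TruthRecord]:
    """Draw one dataset (and the latent truth) from the generative model."""
    sizes = config.resolved_area_sizes()
    areas = list(sizes)
    props = config._prop_active_map(sizes)
    kappa, nu = config.family_params

    hyper_rng = _area_rng(config.seed, 0)
    mu = np.empty(len(areas))
    tau2 = np.empty(len(areas))
    records: list[EffectRecord] = []
    theta_all: list[float] = []
    for k, (area, n_k) in enumerate(sizes.items()):
        rng = _area_rng(config.seed, k + 1)
        mu[k] = config.M_true + config.eta_true * rng.standard_normal()
        tau2[k] = _draw_tau2(config.variance_family, kappa, nu, rng)
        x = (rng.uniform(size=n_k) < props[k]).astype(float)
        theta = mu[k] + config.B_true * x + np.sqrt(tau2[k]) * rng.standard_normal(n_k)
        se = _draw_se(config.se_law, n_k, rng)
        y = theta + se * rng.standard_normal(n_k)
        theta_all.extend(theta.tolist())
        for j in range(n_k):
            records.append(
                EffectRecord(
                    study_id=f"{area}_s{j + 1:03d}",
                    y=float(y[j]),
                    se=float(se[j]),
                    disease_area=area,
                    comparison_type=ACTIVE_VS_ACTIVE if x[j] else ACTIVE_VS_INACTIVE,
                )
            )
    del hyper_rng  # hyper-level stream reserved for future layout changes
    truth = TruthRecord(
        M=config.M_true,
        eta=config.eta_true,
        variance_family=config.variance_family,
        family_params=(float(kappa), float(nu)),
        B=config.B_true,
        areas=tuple(areas),
        mu=tuple(float(v) for v in mu),
        tau2=tuple(float(v) for v in tau2),
        theta=tuple(theta_all),
        seed=config.seed,
    )
    return TrialDataset(records), truth


class Fixture(NamedTuple):
    config: GeneratorConfig
    dataset: TrialDataset
    truth: TruthRecord


#: Disease-area labels used by the composition-shaped fixture.
_TABLE_SHAPE_AREAS = {
    "circulatory": 3,
    "digestive": 1,
    "musculoskeletal": 1,
    "nervous": 2,
    "health_services": 2,
    "injury": 1,
    "mental_health": 2,
    "obstetrics": 2,
    "oncology": 100,
}


def make_fixture_suite(root_seed: int = 0) -> dict[str, Fixture]:
    """Named, deterministic fixtures covering the layouts the tests need.

    ``table1_shape`` reproduces the historical dataset's composition at
    reduced scale: nine areas, one dominant area holding ~87.7% of records,
    and a mostly-active comparator mix in the dominant area.
    """
    suite: dict[str, Fixture] = {}

    table1 = GeneratorConfig(
        area_sizes=_TABLE_SHAPE_AREAS,
        prop_active={**{a: 0.5 for a in _TABLE_SHAPE_AREAS}, "oncology": 0.84},
        seed=root_seed + 11,
    )
    balanced = GeneratorConfig(
        area_sizes=4,
        records_per_area=8,
        seed=root_seed + 23,
    )
    single = GeneratorConfig(
        area_sizes={"oncology": 12},
        seed=root_seed + 37,
    )
    for name, cfg in (("table1_shape", table1), ("balanced_small", balanced), ("single_area", single)):
        data, truth = simulate_dataset(cfg)
        suite[name] = Fixture(cfg, data, truth)
    return suite
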