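"""Independent oracles used by the hierarchy tests.

These deliberately re-derive quantities through different code paths
(scipy.stats densities, deterministic quadrature) from the implementation
they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from metapriors.dataset import EffectRecord, TrialDataset


def toy_dataset(y, se, areas, comparison=None) -> TrialDataset:
    records = []
    for i, (yi, si, ai) in enumerate(zip(y, se, areas)):
        records.append(
            EffectRecord(
                study_id=f"t{i}",
                y=float(yi),
                se=float(si),
                disease_area=str(ai),
                comparison_type=None if comparison is None else comparison[i],
            )
        )
    return TrialDataset(records)


def density_oracle(spec, data, point) -> float:
    """Log joint density assembled term by term with scipy.stats."""
    y, se, a = data.y, data.se, data.area_codes
    mu = np.asarray(point["mu"], float)
    tau2 = np.asarray(point["tau2"], float)
    theta = np.asarray(point["theta"], float)
    M, eta = float(point["M"]), float(point["eta"])
    kappa, nu = float(point["kappa"]), float(point["nu"])
    B = float(point.get("B", 0.0))
    x = np.nan_to_num(data.x) if spec.has_covariate else np.zeros(len(y))

    lp = stats.norm.logpdf(y, theta, se).sum()
    lp += stats.norm.logpdf(theta, mu[a] + B * x, np.sqrt(tau2[a])).sum()
    lp += stats.norm.logpdf(mu, M, eta).sum()
    lp += stats.norm.logpdf(M, 0, 1000.0)
    lp += stats.uniform.logpdf(eta, 0, 5.0)
    if spec.has_covariate:
        lp += stats.norm.logpdf(B, 0, 1000.0)
    if spec.variance_family == "lognormal":
        lp += stats.lognorm.logpdf(tau2, s=nu, scale=np.exp(kappa)).sum()
        lp += stats.norm.logpdf(kappa, 0, 1000.0)
        lp += stats.uniform.logpdf(nu, 0, 5.0)
    elif spec.variance_family == "gamma":
        lp += stats.gamma.logpdf(tau2, a=kappa, scale=nu).sum()
        lp += stats.uniform.logpdf(kappa, 0, 50.0).sum()
        lp += stats.uniform.logpdf(nu, 0, 50.0).sum()
    else:
        lp += stats.halfnorm.logpdf(tau2, loc=kappa, scale=nu).sum()
        # half-normal(0, 1000^2) truncated to [0, 100]
        lp += stats.halfnorm.logpdf(kappa, 0, 1000.0) - np.log(
            stats.halfnorm.cdf(100.0, 0, 1000.0)
        )
        lp += stats.uniform.logpdf(nu, 0, 5.0)
    return float(lp)


def quadrature_posterior_mu(data, tau2, eta, prior_sd_m=1000.0, grid_half_width=4.0, n_grid=4001):
    """Posterior means of the area effects with tau^2 and eta pinned.

    Marginalizes the study effects analytically (y_i | mu_A is normal with
    variance se_i^2 + tau_A^2), then integrates the overall mean M on a
    dense grid: p(M | y) is proportional to the prior times the product
    over areas of the normal marginal of the area's precision-weighted
    mean.  E[mu_A | y] follows by iterated expectation, E[mu_A | M] being
    linear in M.
    """
    y, se, a = data.y, data.se, data.area_codes
    tau2 = np.asarray(tau2, float)
    n_areas = data.n_areas
    v = se**2 + tau2[a]
    prec_d = np.array([np.sum(1.0 / v[a == k]) for k in range(n_areas)])
    mean_d = np.array([np.sum(y[a == k] / v[a == k]) for k in range(n_areas)]) / prec_d

    center = float(np.mean(mean_d))
    spread = grid_half_width * float(np.sqrt(eta**2 + 1.0 / prec_d.min()))
    grid = np.linspace(center - spread, center + spread, n_grid)

    marg_var = eta**2 + 1.0 / prec_d  # per area
    loglik = np.sum(
        -0.5 * (mean_d[None, :] - grid[:, None]) ** 2 / marg_var[None, :], axis=1
    )
    loglik += -0.5 * (grid / prior_sd_m) ** 2
    w = np.exp(loglik - loglik.max())
    w /= w.sum()

    post_prec = prec_d + 1.0 / eta**2
    # E[mu_A | M] = (prec_d * mean_d + M / eta^2) / post_prec
    e_mu_given_m = (prec_d[None, :] * mean_d[None, :] + grid[:, None] / eta**2) / post_prec[None, :]
    e_mu = (w[:, None] * e_mu_given_m).sum(axis=0)
    e_m = float((w * grid).sum())
    return e_mu, e_m
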