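"""Shared fixtures.

The heavy MCMC fits are session-scoped so the recovery-preset chain is fitted
once and reused by every test that inspects it (partition recovery, effect
recovery, robustness comparisons).
"""

from __future__ import annotations

import numpy as np
import pytest

import profreg as pr
from profreg.synthetic import generate_dataset


def fit_dataset(dataset, mcmc_config, alpha_shape=2.0, alpha_rate=1.0):
    """Preprocess a synthetic dataset and run the sampler on it."""
    norm = pr.normalize_exposures(dataset.exposures)
    offset = pr.compute_offset(dataset.outcome)
    T = len(dataset.outcome)
    n_years = max(T / 365.25, 1.0)
    design = pr.build_confounder_design(
        np.arange(1, T + 1),
        dataset.temperature,
        time_df=max(int(round(8 * n_years)), 2),
        temp_df=3,
    )
    hyper = pr.empirical_hyperparams(
        norm, alpha_shape=alpha_shape, alpha_rate=alpha_rate
    )
    chain = pr.run_mcmc(norm.z, dataset.outcome, design, offset, hyper, mcmc_config)
    return {
        "dataset": dataset,
        "norm": norm,
        "offset": offset,
        "design": design,
        "hyper": hyper,
        "chain": chain,
    }


def true_relative_risks(dataset, config) -> np.ndarray:
    """The relative risks the model reports: cluster risk against the
    period-average rate, given the realised labels and confounder path.
    RR_k = exp(mu_k) * mean_t(lambda_t e^{-mu_{g_t}}) / mean(y)."""
    mu = config.true_log_rr
    lam = np.exp(dataset.true_log_rates)
    confounder_level = float(np.mean(lam * np.exp(-mu[dataset.true_labels - 1])))
    return np.exp(mu) * confounder_level / dataset.outcome.mean()


@pytest.fixture(scope="session")
def recovery_setup():
    """Recovery preset dataset plus a scaled-down MCMC fit (shared)."""
    config = pr.recovery_config(seed=11)
    dataset = generate_dataset(config)
    fit = fit_dataset(dataset, pr.McmcConfig.scaled_down(seed=101))
    fit["config"] = config
    S = pr.similarity_matrix(fit["chain"])
    fit["similarity"] = S
    fit["partition"] = pr.representative_partition(S, range(2, 8))
    return fit


@pytest.fixture(scope="session")
def recovery_missing_setup():
    """Same preset with 5% MCAR missingness injected."""
    config = pr.recovery_config(seed=11, missing_rate=0.05)
    dataset = generate_dataset(config)
    fit = fit_dataset(dataset, pr.McmcConfig.scaled_down(seed=101))
    fit["config"] = config
    S = pr.similarity_matrix(fit["chain"])
    fit["partition"] = pr.representative_partition(S, range(2, 8))
    return fit


@pytest.fixture(scope="session")
def cv_report():
    """One shared 3:1 predictive cross-validation on the recovery preset."""
    dataset = generate_dataset(pr.recovery_config(seed=21))
    split = dataset.dates[int(0.75 * len(dataset.dates))]
    return pr.cross_validate(
        dataset.dates,
        dataset.exposures,
        dataset.outcome,
        dataset.temperature,
        split,
        mcmc_config=pr.McmcConfig(n_iter=6000, burn_in=2000, thin=5, seed=22),
        seed=23,
    )


@pytest.fixture(scope="session")
def tiny_sampler_inputs():
    """Small complete-data inputs for unit-level sampler checks."""
    rng = np.random.default_rng(5)
    T, P = 40, 3
    z = rng.standard_normal((T, P))
    y = rng.poisson(20.0, size=T)
    temperature = rng.normal(12.0, 6.0, size=T)
    design = pr.build_confounder_design(np.arange(1, T + 1), temperature, 3, 2)
    offset = pr.OffsetSeries(E=np.full(T, 20.0))
    hyper = pr.empirical_hyperparams(pr.normalize_exposures(z))
    return {"z": z, "y": y, "design": design, "offset": offset, "hyper": hyper}
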