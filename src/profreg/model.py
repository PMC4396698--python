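"""Joint probability model: likelihood terms, priors, empirical hyperpriors.

The model mixes, over an unbounded number of components k with
stick-breaking weights w_k, a multivariate normal for the daily exposure
profile z_t and a Poisson for the daily count y_t:

    p(y_t, z_t | Theta, u_t) = sum_k w_k p(y_t | Theta_k, Theta_0, u_t)
                                       p(z_t | Theta_k)

with log rate  log E_t + mu_k + (U beta)_t + eps_t,  where mu_k is the
cluster log relative risk against the period-average rate E_t, U is the
fixed spline design and eps_t a Gaussian day effect.  Everything here is a
pure function of its arguments so the sampler and the test oracles can share
one definition of the target density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import DefinitenessError, DegenerateColumnError, ValidationError
from .preprocess import NormalizedExposureMatrix, OffsetSeries, SplineDesign

__all__ = [
    "Hyperparameters",
    "ClusterParams",
    "GlobalParams",
    "ModelState",
    "empirical_hyperparams",
    "stick_breaking",
    "mvn_logdensity",
    "poisson_logrates",
    "log_prior",
    "joint_logdensity",
]


@dataclass
class Hyperparameters:
    """Fixed hyperparameters, mostly set empirically from the data.

    m0/Sigma0 parameterise the Normal prior on cluster locations m_k
    (Sigma0 diagonal with squared empirical ranges); Phi/nu the Wishart
    prior on cluster precisions Q_k; (a, b) the Gamma prior on the DP
    concentration alpha; the Student-t settings the weakly informative
    priors on spline coefficients beta and cluster effects mu_k; the Gamma
    (shape, rate) pair the prior on the extra-Poisson precision 1/sigma_eps^2.
    """

    m0: np.ndarray
    Sigma0_diag: np.ndarray
    Phi: np.ndarray
    nu: float
    alpha_shape: float = 2.0
    alpha_rate: float = 1.0
    beta_df: float = 7.0
    beta_scale: float = 2.5
    mu_df: float = 7.0
    mu_scale: float = 2.5
    tau_eps_shape: float = 5.0
    tau_eps_rate: float = 0.5

    @property
    def P(self) -> int:
        return len(self.m0)


@dataclass
class ClusterParams:
    """Parameters of one mixture component."""

    m: np.ndarray  # (P,) location
    Q: np.ndarray  # (P, P) precision, symmetric positive-definite
    mu: float  # log relative risk


@dataclass
class GlobalParams:
    """Parameters shared across components."""

    beta: np.ndarray  # (H,) spline coefficients
    eps: np.ndarray  # (T,) day effects
    sigma_eps: float
    alpha: float


@dataclass
class ModelState:
    """One MCMC state.

    ``g`` holds 0-based allocations; ``V`` the stick-breaking fractions for
    the instantiated components; ``w`` the implied weights; cluster arrays
    are stacked over the instantiated components.  ``z`` is the exposure
    matrix with missing cells filled by the current imputations.
    """

    g: np.ndarray  # (T,) int
    V: np.ndarray  # (K,)
    w: np.ndarray  # (K,)
    m: np.ndarray  # (K, P)
    Q: np.ndarray  # (K, P, P)
    mu: np.ndarray  # (K,)
    beta: np.ndarray  # (H,)
    eps: np.ndarray  # (T,)
    sigma_eps: float
    alpha: float
    z: np.ndarray | None = None  # (T, P) imputed-complete exposures

    @property
    def K(self) -> int:
        return len(self.V)

    def occupancy(self) -> np.ndarray:
        return np.bincount(self.g, minlength=self.K)


def empirical_hyperparams(
    z: NormalizedExposureMatrix | np.ndarray, phi_mode: str = "diagonal", **overrides
) -> Hyperparameters:
    """Empirical-Bayes hyperparameters from the normalised exposure matrix.

    m0 = column means, Sigma0 = diag(squared column ranges), Phi the inverse
    empirical variance scaled by 1/P (element-wise on a diagonal by default;
    ``phi_mode='full'`` uses the inverse of the full empirical covariance
    instead), nu = P.  All statistics use observed entries only.
    """
    zmat = z.z if isinstance(z, NormalizedExposureMatrix) else np.asarray(z, dtype=float)
    P = zmat.shape[1]
    if np.any(np.sum(np.isfinite(zmat), axis=0) < 2):
        raise DegenerateColumnError("every column needs at least 2 observed values")
    m0 = np.nanmean(zmat, axis=0)
    ranges = np.nanmax(zmat, axis=0) - np.nanmin(zmat, axis=0)
    variances = np.nanvar(zmat, axis=0, ddof=1)
    if np.any(ranges <= 0) or np.any(variances <= 0):
        raise DegenerateColumnError("zero empirical range or variance in a column")
    if phi_mode == "diagonal":
        Phi = np.diag(1.0 / variances) / P
    elif phi_mode == "full":
        obs = zmat[np.all(np.isfinite(zmat), axis=1)]
        if obs.shape[0] <= P:
            raise DegenerateColumnError("too few complete rows for a full-matrix Phi")
        Phi = np.linalg.inv(np.cov(obs, rowvar=False)) / P
    else:
        raise ValidationError(f"unknown phi_mode {phi_mode!r}")
    return Hyperparameters(
        m0=m0, Sigma0_diag=ranges**2, Phi=Phi, nu=float(P), **overrides
    )


def stick_breaking(V: np.ndarray) -> np.ndarray:
    """Weights from stick-breaking fractions: w_k = V_k prod_{i<k} (1 - V_i)."""
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0.0) or np.any(V > 1.0):
        raise ValidationError("stick fractions must lie in (0, 1]")
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - V[:-1])])
    return V * remaining


def mvn_logdensity(z_t: np.ndarray, params: ClusterParams) -> float:
    """Multivariate normal log-density in precision form.

    NaN entries of ``z_t`` are treated as missing: the density is the
    marginal over the observed coordinates (Sigma restricted to them).
    """
    z_t = np.asarray(z_t, dtype=float)
    obs = np.isfinite(z_t)
    Q = np.asarray(params.Q, dtype=float)
    if not np.any(obs):
        return 0.0
    if np.all(obs):
        diff = z_t - params.m
        sign, logdet = np.linalg.slogdet(Q)
        if sign <= 0:
            raise DefinitenessError("cluster precision matrix is singular or indefinite")
        return float(
            -0.5 * len(z_t) * np.log(2.0 * np.pi)
            + 0.5 * logdet
            - 0.5 * diff @ Q @ diff
        )
    Sigma = np.linalg.inv(Q)
    sub = Sigma[np.ix_(obs, obs)]
    return float(
        stats.multivariate_normal.logpdf(z_t[obs], mean=params.m[obs], cov=sub)
    )


def poisson_logrates(
    state: ModelState, design: SplineDesign, offset: OffsetSeries, y: np.ndarray
) -> tuple[np.ndarray, float]:
    """Log rates log(lambda_t) and the Poisson log-likelihood of y.

    log lambda_t = log E_t + mu_{g_t} + (U beta)_t + eps_t.
    """
    y = np.asarray(y, dtype=float)
    loglam = (
        np.log(offset.E) + state.mu[state.g] + design.basis @ state.beta + state.eps
    )
    if not np.all(np.isfinite(loglam)):
        raise ValidationError("non-finite log rate")
    loglik = float(np.sum(y * loglam - np.exp(loglam) - gammaln(y + 1.0)))
    return loglam, loglik


def _t_logpdf(x, df: float, scale: float) -> np.ndarray:
    return stats.t.logpdf(x, df=df, loc=0.0, scale=scale)


def log_prior(state: ModelState, hyper: Hyperparameters) -> float:
    """Sum of the log prior densities of every parameter in the state.

    Components: Normal(m0, Sigma0) on m_k, Wishart(Phi, nu) on Q_k,
    Student-t on mu_k and beta, Beta(1, alpha) on sticks, Gamma(a, b) on
    alpha, Normal(0, sigma_eps^2) on eps, Gamma on 1/sigma_eps^2.
    Parameters outside their support give -inf rather than raising.
    """
    if state.alpha <= 0 or state.sigma_eps <= 0:
        return -np.inf
    if np.any(state.V <= 0) or np.any(state.V >= 1):
        return -np.inf
    lp = 0.0
    for k in range(state.K):
        lp += float(
            np.sum(
                stats.norm.logpdf(
                    state.m[k], hyper.m0, np.sqrt(hyper.Sigma0_diag)
                )
            )
        )
        try:
            lp += float(stats.wishart.logpdf(state.Q[k], df=hyper.nu, scale=hyper.Phi))
        except (np.linalg.LinAlgError, ValueError):
            return -np.inf
        lp += float(_t_logpdf(state.mu[k], hyper.mu_df, hyper.mu_scale))
    lp += float(np.sum(_t_logpdf(state.beta, hyper.beta_df, hyper.beta_scale)))
    lp += float(np.sum(stats.beta.logpdf(state.V, 1.0, state.alpha)))
    lp += float(
        stats.gamma.logpdf(state.alpha, hyper.alpha_shape, scale=1.0 / hyper.alpha_rate)
    )
    lp += float(np.sum(stats.norm.logpdf(state.eps, 0.0, state.sigma_eps)))
    tau = state.sigma_eps**-2
    lp += float(
        stats.gamma.logpdf(tau, hyper.tau_eps_shape, scale=1.0 / hyper.tau_eps_rate)
    )
    return lp


def joint_logdensity(
    state: ModelState,
    y: np.ndarray,
    design: SplineDesign,
    offset: OffsetSeries,
    hyper: Hyperparameters,
) -> float:
    """Log of likelihood x prior for a complete state (imputed z in place)."""
    lp = log_prior(state, hyper)
    if not np.isfinite(lp):
        return -np.inf
    _, lly = poisson_logrates(state, design, offset, y)
    z = state.z
    llz = 0.0
    for k in range(state.K):
        idx = np.flatnonzero(state.g == k)
        if len(idx) == 0:
            continue
        params = ClusterParams(m=state.m[k], Q=state.Q[k], mu=state.mu[k])
        for t in idx:
            llz += mvn_logdensity(z[t], params)
    lw = np.log(state.w)
    return lp + lly + llz + float(np.sum(lw[state.g]))
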