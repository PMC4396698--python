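"""MCMC inference for the profile-regression mixture model.

A dependent-slice sampler: each day t carries an auxiliary variable
u_t ~ Uniform(0, xi_{g_t}) with a deterministic decreasing sequence
xi_k = (1 - rho) rho^(k-1), so only the finite set {k : xi_k > u_t} of
components needs instantiating per sweep and no truncation level is ever
imposed.  Conjugate Gibbs updates handle sticks, the DP concentration,
cluster locations/precisions and the extra-Poisson precision; the response
parameters (cluster log relative risks, spline coefficients, day effects)
use random-walk Metropolis-within-Gibbs with proposal scales adapted during
burn-in only.  Missing exposure coordinates are marginalised out of the
allocation step and re-imputed from the allocated cluster's conditional
multivariate normal immediately afterwards, so the conjugate cluster
updates always see complete rows consistent with the current allocation.
Label-switching moves improve mixing over the stick ordering.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import ProfregError, ValidationError
from .model import Hyperparameters, ModelState, stick_breaking
from .preprocess import OffsetSeries, SplineDesign

__all__ = [
    "McmcConfig",
    "McmcChain",
    "SliceSampler",
    "run_mcmc",
    "save_chain",
    "load_chain",
    "sample_prior_state",
    "simulate_data",
]

_MAX_COMPONENTS = 500


@dataclass
class McmcConfig:
    """Sampler settings.  Defaults follow the full analysis protocol
    (70,000 sweeps, 20,000 burn-in, 1-in-10 thinning -> 5000 stored draws);
    `scaled_down()` gives the light configuration used for simulation
    studies (10,000 / 3,000 / 5)."""

    n_iter: int = 70000
    burn_in: int = 20000
    thin: int = 10
    init_clusters: int = 10
    seed: int = 0
    rho: float = 0.75
    prop_scale_mu: float = 0.05
    prop_scale_beta: float = 0.05
    prop_scale_eps: float = 0.2
    prior_only: bool = False
    fix_alpha: float | None = None
    enable_pair_swap: bool = True
    enable_neighbour_swap: bool = True
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValidationError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if not (0.0 < self.rho < 1.0):
            raise ValidationError("rho must lie in (0, 1)")
        if self.init_clusters < 1:
            raise ValidationError("init_clusters must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def scaled_down(cls, **kw) -> "McmcConfig":
        kw.setdefault("n_iter", 10000)
        kw.setdefault("burn_in", 3000)
        kw.setdefault("thin", 5)
        return cls(**kw)


@dataclass
class McmcChain:
    """Thinned post-burn-in draws plus per-sweep bookkeeping."""

    states: list
    allocations: np.ndarray  # (n_stored, T) int32
    n_occupied: np.ndarray  # (n_iter,) occupied clusters per sweep
    acceptance: dict
    config: McmcConfig
    hyper: Hyperparameters
    y: np.ndarray = None
    design: SplineDesign = None
    offset: OffsetSeries = None

    @property
    def n_stored(self) -> int:
        return len(self.states)

    @property
    def T(self) -> int:
        return self.allocations.shape[1]


def _t_logpdf_fast(x, df: float, scale: float) -> np.ndarray:
    """Student-t log-density, location 0; avoids scipy call overhead."""
    c = (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
    )
    return c - 0.5 * (df + 1.0) * np.log1p((np.asarray(x) / scale) ** 2 / df)


_TRIL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _tril_idx(P: int) -> tuple[np.ndarray, np.ndarray]:
    if P not in _TRIL_CACHE:
        _TRIL_CACHE[P] = np.tril_indices(P, -1)
    return _TRIL_CACHE[P]


def _wishart_rvs_batch(
    rng: np.random.Generator, df: float, chol_scale: np.ndarray, n: int
) -> np.ndarray:
    """``n`` Bartlett-decomposition Wishart draws with a shared scale factor."""
    P = chol_scale.shape[0]
    A = np.zeros((n, P, P))
    diag = np.arange(P)
    A[:, diag, diag] = np.sqrt(rng.chisquare(df - diag, size=(n, P)))
    if P > 1:
        i, j = _tril_idx(P)
        A[:, i, j] = rng.standard_normal((n, len(i)))
    LA = chol_scale @ A
    return LA @ np.swapaxes(LA, 1, 2)


def _wishart_rvs(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Single Bartlett-decomposition Wishart draw (scale parameterisation)."""
    return _wishart_rvs_batch(rng, df, np.linalg.cholesky(scale), 1)[0]


class SliceSampler:
    """Runs the dependent-slice MCMC on one prepared dataset.

    Parameters
    ----------
    z : (T, P) array
        Normalised exposures; NaN marks missing cells.
    y : (T,) array
        Daily counts.
    design, offset, hyper, config
        Fixed spline design, Poisson offset, hyperparameters, MCMC settings.
    """

    def __init__(
        self,
        z: np.ndarray,
        y: np.ndarray,
        design: SplineDesign,
        offset: OffsetSeries,
        hyper: Hyperparameters,
        config: McmcConfig,
    ) -> None:
        z = np.asarray(z, dtype=float)
        self.T, self.P = z.shape
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != self.T:
            raise ValidationError("y and z must cover the same days")
        self.design = design
        self.H = design.basis.shape[1]
        self.offset = offset
        self.logE = np.log(offset.E)
        self.hyper = hyper
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.obs_mask = np.isfinite(z)
        self.z = z.copy()
        # initial imputation: prior cluster location (column means)
        for p in range(self.P):
            col = self.z[:, p]
            col[~self.obs_mask[:, p]] = hyper.m0[p]
        self._pattern_groups = self._group_missing_patterns()
        self._Phi_inv = np.linalg.inv(hyper.Phi)
        self._chol_Phi = np.linalg.cholesky(hyper.Phi)
        self._Sigma0_inv = 1.0 / hyper.Sigma0_diag
        self._ydotU = design.basis.T @ self.y
        self._init_state()
        self._acc = {"mu": [0, 0], "beta": [0, 0], "eps": [0, 0], "swap": [0, 0]}
        self._scale_mu = config.prop_scale_mu
        self._scale_beta = np.full(self.H, config.prop_scale_beta)
        self._scale_eps = config.prop_scale_eps
        self._adapt_acc = {"mu": [0, 0], "beta": np.zeros((self.H, 2)), "eps": [0, 0]}

    # ---------------------------------------------------------------- setup

    def _group_missing_patterns(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Rows grouped by missing pattern; complete rows are excluded."""
        incomplete = np.flatnonzero(~self.obs_mask.all(axis=1))
        groups: dict[bytes, list[int]] = {}
        for t in incomplete:
            groups.setdefault(self.obs_mask[t].tobytes(), []).append(t)
        out = []
        for key, rows in groups.items():
            obs = np.frombuffer(key, dtype=bool).copy()
            out.append((np.array(rows), obs))
        return out

    def _init_state(self) -> None:
        cfg, h = self.config, self.hyper
        K = cfg.init_clusters
        self.g = self.rng.integers(0, K, size=self.T)
        self.alpha = (
            cfg.fix_alpha
            if cfg.fix_alpha is not None
            else h.alpha_shape / h.alpha_rate
        )
        self.V = np.clip(self.rng.beta(1.0, self.alpha, size=K), 1e-12, 1 - 1e-12)
        self.w = stick_breaking(self.V)
        var = np.nanvar(np.where(self.obs_mask, self.z, np.nan), axis=0, ddof=1)
        var = np.where(var > 0, var, 1.0)
        self.m = np.empty((K, self.P))
        self.Q = np.empty((K, self.P, self.P))
        for k in range(K):
            idx = self.g == k
            self.m[k] = self.z[idx].mean(axis=0) if idx.any() else h.m0
            self.Q[k] = np.diag(1.0 / var)
        self.mu = np.zeros(K)
        self.beta = np.zeros(self.H)
        self.eps = np.zeros(self.T)
        self.sigma_eps = float(
            1.0 / np.sqrt(h.tau_eps_shape / h.tau_eps_rate)
        )
        self._refresh_chol()
        self._Sigma_cache: dict[int, np.ndarray] = {}

    def _refresh_chol(self) -> None:
        self.cholQ = np.empty_like(self.Q)
        self.logdetQ = np.empty(len(self.Q))
        for k in range(len(self.Q)):
            self._set_Q(k, self.Q[k])

    def _set_Q(self, k: int, Q: np.ndarray) -> None:
        for jitter in (0.0, 1e-8, 1e-6):
            try:
                L = np.linalg.cholesky(Q + jitter * np.eye(self.P))
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise ProfregError(f"cluster {k} precision not positive-definite")
        self.Q[k] = Q + 0.0
        self.cholQ[k] = L
        self.logdetQ[k] = 2.0 * np.sum(np.log(np.diag(L)))
        if hasattr(self, "_Sigma_cache"):
            self._Sigma_cache.pop(k, None)

    def _Sigma(self, k: int) -> np.ndarray:
        S = self._Sigma_cache.get(k)
        if S is None:
            S = np.linalg.inv(self.Q[k])
            self._Sigma_cache[k] = S
        return S

    @property
    def K(self) -> int:
        return len(self.V)

    def _xi(self, K: int) -> np.ndarray:
        rho = self.config.rho
        return (1.0 - rho) * rho ** np.arange(K)

    def _extend_to(self, K_new: int) -> None:
        """Instantiate components up to index K_new-1 from the prior."""
        K_old = self.K
        if K_new <= K_old:
            return
        if K_new > _MAX_COMPONENTS:
            raise ProfregError("slice variables requested too many components")
        n_add = K_new - K_old
        h, rng = self.hyper, self.rng
        V_new = np.clip(rng.beta(1.0, self.alpha, size=n_add), 1e-12, 1 - 1e-12)
        self.V = np.concatenate([self.V, V_new])
        self.w = stick_breaking(self.V)
        m_new = h.m0 + np.sqrt(h.Sigma0_diag) * rng.standard_normal((n_add, self.P))
        self.m = np.vstack([self.m, m_new])
        Q_new = _wishart_rvs_batch(rng, h.nu, self._chol_Phi, n_add)
        self.Q = np.concatenate([self.Q, Q_new])
        mu_new = rng.standard_t(h.mu_df, size=n_add) * h.mu_scale
        self.mu = np.concatenate([self.mu, mu_new])
        chol_new = np.linalg.cholesky(Q_new)
        self.cholQ = np.concatenate([self.cholQ, chol_new])
        diag = np.arange(self.P)
        self.logdetQ = np.concatenate(
            [self.logdetQ, 2.0 * np.sum(np.log(chol_new[:, diag, diag]), axis=1)]
        )

    def _truncate(self, K_new: int) -> None:
        K_new = max(K_new, 1)
        if K_new >= self.K:
            return
        self.V = self.V[:K_new]
        self.w = stick_breaking(self.V)
        self.m = self.m[:K_new]
        self.Q = self.Q[:K_new]
        self.mu = self.mu[:K_new]
        self.cholQ = self.cholQ[:K_new]
        self.logdetQ = self.logdetQ[:K_new]
        self._Sigma_cache = {k: v for k, v in self._Sigma_cache.items() if k < K_new}

    # ---------------------------------------------------- exposure density

    def _exposure_loglik(self, K: int) -> np.ndarray:
        """(T, K) log p(z_t | component k), marginal over missing coords."""
        out = np.empty((self.T, K))
        const = -0.5 * self.P * np.log(2.0 * np.pi)
        for k in range(K):
            diff = self.z - self.m[k]
            quad = np.einsum("ij,ij->i", diff @ self.cholQ[k], diff @ self.cholQ[k])
            out[:, k] = const + 0.5 * self.logdetQ[k] - 0.5 * quad
        for rows, obs in self._pattern_groups:
            n_obs = int(obs.sum())
            zo = self.z[np.ix_(rows, np.flatnonzero(obs))]
            for k in range(K):
                if n_obs == 0:
                    out[rows, k] = 0.0
                    continue
                sub = self._Sigma(k)[np.ix_(obs, obs)]
                L = np.linalg.cholesky(sub)
                diff = zo - self.m[k][obs]
                x = np.linalg.solve(L, diff.T)
                quad = np.sum(x * x, axis=0)
                out[rows, k] = (
                    -0.5 * n_obs * np.log(2.0 * np.pi)
                    - np.sum(np.log(np.diag(L)))
                    - 0.5 * quad
                )
        return out

    # ------------------------------------------------------------- updates

    def update_allocations(self) -> np.ndarray:
        """Slice-conditional reallocation of every day."""
        xi_cur = self._xi(self.K)[self.g]
        u = self.rng.uniform(0.0, xi_cur)
        rho = self.config.rho
        # largest index with xi_k > min(u):  k < log(u/(1-rho)) / log(rho)
        K_need = int(np.ceil(np.log(u.min() / (1.0 - rho)) / np.log(rho)))
        K_need = max(K_need, 1)
        self._extend_to(K_need)
        K = self.K
        xi = self._xi(K)
        with np.errstate(divide="ignore"):  # a zero weight is a valid -inf
            logprob = np.log(self.w)[None, :] - np.log(xi)[None, :]
        logprob = np.broadcast_to(logprob, (self.T, K)).copy()
        if not self.config.prior_only:
            logprob += self._exposure_loglik(K)
            base = self.logE + self.design.basis @ self.beta + self.eps
            loglam = base[:, None] + self.mu[None, :]
            logprob += self.y[:, None] * loglam - np.exp(loglam)
        mask = xi[None, :] > u[:, None]
        if not mask.any(axis=1).all():
            raise ProfregError("empty slice candidate set")
        logprob[~mask] = -np.inf
        gumbel = self.rng.gumbel(size=(self.T, K))
        self.g = np.argmax(logprob + gumbel, axis=1)
        self._truncate(int(self.g.max()) + 1)
        return self.g

    def update_sticks_and_alpha(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Conjugate Beta draws for sticks; Gamma draw for the concentration."""
        n = np.bincount(self.g, minlength=self.K).astype(float)
        tail = np.concatenate([np.cumsum(n[::-1])[::-1][1:], [0.0]])
        self.V = np.clip(
            self.rng.beta(1.0 + n, self.alpha + tail), 1e-12, 1.0 - 1e-12
        )
        self.w = stick_breaking(self.V)
        if self.config.fix_alpha is None:
            shape = self.hyper.alpha_shape + self.K
            rate = self.hyper.alpha_rate - np.sum(np.log1p(-self.V))
            self.alpha = float(self.rng.gamma(shape, 1.0 / rate))
        return self.V, self.w, self.alpha

    def impute_missing(self) -> np.ndarray:
        """Redraw missing coords from the allocated cluster's conditional MVN.

        Uses the precision-form conditional: z_mis | z_obs is normal with
        mean m_mis - Q_mm^{-1} Q_mo (z_obs - m_obs) and precision Q_mm.
        A fully missing row draws from the component's full MVN.
        """
        for rows, obs in self._pattern_groups:
            mis = ~obs
            for k in np.unique(self.g[rows]):
                rk = rows[self.g[rows] == k]
                Q = self.Q[k]
                Qmm = Q[np.ix_(mis, mis)]
                Lmm = np.linalg.cholesky(Qmm)
                if obs.any():
                    Qmo = Q[np.ix_(mis, obs)]
                    diff_o = self.z[np.ix_(rk, np.flatnonzero(obs))] - self.m[k][obs]
                    shift = np.linalg.solve(Qmm, Qmo @ diff_o.T).T
                    mean = self.m[k][mis] - shift
                else:
                    mean = np.broadcast_to(self.m[k][mis], (len(rk), mis.sum()))
                noise = self.rng.standard_normal((mis.sum(), len(rk)))
                draw = mean + np.linalg.solve(Lmm.T, noise).T
                self.z[np.ix_(rk, np.flatnonzero(mis))] = draw
        return self.z

    def update_cluster_locations(self) -> None:
        """Conjugate Normal/Wishart draws; empty components refresh from the prior."""
        h, rng = self.hyper, self.rng
        n_true = np.bincount(self.g, minlength=self.K)
        # likelihood removed: the m/Q conditional is the prior for every k,
        # but mu stays with the Metropolis step so that path is exercised too
        n = np.zeros_like(n_true) if self.config.prior_only else n_true
        empty = np.flatnonzero(n == 0)
        empty_mu = np.flatnonzero(n_true == 0)
        if len(empty):
            self.m[empty] = h.m0 + np.sqrt(h.Sigma0_diag) * rng.standard_normal(
                (len(empty), self.P)
            )
            Q_new = _wishart_rvs_batch(rng, h.nu, self._chol_Phi, len(empty))
            self.Q[empty] = Q_new
            chol_new = np.linalg.cholesky(Q_new)
            self.cholQ[empty] = chol_new
            diag = np.arange(self.P)
            self.logdetQ[empty] = 2.0 * np.sum(np.log(chol_new[:, diag, diag]), axis=1)
            for k in empty:
                self._Sigma_cache.pop(int(k), None)
        if len(empty_mu):
            self.mu[empty_mu] = rng.standard_t(h.mu_df, size=len(empty_mu)) * h.mu_scale
        for k in range(self.K):
            if n[k] == 0:
                continue
            rows = self.z[self.g == k]
            # m_k | rest: Normal with precision Sigma0^-1 + n Q_k
            prec = np.diag(self._Sigma0_inv) + n[k] * self.Q[k]
            Lp = np.linalg.cholesky(prec)
            rhs = self._Sigma0_inv * h.m0 + self.Q[k] @ rows.sum(axis=0)
            mean = np.linalg.solve(prec, rhs)
            self.m[k] = mean + np.linalg.solve(Lp.T, rng.standard_normal(self.P))
            # Q_k | rest: Wishart(nu + n_k, (Phi^-1 + S)^-1)
            centred = rows - self.m[k]
            S = centred.T @ centred
            scale = np.linalg.inv(self._Phi_inv + S)
            scale = 0.5 * (scale + scale.T)
            self._set_Q(k, _wishart_rvs(rng, h.nu + n[k], scale))

    def update_response_params(self) -> None:
        """Metropolis updates for mu_k, beta, eps; conjugate draw for tau_eps."""
        cfg, h, rng = self.config, self.hyper, self.rng
        prior_only = cfg.prior_only
        base = self.logE + self.design.basis @ self.beta + self.eps
        lam = np.exp(base + self.mu[self.g])

        # --- cluster log relative risks (independent across clusters)
        n = np.bincount(self.g, minlength=self.K)
        occ = np.flatnonzero(n > 0)
        if len(occ):
            S_y = np.bincount(self.g, weights=self.y, minlength=self.K)[occ]
            S_lam = np.bincount(self.g, weights=lam, minlength=self.K)[occ]
            delta = self._scale_mu * rng.standard_normal(len(occ))
            dprior = _t_logpdf_fast(self.mu[occ] + delta, h.mu_df, h.mu_scale)
            dprior -= _t_logpdf_fast(self.mu[occ], h.mu_df, h.mu_scale)
            dll = 0.0 if prior_only else S_y * delta - S_lam * np.expm1(delta)
            accept = np.log(rng.uniform(size=len(occ))) < dll + dprior
            self.mu[occ[accept]] += delta[accept]
            self._acc["mu"][0] += int(accept.sum())
            self._acc["mu"][1] += len(occ)
            self._adapt_acc["mu"][0] += int(accept.sum())
            self._adapt_acc["mu"][1] += len(occ)
            if accept.any():
                lam = np.exp(base + self.mu[self.g])

        # --- spline coefficients, one random-walk step per coordinate
        U = self.design.basis
        for hidx in range(self.H):
            d = float(self._scale_beta[hidx] * rng.standard_normal())
            col = U[:, hidx]
            dprior = float(
                _t_logpdf_fast(self.beta[hidx] + d, h.beta_df, h.beta_scale)
                - _t_logpdf_fast(self.beta[hidx], h.beta_df, h.beta_scale)
            )
            if prior_only:
                dll = 0.0
            else:
                factor = np.exp(d * col)
                dll = d * self._ydotU[hidx] - float(np.sum(lam * (factor - 1.0)))
            if np.log(rng.uniform()) < dll + dprior:
                self.beta[hidx] += d
                if not prior_only:
                    lam *= factor
                    base += d * col
                self._acc["beta"][0] += 1
                self._adapt_acc["beta"][hidx, 0] += 1
            self._acc["beta"][1] += 1
            self._adapt_acc["beta"][hidx, 1] += 1

        # --- day effects: conditionally independent, element-wise Metropolis
        d = self._scale_eps * rng.standard_normal(self.T)
        dprior = (self.eps**2 - (self.eps + d) ** 2) / (2.0 * self.sigma_eps**2)
        dll = 0.0 if prior_only else self.y * d - lam * np.expm1(d)
        accept = np.log(rng.uniform(size=self.T)) < dll + dprior
        self.eps[accept] += d[accept]
        self._acc["eps"][0] += int(accept.sum())
        self._acc["eps"][1] += self.T
        self._adapt_acc["eps"][0] += int(accept.sum())
        self._adapt_acc["eps"][1] += self.T

        # --- extra-Poisson precision: conjugate Gamma
        shape = h.tau_eps_shape + 0.5 * self.T
        rate = h.tau_eps_rate + 0.5 * float(np.sum(self.eps**2))
        tau = float(rng.gamma(shape, 1.0 / rate))
        self.sigma_eps = tau**-0.5

    def label_switching_moves(self) -> None:
        """Two Metropolis moves over the stick ordering; posterior-invariant."""
        cfg, rng = self.config, self.rng
        if self.K < 2:
            return
        n = np.bincount(self.g, minlength=self.K).astype(float)
        if cfg.enable_pair_swap:
            j, k = rng.choice(self.K, size=2, replace=False)
            V_new = self.V.copy()
            V_new[[j, k]] = V_new[[k, j]]
            w_new = stick_breaking(V_new)
            n_new = n.copy()
            n_new[[j, k]] = n_new[[k, j]]
            logacc = float(n_new @ np.log(w_new) - n @ np.log(self.w))
            self._acc["swap"][1] += 1
            if np.log(rng.uniform()) < logacc:
                self._acc["swap"][0] += 1
                self.V, self.w, n = V_new, w_new, n_new
                self._swap_components(j, k)
        if cfg.enable_neighbour_swap and self.K >= 2:
            k = int(rng.integers(0, self.K - 1))
            logacc = (n[k + 1] - n[k]) * (np.log(self.w[k]) - np.log(self.w[k + 1]))
            self._acc["swap"][1] += 1
            if np.log(rng.uniform()) < logacc:
                self._acc["swap"][0] += 1
                self._swap_components(k, k + 1)

    def _swap_components(self, j: int, k: int) -> None:
        for arr in (self.m, self.Q, self.cholQ, self.mu, self.logdetQ):
            arr[[j, k]] = arr[[k, j]]
        gj, gk = self.g == j, self.g == k
        self.g[gj], self.g[gk] = k, j
        sj = self._Sigma_cache.pop(j, None)
        sk = self._Sigma_cache.pop(k, None)
        if sk is not None:
            self._Sigma_cache[j] = sk
        if sj is not None:
            self._Sigma_cache[k] = sj

    # ------------------------------------------------------------ plumbing

    def _adapt(self) -> None:
        """Robbins-Monro proposal-scale adaptation (burn-in only)."""

        def tune(scale, acc, total, target=0.44):
            if total == 0:
                return scale
            rate = acc / total
            return float(np.clip(scale * np.exp(0.6 * (rate - target)), 1e-4, 50.0))

        a = self._adapt_acc
        self._scale_mu = tune(self._scale_mu, a["mu"][0], a["mu"][1])
        self._scale_eps = tune(self._scale_eps, a["eps"][0], a["eps"][1])
        for hidx in range(self.H):
            self._scale_beta[hidx] = tune(
                self._scale_beta[hidx], a["beta"][hidx, 0], a["beta"][hidx, 1]
            )
        self._adapt_acc = {"mu": [0, 0], "beta": np.zeros((self.H, 2)), "eps": [0, 0]}

    def get_state(self) -> ModelState:
        return ModelState(
            g=self.g.copy(),
            V=self.V.copy(),
            w=self.w.copy(),
            m=self.m.copy(),
            Q=self.Q.copy(),
            mu=self.mu.copy(),
            beta=self.beta.copy(),
            eps=self.eps.copy(),
            sigma_eps=float(self.sigma_eps),
            alpha=float(self.alpha),
        )

    def set_state(self, state: ModelState) -> None:
        self.g = state.g.copy()
        self.V = state.V.copy()
        self.w = state.w.copy()
        self.m = state.m.copy()
        self.Q = state.Q.copy()
        self.mu = state.mu.copy()
        self.beta = state.beta.copy()
        self.eps = state.eps.copy()
        self.sigma_eps = float(state.sigma_eps)
        self.alpha = float(state.alpha)
        if state.z is not None:
            self.z = state.z.copy()
        self._Sigma_cache = {}
        self._refresh_chol()

    def sweep(self) -> None:
        """One full sweep over all conditional updates."""
        self.update_allocations()
        self.update_sticks_and_alpha()
        self.impute_missing()
        self.update_cluster_locations()
        self.update_response_params()
        self.label_switching_moves()

    def run(self, progress: bool = False) -> McmcChain:
        cfg = self.config
        states: list[ModelState] = []
        allocations = np.empty((cfg.n_stored, self.T), dtype=np.int32)
        n_occupied = np.empty(cfg.n_iter, dtype=np.int32)
        stored = 0
        for it in range(1, cfg.n_iter + 1):
            self.sweep()
            n_occupied[it - 1] = len(np.unique(self.g))
            if it <= cfg.burn_in:
                if it % cfg.adapt_interval == 0:
                    self._adapt()
            elif (it - cfg.burn_in) % cfg.thin == 0 and stored < cfg.n_stored:
                if not (
                    np.all(np.isfinite(self.mu))
                    and np.all(np.isfinite(self.beta))
                    and np.all(np.isfinite(self.eps))
                ):
                    raise ProfregError(
                        f"non-finite state at sweep {it}: {self.get_state()}"
                    )
                states.append(self.get_state())
                allocations[stored] = self.g
                stored += 1
        acceptance = {
            name: (c[0] / c[1] if c[1] else np.nan) for name, c in self._acc.items()
        }
        for name, rate in acceptance.items():
            if name in ("mu", "beta", "eps") and (rate == 0.0 or rate == 1.0):
                import warnings

                warnings.warn(
                    f"acceptance rate for {name} pinned at {rate}", stacklevel=2
                )
        return McmcChain(
            states=states,
            allocations=allocations[:stored],
            n_occupied=n_occupied,
            acceptance=acceptance,
            config=cfg,
            hyper=self.hyper,
            y=self.y,
            design=self.design,
            offset=self.offset,
        )


def run_mcmc(
    z: np.ndarray,
    y: np.ndarray,
    design: SplineDesign,
    offset: OffsetSeries,
    hyper: Hyperparameters,
    config: McmcConfig,
) -> McmcChain:
    """Fit the model: full sweeps of allocation, stick/concentration,
    imputation, cluster-parameter, response-parameter and label-switching
    updates; returns the thinned post-burn-in chain."""
    return SliceSampler(z, y, design, offset, hyper, config).run()


# ----------------------------------------------------------- serialisation

def save_chain(chain: McmcChain, directory) -> None:
    """Write the chain as a columnar store: one file per parameter block
    (states padded with NaN to the largest component count) plus the
    allocations matrix and a JSON meta file."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    S = chain.n_stored
    Kmax = max(s.K for s in chain.states)
    P = chain.states[0].m.shape[1]
    H = chain.states[0].beta.size
    T = chain.T
    blocks = {
        "mu": np.full((S, Kmax), np.nan),
        "V": np.full((S, Kmax), np.nan),
        "w": np.full((S, Kmax), np.nan),
        "m": np.full((S, Kmax, P), np.nan),
        "Q": np.full((S, Kmax, P, P), np.nan),
        "beta": np.empty((S, H)),
        "eps": np.empty((S, T)),
        "sigma_eps": np.empty(S),
        "alpha": np.empty(S),
    }
    K_per_state = np.empty(S, dtype=np.int32)
    for i, st in enumerate(chain.states):
        K = st.K
        K_per_state[i] = K
        blocks["mu"][i, :K] = st.mu
        blocks["V"][i, :K] = st.V
        blocks["w"][i, :K] = st.w
        blocks["m"][i, :K] = st.m
        blocks["Q"][i, :K] = st.Q
        blocks["beta"][i] = st.beta
        blocks["eps"][i] = st.eps
        blocks["sigma_eps"][i] = st.sigma_eps
        blocks["alpha"][i] = st.alpha
    for name, arr in blocks.items():
        np.save(directory / f"{name}.npy", arr)
    np.save(directory / "allocations.npy", chain.allocations)
    np.save(directory / "K_per_state.npy", K_per_state)
    np.save(directory / "n_occupied.npy", chain.n_occupied)
    meta = {"config": asdict(chain.config), "acceptance": chain.acceptance,
            "hyper": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                      for k, v in vars(chain.hyper).items()}}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_chain(directory) -> McmcChain:
    """Read a chain previously written by :func:`save_chain`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    blocks = {
        name: np.load(directory / f"{name}.npy")
        for name in ("mu", "V", "w", "m", "Q", "beta", "eps", "sigma_eps", "alpha")
    }
    allocations = np.load(directory / "allocations.npy")
    K_per_state = np.load(directory / "K_per_state.npy")
    n_occupied = np.load(directory / "n_occupied.npy")
    states = []
    for i in range(len(K_per_state)):
        K = int(K_per_state[i])
        states.append(
            ModelState(
                g=allocations[i].astype(int),
                V=blocks["V"][i, :K],
                w=blocks["w"][i, :K],
                m=blocks["m"][i, :K],
                Q=blocks["Q"][i, :K],
                mu=blocks["mu"][i, :K],
                beta=blocks["beta"][i],
                eps=blocks["eps"][i],
                sigma_eps=float(blocks["sigma_eps"][i]),
                alpha=float(blocks["alpha"][i]),
            )
        )
    hyper = Hyperparameters(
        **{
            k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in meta["hyper"].items()
        }
    )
    return McmcChain(
        states=states,
        allocations=allocations,
        n_occupied=n_occupied,
        acceptance=meta["acceptance"],
        config=McmcConfig(**meta["config"]),
        hyper=hyper,
    )


# ------------------------------------------------------------------ priors

def sample_prior_state(
    hyper: Hyperparameters,
    T: int,
    H: int,
    rng: np.random.Generator,
) -> ModelState:
    """Draw a complete state from the prior (sticks extended until every
    day's allocation lands on an instantiated component)."""
    P = hyper.P
    alpha = float(rng.gamma(hyper.alpha_shape, 1.0 / hyper.alpha_rate))
    V = []
    w = []
    remaining = 1.0
    uni = rng.uniform(size=T)
    g = np.full(T, -1)
    cum = 0.0
    while (g < 0).any() or len(V) < 1:
        v = float(np.clip(rng.beta(1.0, alpha), 1e-12, 1 - 1e-12))
        wk = v * remaining
        remaining *= 1.0 - v
        newly = (g < 0) & (uni < cum + wk)
        g[newly] = len(V)
        cum += wk
        V.append(v)
        w.append(wk)
        if len(V) > _MAX_COMPONENTS:
            g[g < 0] = 0
            break
    K = len(V)
    m = hyper.m0 + np.sqrt(hyper.Sigma0_diag) * rng.standard_normal((K, P))
    Q = np.stack([_wishart_rvs(rng, hyper.nu, hyper.Phi) for _ in range(K)])
    mu = rng.standard_t(hyper.mu_df, size=K) * hyper.mu_scale
    beta = rng.standard_t(hyper.beta_df, size=H) * hyper.beta_scale
    tau = rng.gamma(hyper.tau_eps_shape, 1.0 / hyper.tau_eps_rate)
    sigma_eps = float(tau**-0.5)
    eps = rng.normal(0.0, sigma_eps, size=T)
    return ModelState(
        g=g,
        V=np.array(V),
        w=np.array(w),
        m=m,
        Q=Q,
        mu=np.array(mu),
        beta=beta,
        eps=eps,
        sigma_eps=sigma_eps,
        alpha=alpha,
    )


def simulate_data(
    state: ModelState,
    design: SplineDesign,
    offset: OffsetSeries,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (z, y) from the model given a complete state (for
    successive-conditional correctness checks)."""
    T = len(state.g)
    P = state.m.shape[1]
    z = np.empty((T, P))
    for k in np.unique(state.g):
        idx = state.g == k
        Sigma = np.linalg.inv(state.Q[k])
        L = np.linalg.cholesky(Sigma)
        z[idx] = state.m[k] + rng.standard_normal((int(idx.sum()), P)) @ L.T
    loglam = (
        np.log(offset.E)
        + state.mu[state.g]
        + design.basis @ state.beta
        + state.eps
    )
    y = rng.poisson(np.exp(loglam))
    return z, y
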