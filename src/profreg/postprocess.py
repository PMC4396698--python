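"""Posterior post-processing: representative partition and summaries.

The chain's allocation draws are condensed into a posterior similarity
matrix S (S_ij = fraction of retained sweeps in which days i and j share a
cluster).  Partitioning around medoids on the dissimilarity 1 - S gives a
representative partition, with the number of clusters chosen by maximum
average silhouette width.  Cluster characteristics are then recovered by
model averaging: at every sweep, each representative cluster's parameters
are the sweep parameters averaged over its days, and those per-sweep values
are summarised across the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import arviz as az
from sklearn.metrics import silhouette_score

from .errors import ValidationError
from .preprocess import NormalizedExposureMatrix, denormalize
from .sampler import McmcChain

__all__ = [
    "PosteriorSimilarityMatrix",
    "RepresentativePartition",
    "ClusterSummary",
    "similarity_matrix",
    "pam",
    "representative_partition",
    "cluster_summaries",
    "membership_heatmap_data",
    "diagnostics",
]


@dataclass
class PosteriorSimilarityMatrix:
    """T x T co-clustering probabilities (symmetric, unit diagonal)."""

    S: np.ndarray


@dataclass
class RepresentativePartition:
    """Consensus clustering of the days.

    ``labels`` are contiguous from 1, ordered by descending cluster size;
    ``medoids`` are day indices (0-based) and members of their clusters.
    """

    labels: np.ndarray
    medoids: np.ndarray
    silhouette_by_k: dict[int, float]

    @property
    def k(self) -> int:
        return len(self.medoids)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


@dataclass
class ClusterSummary:
    """Model-averaged cluster characteristics with 95% credible intervals."""

    exposure_mean: np.ndarray  # (k, P) normalised scale
    exposure_ci: np.ndarray  # (k, P, 2)
    exposure_mean_original: np.ndarray | None
    exposure_ci_original: np.ndarray | None
    rr_mean: np.ndarray  # (k,) posterior mean of exp(mu)
    rr_ci: np.ndarray  # (k, 2)
    sizes: np.ndarray
    membership_probabilities: np.ndarray  # (T, k)

    def to_frame(self, metric_names=None) -> pd.DataFrame:
        k, P = self.exposure_mean.shape
        names = metric_names or [f"z_{p + 1}" for p in range(P)]
        exp_mean = (
            self.exposure_mean_original
            if self.exposure_mean_original is not None
            else self.exposure_mean
        )
        exp_ci = (
            self.exposure_ci_original
            if self.exposure_ci_original is not None
            else self.exposure_ci
        )
        rows = []
        for c in range(k):
            row = {"cluster": c + 1, "days": int(self.sizes[c])}
            row["RR"] = self.rr_mean[c]
            row["RR_lo"], row["RR_hi"] = self.rr_ci[c]
            for p, name in enumerate(names):
                row[name] = exp_mean[c, p]
                row[f"{name}_lo"], row[f"{name}_hi"] = exp_ci[c, p]
            rows.append(row)
        return pd.DataFrame(rows)


def similarity_matrix(chain: McmcChain | np.ndarray) -> PosteriorSimilarityMatrix:
    """Average the per-sweep co-clustering indicators over retained sweeps."""
    alloc = chain.allocations if isinstance(chain, McmcChain) else np.asarray(chain)
    if alloc.ndim != 2 or alloc.shape[0] == 0:
        raise ValidationError("need a non-empty (n_sweeps, T) allocation array")
    n, T = alloc.shape
    S = np.zeros((T, T))
    for s in range(n):
        g = alloc[s]
        S += g[:, None] == g[None, :]
    S /= n
    return PosteriorSimilarityMatrix(S=S)


def _pam_build(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD phase: medoids minimising total dissimilarity."""
    T = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        d_near = D[:, medoids].min(axis=1)
        # gain of adding candidate c: sum of max(d_near - D[:, c], 0)
        gains = np.clip(d_near[:, None] - D, 0.0, None).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return np.array(sorted(medoids))


def pam(D: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a precomputed dissimilarity matrix.

    BUILD then SWAP until no single medoid/non-medoid exchange lowers the
    total dissimilarity.  Deterministic; ties resolved toward the lowest
    index.  Returns (labels 0..k-1, medoid indices).
    """
    D = np.asarray(D, dtype=float)
    T = D.shape[0]
    if k >= T:
        raise ValidationError("number of clusters must be smaller than T")
    if k < 1:
        raise ValidationError("need at least one cluster")
    medoids = _pam_build(D, k)
    for _ in range(max_iter):
        dist_to_med = D[:, medoids]  # (T, k)
        order = np.argsort(dist_to_med, axis=1, kind="stable")
        nearest = order[:, 0]
        d_near = dist_to_med[np.arange(T), nearest]
        cost = d_near.sum()
        if k > 1:
            d_second = dist_to_med[np.arange(T), order[:, 1]]
        else:
            d_second = np.full(T, np.inf)
        best = (0.0, None, None)
        for mi in range(k):
            # cost after replacing medoid mi by candidate c, for every c
            backup = np.where(nearest == mi, d_second, d_near)
            new_cost = np.minimum(backup[:, None], D).sum(axis=0)
            new_cost[medoids] = np.inf
            c = int(np.argmin(new_cost))
            delta = new_cost[c] - cost
            if delta < best[0] - 1e-12:
                best = (delta, mi, c)
        if best[1] is None:
            break
        medoids = medoids.copy()
        medoids[best[1]] = best[2]
        medoids = np.sort(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    labels[medoids] = np.arange(k)  # a medoid always belongs to its own cluster
    return labels, medoids


def representative_partition(
    S: PosteriorSimilarityMatrix | np.ndarray, k_range=range(2, 9)
) -> RepresentativePartition:
    """PAM on 1 - S for each k; keep the k with the best average silhouette.

    Ties break toward the smallest k.  Returned labels are contiguous from 1
    and sorted by descending cluster size.
    """
    Smat = S.S if isinstance(S, PosteriorSimilarityMatrix) else np.asarray(S)
    T = Smat.shape[0]
    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ValidationError("k_range must be non-empty")
    if max(k_range) >= T:
        raise ValidationError("k_range values must be smaller than T")
    D = 1.0 - Smat
    np.fill_diagonal(D, 0.0)
    results = {}
    sil = {}
    for k in sorted(k_range):
        labels, medoids = pam(D, k)
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(D, labels, metric="precomputed"))
        results[k] = (labels, medoids)
    best_k = max(sorted(sil), key=lambda k: sil[k])  # ties -> smallest k
    labels, medoids = results[best_k]
    # relabel by descending size, 1-based
    sizes = np.bincount(labels, minlength=best_k)
    order = np.argsort(-sizes, kind="stable")
    rank = np.empty(best_k, dtype=int)
    rank[order] = np.arange(best_k)
    return RepresentativePartition(
        labels=rank[labels] + 1,
        medoids=medoids[order],
        silhouette_by_k=sil,
    )


def membership_heatmap_data(
    chain: McmcChain, partition: RepresentativePartition
) -> np.ndarray:
    """(T, k) posterior membership probabilities.

    Row t counts the fraction of retained sweeps in which day t shares a
    sweep-cluster with each representative medoid, normalised to sum to 1
    (a day can co-cluster with several medoids in one sweep).
    """
    alloc = chain.allocations
    med = partition.medoids
    co = np.zeros((alloc.shape[1], len(med)))
    for s in range(alloc.shape[0]):
        g = alloc[s]
        co += g[:, None] == g[med][None, :]
    rowsum = co.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return co / rowsum


def cluster_summaries(
    chain: McmcChain,
    partition: RepresentativePartition,
    normalization: NormalizedExposureMatrix | None = None,
    ci_level: float = 0.95,
) -> ClusterSummary:
    """Model-averaged cluster profiles and relative risks.

    For each sweep and representative cluster, the sweep's parameters
    (component locations m, relative risks exp(mu)) are averaged over the
    sweep-components of the cluster's days; the per-sweep values are then
    summarised by their mean and central credible interval.  Exposure
    profiles are also back-transformed to original units when the training
    normalisation constants are supplied.
    """
    T = chain.T
    if len(partition.labels) != T:
        raise ValidationError("partition and chain must cover the same days")
    k = partition.k
    n_sweeps = chain.n_stored
    P = chain.states[0].m.shape[1]
    day_sets = [np.flatnonzero(partition.labels == c + 1) for c in range(k)]
    if any(len(d) == 0 for d in day_sets):
        raise ValidationError("empty representative cluster")
    exp_draws = np.empty((n_sweeps, k, P))
    rr_draws = np.empty((n_sweeps, k))
    for s, state in enumerate(chain.states):
        m_per_day = state.m[state.g]  # (T, P)
        rr_per_day = np.exp(state.mu[state.g])
        # calibrate to risk against the period-average rate: the day-averaged
        # confounder factor mean_t exp(f_t + sigma^2/2) is a level common to
        # every cluster and would otherwise bias exp(mu) off 1 under strong
        # seasonality (Jensen gap of the mean-zero spline)
        if chain.design is not None:
            level = float(
                np.mean(
                    np.exp(
                        chain.design.basis @ state.beta + 0.5 * state.sigma_eps**2
                    )
                )
            )
        else:
            level = 1.0
        for c, days in enumerate(day_sets):
            exp_draws[s, c] = m_per_day[days].mean(axis=0)
            rr_draws[s, c] = level * rr_per_day[days].mean()
    lo, hi = 50.0 * (1.0 - ci_level), 50.0 * (1.0 + ci_level)
    exp_ci = np.stack(
        [
            np.percentile(exp_draws, lo, axis=0),
            np.percentile(exp_draws, hi, axis=0),
        ],
        axis=-1,
    )
    rr_ci = np.stack(
        [np.percentile(rr_draws, lo, axis=0), np.percentile(rr_draws, hi, axis=0)],
        axis=-1,
    )
    if normalization is not None:
        exp_mean_orig = denormalize(exp_draws.mean(axis=0), normalization)
        exp_ci_orig = np.stack(
            [
                denormalize(exp_ci[..., 0], normalization),
                denormalize(exp_ci[..., 1], normalization),
            ],
            axis=-1,
        )
    else:
        exp_mean_orig = exp_ci_orig = None
    return ClusterSummary(
        exposure_mean=exp_draws.mean(axis=0),
        exposure_ci=exp_ci,
        exposure_mean_original=exp_mean_orig,
        exposure_ci_original=exp_ci_orig,
        rr_mean=rr_draws.mean(axis=0),
        rr_ci=rr_ci,
        sizes=np.array([len(d) for d in day_sets]),
        membership_probabilities=membership_heatmap_data(chain, partition),
    )


def diagnostics(chain: McmcChain, max_lag: int = 50) -> pd.DataFrame:
    """Trace summaries, lag-1 autocorrelation and effective sample size for
    the main global parameters (concentration, extra-Poisson SD, number of
    occupied clusters, first spline coefficient)."""
    if chain.n_stored == 0:
        raise ValidationError("empty chain")
    series = {
        "alpha": np.array([s.alpha for s in chain.states]),
        "sigma_eps": np.array([s.sigma_eps for s in chain.states]),
        "n_occupied": np.array(
            [len(np.unique(s.g)) for s in chain.states], dtype=float
        ),
    }
    if chain.states[0].beta.size:
        series["beta_1"] = np.array([s.beta[0] for s in chain.states])
    rows = []
    for name, x in series.items():
        var = x.var()
        if var == 0.0:
            rows.append(
                {
                    "parameter": name,
                    "mean": x.mean(),
                    "sd": 0.0,
                    "acf_lag1": np.nan,
                    "ess": np.nan,
                    "constant": True,
                }
            )
            continue
        xc = x - x.mean()
        acf1 = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc))
        ess = float(az.ess(az.convert_to_dataset(x[None, :])).x.values)
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "sd": float(x.std()),
                "acf_lag1": acf1,
                "ess": ess,
                "constant": False,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
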