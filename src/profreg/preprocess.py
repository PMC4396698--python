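"""Exposure normalisation, lag alignment, spline confounder bases, offset.

Exposures are put on a comparable robust scale with the modified z-score
(value minus column median, divided by the median absolute deviation).
Confounders (calendar time, temperature) enter the health model through
natural cubic spline bases built once, outside the sampler, and passed in as
fixed data.  The Poisson offset is the period-average daily count, so the
cluster effects are log relative risks against the period average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tsa.stattools import pacf

from .errors import DegenerateColumnError, ValidationError

__all__ = [
    "NormalizedExposureMatrix",
    "SplineDesign",
    "OffsetSeries",
    "modified_zscore",
    "normalize_exposures",
    "denormalize",
    "lag_exposures",
    "natural_spline_knots",
    "natural_spline_eval",
    "natural_spline_basis",
    "build_confounder_design",
    "select_df",
    "compute_offset",
    "bs_from_black_carbon",
]

# Conversion from aethalometer black carbon to a black-smoke-equivalent scale.
BLACK_CARBON_TO_BS = 0.27


@dataclass
class NormalizedExposureMatrix:
    """Robust-normalised exposures plus the constants to undo the transform."""

    z: np.ndarray  # (T, P); NaN preserved
    column_medians: np.ndarray  # (P,) original units
    column_mads: np.ndarray  # (P,) original units, all > 0


@dataclass
class SplineDesign:
    """Fixed confounder design: concatenated natural-cubic-spline bases.

    Each variable's block is built from the truncated-power natural basis on
    a [0, 1]-rescaled axis, then mean-centred and orthonormalised by QR (a
    pure change of coordinates within the same spline space, kept for
    numerical conditioning and sampler mixing).  Centring means the design
    spans only mean-zero fluctuations, so the level of the log-rate is
    carried entirely by the offset and the cluster effects.  The knots and
    the per-block linear transform are stored so a block can be
    re-evaluated on new data (scenario temperature).
    """

    basis: np.ndarray  # (T, H), centred
    df_per_variable: dict[str, int]
    knot_locations: dict[str, np.ndarray]
    blocks: dict[str, slice] = field(default_factory=dict)
    block_info: dict[str, dict] = field(default_factory=dict)

    @property
    def H(self) -> int:
        return self.basis.shape[1]

    def evaluate_block(self, name: str, values: np.ndarray) -> np.ndarray:
        """Evaluate one variable's (centred) basis block at new values."""
        info = self.block_info[name]
        raw = _scaled_natural_basis(np.asarray(values, float), info["knots"])
        return (raw - info["raw_means"]) @ info["transform"]


@dataclass
class OffsetSeries:
    """Constant Poisson offset: the period-average daily count."""

    E: np.ndarray  # (T,) positive


def modified_zscore(column: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Robust normalisation z = (x - median) / median(|x - median|).

    Statistics use observed (non-NaN) entries only; NaNs stay NaN.
    Raises :class:`DegenerateColumnError` when the MAD is zero — such a
    column must be dropped or fixed, never silently divided.
    """
    x = np.asarray(column, dtype=float)
    obs = x[np.isfinite(x)]
    if len(np.unique(obs)) < 2:
        raise DegenerateColumnError("column needs at least 2 distinct observed values")
    med = float(np.median(obs))
    mad = float(np.median(np.abs(obs - med)))
    if mad == 0.0:
        raise DegenerateColumnError("column MAD is zero; modified z-score undefined")
    return (x - med) / mad, (med, mad)


def normalize_exposures(matrix: np.ndarray) -> NormalizedExposureMatrix:
    """Apply the modified z-score column-wise."""
    X = np.asarray(matrix, dtype=float)
    z = np.empty_like(X)
    meds = np.empty(X.shape[1])
    mads = np.empty(X.shape[1])
    for p in range(X.shape[1]):
        z[:, p], (meds[p], mads[p]) = modified_zscore(X[:, p])
    return NormalizedExposureMatrix(z=z, column_medians=meds, column_mads=mads)


def denormalize(z: np.ndarray, norm: NormalizedExposureMatrix) -> np.ndarray:
    """Map normalised values back to original units (z * mad + median)."""
    return np.asarray(z) * norm.column_mads + norm.column_medians


def lag_exposures(
    dates: pd.DatetimeIndex, exposures: np.ndarray, lag: int = 1
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Align exposures so day t's outcome is paired with day t-lag exposures.

    Alignment is by calendar date, not row position: if the date ``lag`` days
    before an outcome day is absent from the record, that outcome day is
    dropped.  Returns (kept outcome dates, matching lagged exposure rows).
    """
    if lag < 0:
        raise ValidationError("lag must be non-negative")
    if lag >= len(dates):
        raise ValidationError("lag must be smaller than the series length")
    if lag == 0:
        return dates, np.asarray(exposures)
    wanted = dates - pd.Timedelta(days=lag)
    pos = pd.Index(dates).get_indexer(wanted)
    keep = pos >= 0
    return dates[keep], np.asarray(exposures)[pos[keep]]


def natural_spline_knots(values: np.ndarray, df: int) -> np.ndarray:
    """Knot vector for a ``df``-column natural cubic spline basis.

    Boundary knots at the data extremes, df-1 interior knots at equally
    spaced quantiles of the observed values.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("spline values must be finite")
    if df < 1:
        raise ValidationError("df must be >= 1")
    if df > len(np.unique(v)):
        raise ValidationError("df exceeds the number of distinct values")
    probs = np.linspace(0.0, 1.0, df + 1)
    knots = np.quantile(v, probs)
    if len(np.unique(knots)) != len(knots):
        raise ValidationError("duplicate knots; reduce df for this variable")
    return knots


def natural_spline_eval(values: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the natural cubic spline basis defined by ``knots``.

    Truncated-power construction: with K knots the basis (intercept
    excluded) is N_1(x) = x and N_{1+j}(x) = d_j(x) - d_{K-1}(x) for
    j = 1..K-2, where d_j(x) = [(x-k_j)_+^3 - (x-k_K)_+^3] / (k_K - k_j).
    The span is every natural cubic spline on the knots, linear beyond the
    boundary knots, modulo constants.
    """
    x = np.asarray(values, dtype=float)
    k = np.asarray(knots, dtype=float)
    K = len(k)
    if K == 2:
        return x[:, None].copy()

    def d(j: int) -> np.ndarray:
        num = np.clip(x - k[j], 0.0, None) ** 3 - np.clip(x - k[K - 1], 0.0, None) ** 3
        return num / (k[K - 1] - k[j])

    cols = [x]
    d_last = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - d_last)
    return np.column_stack(cols)


def natural_spline_basis(values: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns, knots at quantiles."""
    return natural_spline_eval(values, natural_spline_knots(values, df))


def _scaled_natural_basis(values: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Raw natural basis on the [0, 1]-rescaled axis (numerical range control)."""
    lo, hi = knots[0], knots[-1]
    span = hi - lo
    return natural_spline_eval((values - lo) / span, (knots - lo) / span)


def build_confounder_design(
    time_index: np.ndarray,
    temperature: np.ndarray,
    time_df: int,
    temp_df: int = 3,
) -> SplineDesign:
    """Concatenated centred, per-block-orthonormalised spline bases."""
    variables = {
        "time": (np.asarray(time_index, dtype=float), time_df),
        "temperature": (np.asarray(temperature, dtype=float), temp_df),
    }
    pieces, blocks, info, knots_out = [], {}, {}, {}
    start = 0
    for name, (x, df) in variables.items():
        knots = natural_spline_knots(x, df)
        raw = _scaled_natural_basis(x, knots)
        raw_means = raw.mean(axis=0)
        _, R = np.linalg.qr(raw - raw_means)
        signs = np.sign(np.diag(R))
        signs[signs == 0] = 1.0
        R = R * signs[:, None]  # positive-diagonal convention: unique QR
        # columns rescaled to ~unit variance; transform maps raw -> final
        transform = np.linalg.solve(R, np.eye(df)) * np.sqrt(len(x))
        pieces.append((raw - raw_means) @ transform)
        blocks[name] = slice(start, start + df)
        info[name] = {"knots": knots, "raw_means": raw_means, "transform": transform}
        knots_out[name] = knots
        start += df
    return SplineDesign(
        basis=np.column_stack(pieces),
        df_per_variable={name: df for name, (_, df) in variables.items()},
        knot_locations=knots_out,
        blocks=blocks,
        block_info=info,
    )


def select_df(
    y: np.ndarray,
    time_index: np.ndarray,
    temperature: np.ndarray,
    offset: "OffsetSeries",
    time_df_grid,
    temp_df_grid=(3,),
    pacf_lags: int = 30,
) -> dict:
    """Choose spline degrees of freedom by AIC over a joint grid.

    Fits a log-linear Poisson regression of the counts on intercept plus the
    combined spline design with offset for every (time_df, temp_df) pair,
    records AIC and BIC, picks the AIC minimiser (ties -> fewer total df),
    and reports the partial autocorrelation of the deviance residuals at the
    chosen setting.  Non-convergent fits are flagged and excluded.
    """
    if len(time_df_grid) == 0 or len(temp_df_grid) == 0:
        raise ValidationError("df grids must be non-empty")
    y = np.asarray(y, dtype=float)
    log_offset = np.log(offset.E)
    rows = []
    fits = {}
    for tdf in time_df_grid:
        for qdf in temp_df_grid:
            design = build_confounder_design(time_index, temperature, tdf, qdf)
            X = sm.add_constant(design.basis)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.GLM(y, X, family=sm.families.Poisson(), offset=log_offset).fit()
                converged = bool(res.converged) and np.all(np.isfinite(res.params))
            except Exception:
                res, converged = None, False
            rows.append(
                {
                    "time_df": tdf,
                    "temp_df": qdf,
                    "aic": res.aic if converged else np.nan,
                    "bic": res.bic_llf if converged else np.nan,
                    "converged": converged,
                }
            )
            if converged:
                fits[(tdf, qdf)] = res
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise ValidationError("no candidate df setting converged")
    # minimum AIC; ties broken toward fewer total df, then smaller time df
    ok = ok.assign(total=ok["time_df"] + ok["temp_df"])
    ok = ok.sort_values(["aic", "total", "time_df"], kind="stable")
    best = ok.iloc[0]
    chosen = (int(best["time_df"]), int(best["temp_df"]))
    resid = fits[chosen].resid_deviance
    lags = min(pacf_lags, len(y) // 2 - 2)
    resid_pacf = pacf(resid, nlags=lags)
    return {
        "time_df": chosen[0],
        "temp_df": chosen[1],
        "table": table,
        "residual_pacf": resid_pacf,
    }


def compute_offset(y: np.ndarray) -> OffsetSeries:
    """Constant offset E_t = mean daily count over the whole period."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValidationError("cannot compute an offset from an empty series")
    mean = float(y.mean())
    if mean <= 0.0:
        raise DegenerateColumnError("all-zero outcome: offset 0 leaves the model undefined")
    return OffsetSeries(E=np.full(len(y), mean))


def bs_from_black_carbon(black_carbon: np.ndarray) -> np.ndarray:
    """Black-smoke equivalent from aethalometer black carbon (factor 0.27)."""
    return np.asarray(black_carbon, dtype=float) * BLACK_CARBON_TO_BS
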