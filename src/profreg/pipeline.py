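"""End-to-end orchestration: I/O, configuration, staged runs, sensitivity.

A run reads a daily CSV (date, y, z_1..z_P, temperature), normalises and
lags the exposures, builds the spline confounder design and offset, fits
the mixture by MCMC, post-processes the chain into a representative
partition with summaries, optionally compares two exposure scenarios, and
writes every stage product plus a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .errors import SchemaError, ValidationError
from .model import empirical_hyperparams
from .postprocess import (
    cluster_summaries,
    diagnostics,
    representative_partition,
    similarity_matrix,
)
from .predict import ExposureScenario, percent_change, predict_scenario
from .preprocess import (
    build_confounder_design,
    compute_offset,
    lag_exposures,
    normalize_exposures,
)
from .sampler import McmcConfig, run_mcmc, save_chain

__all__ = [
    "RunConfig",
    "read_timeseries_csv",
    "write_results",
    "run_full_analysis",
    "run_sensitivity",
]

logger = logging.getLogger("profreg")

SCHEMA_VERSION = 1
WELL_POPULATED_THRESHOLD = 9  # a cluster is well populated above this many days


@dataclass
class RunConfig:
    """Validated configuration of one full analysis run."""

    input_csv: str
    output_dir: str
    schema_version: int = SCHEMA_VERSION
    lag: int = 1
    time_df_per_year: int = 8
    temp_df: int = 3
    alpha_shape: float = 2.0
    alpha_rate: float = 1.0
    phi_mode: str = "diagonal"
    k_range: list = field(default_factory=lambda: list(range(2, 9)))
    scenario_a: str | None = None
    scenario_b: str | None = None
    seed: int = 0
    mcmc: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if data.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ValidationError("unsupported config schema_version")
        missing = {"input_csv", "output_dir"} - set(data)
        if missing:
            raise ValidationError(f"missing config keys: {sorted(missing)}")
        mcmc_allowed = set(McmcConfig.__dataclass_fields__)
        mcmc_unknown = set(data.get("mcmc", {})) - mcmc_allowed
        if mcmc_unknown:
            raise ValidationError(f"unknown mcmc config keys: {sorted(mcmc_unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError("config file must hold a key-value mapping")
        return cls.from_dict(data)

    def validate_paths(self) -> None:
        for attr in ("input_csv", "scenario_a", "scenario_b"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise ValidationError(f"{attr} path does not exist: {value}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_timeseries_csv(path, require_outcome: bool = True) -> dict:
    """Read a daily time-series CSV into arrays.

    Expected columns: date (ISO-8601), y, z_1..z_P, temperature; empty cells
    and "NA" both parse as missing (exposures only).  Duplicate or
    unparseable dates raise :class:`SchemaError` naming the offending rows;
    calendar gaps are detected and reported in the returned dict.  Scenario
    files (``require_outcome=False``) may omit the y column.
    """
    df = pd.read_csv(
        path, na_values=["NA"], keep_default_na=True, float_precision="round_trip"
    )
    required = {"date", "temperature"} | ({"y"} if require_outcome else set())
    if not required <= set(df.columns):
        raise SchemaError(f"missing required columns: {sorted(required - set(df.columns))}")
    z_cols = [c for c in df.columns if c.startswith("z_")]
    if not z_cols:
        raise SchemaError("no exposure columns (z_1..z_P) found")
    z_cols = sorted(z_cols, key=lambda c: int(c.split("_")[1]))
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    bad = df.loc[dates.isna(), "date"]
    if len(bad):
        raise SchemaError(f"unparseable dates in rows: {bad.to_dict()}")
    dup = dates[dates.duplicated()]
    if len(dup):
        raise SchemaError(
            f"duplicate dates: {sorted(d.strftime('%Y-%m-%d') for d in dup.unique())}"
        )
    if "y" in df.columns and df["y"].isna().any():
        raise SchemaError("missing values are only allowed in exposure columns")
    if df["temperature"].isna().any():
        raise SchemaError("missing values are only allowed in exposure columns")
    dates = pd.DatetimeIndex(dates)
    gaps = []
    if len(dates) > 1:
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        gaps = [
            str(dates[i].date()) for i in np.flatnonzero(deltas > 1)
        ]
    return {
        "dates": dates,
        "y": df["y"].to_numpy() if "y" in df.columns else None,
        "exposures": df[z_cols].to_numpy(dtype=float),
        "temperature": df["temperature"].to_numpy(dtype=float),
        "exposure_names": z_cols,
        "gaps_after": gaps,
    }


def write_timeseries_csv(path, dates, y, exposures, temperature) -> None:
    df = pd.DataFrame({"date": pd.DatetimeIndex(dates).strftime("%Y-%m-%d"), "y": y})
    for p in range(exposures.shape[1]):
        df[f"z_{p + 1}"] = exposures[:, p]
    df["temperature"] = temperature
    df.to_csv(path, index=False)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Independent per-stage integer seeds fanned out from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage in order and persist the results bundle."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
    }
    seeds = _stage_seeds(config.seed)
    stage_times = {}
    current_stage = "load"
    try:
        t0 = time.perf_counter()
        data = read_timeseries_csv(config.input_csv)
        stage_times["load"] = time.perf_counter() - t0

        current_stage = "preprocess"
        t0 = time.perf_counter()
        lag_dates, lagged_z = lag_exposures(
            data["dates"], data["exposures"], config.lag
        )
        keep = pd.Index(data["dates"]).get_indexer(lag_dates)
        y = data["y"][keep]
        temperature = data["temperature"][keep]
        norm = normalize_exposures(lagged_z)
        offset = compute_offset(y)
        n_years = max(len(y) / 365.25, 1.0)
        design = build_confounder_design(
            np.arange(1, len(y) + 1),
            temperature,
            time_df=max(int(round(config.time_df_per_year * n_years)), 2),
            temp_df=config.temp_df,
        )
        hyper = empirical_hyperparams(
            norm,
            phi_mode=config.phi_mode,
            alpha_shape=config.alpha_shape,
            alpha_rate=config.alpha_rate,
        )
        stage_times["preprocess"] = time.perf_counter() - t0

        current_stage = "fit"
        t0 = time.perf_counter()
        mcmc_cfg = McmcConfig(**{"seed": seeds[1], **config.mcmc})
        chain = run_mcmc(norm.z, y, design, offset, hyper, mcmc_cfg)
        save_chain(chain, outdir / "chain")
        stage_times["fit"] = time.perf_counter() - t0

        current_stage = "postprocess"
        t0 = time.perf_counter()
        S = similarity_matrix(chain)
        partition = representative_partition(S, config.k_range)
        summary = cluster_summaries(chain, partition, norm)
        diag = diagnostics(chain)
        stage_times["postprocess"] = time.perf_counter() - t0

        prediction = None
        if config.scenario_a and config.scenario_b:
            current_stage = "predict"
            t0 = time.perf_counter()
            preds = []
            for i, path in enumerate((config.scenario_a, config.scenario_b)):
                sc_data = read_timeseries_csv(path, require_outcome=False)
                scenario = ExposureScenario.from_raw(
                    sc_data["dates"],
                    sc_data["exposures"],
                    norm,
                    temperature=sc_data["temperature"],
                )
                preds.append(
                    predict_scenario(chain, scenario, offset, design, seed=seeds[2 + i])
                )
            prediction = percent_change(preds[0], preds[1])
            stage_times["predict"] = time.perf_counter() - t0

        current_stage = "write"
        bundle = {
            "data": data,
            "aligned_dates": lag_dates,
            "normalization": norm,
            "offset": offset,
            "design": design,
            "hyper": hyper,
            "chain": chain,
            "similarity": S,
            "partition": partition,
            "summary": summary,
            "diagnostics": diag,
            "prediction": prediction,
        }
        manifest["stages"] = {k: round(v, 3) for k, v in stage_times.items()}
        manifest["acceptance_rates"] = chain.acceptance
        manifest["n_representative_clusters"] = int(partition.k)
        write_results(bundle, outdir, manifest, data.get("exposure_names"))
        return bundle
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise


def write_results(bundle: dict, outdir, manifest: dict, metric_names=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "similarity_matrix.csv", bundle["similarity"].S, delimiter=",")
    partition = bundle["partition"]
    pd.DataFrame(
        {
            "date": bundle["aligned_dates"].strftime("%Y-%m-%d")
            if bundle.get("aligned_dates") is not None
            else np.arange(len(partition.labels)),
            "cluster": partition.labels,
        }
    ).to_csv(outdir / "partition.csv", index=False)
    bundle["summary"].to_frame(metric_names).to_csv(
        outdir / "cluster_summary.csv", index=False
    )
    np.savetxt(
        outdir / "membership_probabilities.csv",
        bundle["summary"].membership_probabilities,
        delimiter=",",
    )
    bundle["diagnostics"].to_csv(outdir / "diagnostics.csv")
    report = _text_report(bundle)
    (outdir / "report.txt").write_text(report)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    try:
        _plots(bundle, outdir)
    except Exception as exc:  # plotting must never sink a finished run
        logger.warning("plotting failed: %s", exc)


def _text_report(bundle: dict) -> str:
    partition = bundle["partition"]
    summary = bundle["summary"]
    lines = [
        "profile regression run report",
        f"representative clusters: {partition.k}",
        f"cluster sizes: {', '.join(map(str, summary.sizes))}",
        "relative risks (posterior mean [95% CI]):",
    ]
    for c in range(partition.k):
        lo, hi = summary.rr_ci[c]
        lines.append(
            f"  cluster {c + 1}: {summary.rr_mean[c]:.3f} [{lo:.3f}, {hi:.3f}]"
        )
    if bundle.get("prediction"):
        pred = bundle["prediction"]
        lines.append(
            f"scenario percent change: {pred['mean']:.2f}% "
            f"[{pred['ci'][0]:.2f}%, {pred['ci'][1]:.2f}%]"
        )
    acc = bundle["chain"].acceptance
    lines.append(
        "acceptance rates: "
        + ", ".join(f"{k}={v:.2f}" for k, v in acc.items() if np.isfinite(v))
    )
    return "\n".join(lines) + "\n"


def _plots(bundle: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = bundle["summary"]
    probs = summary.membership_probabilities
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(probs.T, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_xlabel("day")
    ax.set_ylabel("representative cluster")
    fig.colorbar(im, ax=ax, label="membership probability")
    fig.savefig(outdir / "membership_heatmap.png", dpi=100)
    plt.close(fig)

    k, P = summary.exposure_mean.shape
    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(P)
    for c in range(k):
        ax.errorbar(
            x + 0.1 * c,
            summary.exposure_mean[c],
            yerr=np.abs(summary.exposure_ci[c].T - summary.exposure_mean[c]),
            fmt="o",
            label=f"cluster {c + 1}",
        )
    ax.set_xlabel("exposure metric")
    ax.set_ylabel("posterior mean (normalised)")
    ax.legend()
    fig.savefig(outdir / "cluster_profiles.png", dpi=100)
    plt.close(fig)

    chain, design = bundle["chain"], bundle["design"]
    betas = np.array([s.beta for s in chain.states])
    contrib = betas @ design.basis.T  # (n_draws, T)
    mean = contrib.mean(axis=0)
    lo, hi = np.percentile(contrib, [2.5, 97.5], axis=0)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(mean, lw=1)
    ax.fill_between(np.arange(len(mean)), lo, hi, alpha=0.3)
    ax.set_xlabel("day")
    ax.set_ylabel("spline contribution to log rate")
    fig.savefig(outdir / "coefficient_curves.png", dpi=100)
    plt.close(fig)


def run_sensitivity(
    config: RunConfig, alpha_priors, well_populated_threshold: int = WELL_POPULATED_THRESHOLD
) -> dict:
    """Refit under several Gamma priors for the DP concentration.

    Reports, per prior, the median per-sweep number of occupied clusters and
    the median number of well-populated clusters (occupancy above
    ``well_populated_threshold`` days), plus the pairwise adjusted Rand
    index between representative partitions.
    """
    alpha_priors = list(alpha_priors)
    if len(alpha_priors) < 2:
        raise ValidationError("need at least 2 alpha prior settings")
    config.validate_paths()
    partitions = {}
    per_prior = {}
    for a, b in alpha_priors:
        sub = RunConfig.from_dict(
            {
                **asdict(config),
                "alpha_shape": float(a),
                "alpha_rate": float(b),
                "output_dir": str(Path(config.output_dir) / f"alpha_{a}_{b}"),
            }
        )
        bundle = run_full_analysis(sub)
        chain = bundle["chain"]
        well = [
            int(np.sum(np.bincount(g) > well_populated_threshold))
            for g in chain.allocations
        ]
        per_prior[(a, b)] = {
            "median_occupied": float(np.median(chain.n_occupied[chain.config.burn_in:])),
            "median_well_populated": float(np.median(well)),
            "n_representative": int(bundle["partition"].k),
        }
        partitions[(a, b)] = bundle["partition"].labels
    keys = list(partitions)
    ari = {}
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            ari[(keys[i], keys[j])] = float(
                adjusted_rand_score(partitions[keys[i]], partitions[keys[j]])
            )
    return {"per_prior": per_prior, "pairwise_ari": ari, "partitions": partitions}


def _versions() -> dict:
    import scipy
    import sklearn

    return {
        "profreg": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
    }
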