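# profreg

Bayesian profile regression for daily multipollutant time series.

Urban air is a mixture: particle number counts, nitrate, sulphate, black
smoke, size-fractionated and source-apportioned particulate mass all move
together, and single-pollutant regressions cannot say which *mixtures* matter
for health. `profreg` addresses this with a Dirichlet-process mixture model
that jointly clusters days by their multipollutant profile **and** a Poisson
count outcome (e.g. daily respiratory deaths), so the clusters are informed
by both exposure and response. It is written for environmental
epidemiologists and biostatisticians analysing daily monitoring data.

## The model

For day t with normalised exposure profile z_t, count y_t and spline design
row u_t:

    p(y_t, z_t | Θ, u_t) = Σ_k  w_k · p(y_t | Θ_k, Θ_0, u_t) · p(z_t | Θ_k)

* w_k — stick-breaking DP weights, V_k ~ Beta(1, α), α ~ Gamma(2, 1);
* z_t | g_t = k ~ N(m_k, Σ_k), with empirical-Bayes hyperpriors on
  (m_k, Q_k = Σ_k⁻¹);
* y_t ~ Poisson(λ_t), log λ_t = log E_t + μ_{g_t} + Σ_h u_{t,h} β_h + ε_t,
  where E_t is the period-average count (offset), μ_k the cluster log
  relative risk, β the natural-cubic-spline coefficients for calendar time
  (8 df/year) and temperature (3 df), and ε_t ~ N(0, σ_ε²) extra-Poisson
  day noise.

Inference is a dependent-slice MCMC sampler (Gibbs + Metropolis-within-Gibbs,
label-switching moves, within-sampler imputation of missing exposure cells).
The posterior over partitions is condensed — via the posterior similarity
matrix and partitioning around medoids on 1 − S — into a representative
partition with model-averaged cluster profiles, relative risks and 95%
credible intervals. A posterior predictive module compares daily-count
distributions under alternative exposure scenarios and reports the percent
change. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import profreg as pr
from profreg.synthetic import generate_dataset
from sklearn.metrics import adjusted_rand_score

# two years, six metrics, three exposure clusters with log-RRs -0.3/0/0.3
config = pr.recovery_config(seed=11)
ds = generate_dataset(config)

norm   = pr.normalize_exposures(ds.exposures)          # modified z-score
offset = pr.compute_offset(ds.outcome)                 # E_t = mean(y)
design = pr.build_confounder_design(
    np.arange(1, 731), ds.temperature, time_df=16, temp_df=3)
hyper  = pr.empirical_hyperparams(norm)

chain = pr.run_mcmc(norm.z, ds.outcome, design, offset, hyper,
                    pr.McmcConfig.scaled_down(seed=101))
S     = pr.similarity_matrix(chain)
part  = pr.representative_partition(S, range(2, 8))
summ  = pr.cluster_summaries(chain, part, norm)

print("clusters:", part.k, "sizes:", part.sizes())
print("ARI vs truth:", round(adjusted_rand_score(ds.true_labels, part.labels), 3))
for c in range(part.k):
    lo, hi = summ.rr_ci[c]
    print(f"cluster {c+1}: RR {summ.rr_mean[c]:.3f} [{lo:.3f}, {hi:.3f}]")
```

Output:

```
clusters: 3 sizes: [436 180 114]
ARI vs truth: 0.991
cluster 1: RR 0.815 [0.792, 0.837]
cluster 2: RR 1.124 [1.083, 1.169]
cluster 3: RR 1.505 [1.442, 1.573]
```

Three clusters are recovered almost exactly (adjusted Rand index 0.99).
Because the offset is the period-average count, each RR is the cluster's
risk relative to the period average; the generative values on that scale
are 0.822 / 1.110 / 1.499 for this draw, and all three 95% intervals cover
them.

There is also a CLI for shell pipelines:

```bash
profreg simulate --preset recovery --seed 1 --out data.csv
profreg fit --config analysis.yaml          # normalise -> splines -> MCMC -> summaries
profreg crossvalidate --input-csv data.csv --split-date 2003-07-03
profreg sensitivity --config analysis.yaml  # alternative Gamma priors on alpha
```

Every run writes a manifest (config digest, seed, package versions) that is
sufficient to reproduce it exactly.

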