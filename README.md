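# dgcnet

Estimation of **dynamic directional brain networks** from multivariate time
series, and discovery of recurring network configurations by multi-level
clustering — with a built-in simulator for validation and a GLM relating
connectivity metrics to behavior.

Resting-state fMRI work increasingly treats connectivity as time-varying:
regions engage and disengage, and the whole-brain configuration appears to
switch between a small number of quasi-stable states. Most of that literature
uses *symmetric* (correlation-based) connectivity. `dgcnet` implements the
directional analogue: time-varying Granger causality between all region pairs,
followed by clustering that finds which directed network configurations recur
over time and across runs/subjects, and a variance-partitioning analysis of
how much behavior the dynamic vs. static metrics explain.

## The model

Signals `Y(t) = [y_1(t) … y_l(t)]` follow a multivariate autoregression

```
Y(t) = B + Σ_{m=1..p} K(m) · Y(t−m) + N(t)
```

with static Granger causality from region *i* to region *j* defined as
`G_ij = Σ_m k_ij(m)²`. Letting the coefficients drift in time, `K(m) → K(m,t)`,
gives **dynamic Granger causality**

```
DGC_ij(t) = Σ_m k_ij(m,t)²
```

estimated by recursive least squares with exponential forgetting: sample
`t−s` is weighted by `(1−F)^s`, where the forgetting factor `F` is chosen on a
grid by minimizing the variance over time of the squared one-step prediction
error energy, `F = argmin var(‖Ñ(t)‖²)`. The model order `p` is selected by
BIC (typically 1 for TR-resolution fMRI).

Downstream, the asymmetric signed DGC matrices are converted into symmetric
distances in two steps:

1. `C_ij = (|DGC_ij|^m + |DGC_ji|^m)^{1/n}` with `m = 2, n = 1`;
2. a reversed-S sigmoid `D = 1 / (a + b·f^C)` with `a = 1`, `b = 0.2`, and the
   base `f` solved from the anchor `D(th₀) = 0.5`, where `th₀` is the 95th
   percentile of `C` under a phase-randomization surrogate null (phases
   scrambled per region in the frequency domain, magnitudes kept — spectra
   preserved, cross-dependence destroyed). At `th₀ = 0.01` and `b = 0.2` the
   solved base is `f = 5¹⁰⁰`, so the transform is evaluated in log space.

Three levels of clustering follow:

* **Level 1 (regions × time)** — agglomerative (average-linkage) clustering of
  the regions at every time point on exponentially smoothed distance matrices
  `S_t = α·S_{t−1} + (1−α)·D_t` (an evolutionary-clustering scheme; `α` chosen
  by one-step-ahead prediction error).
* **Level 2 (time points within a run)** — partitions are compared with a
  greedy label-matching distance (the number of regions whose labels disagree
  after best-overlap clusters are matched), clustered hierarchically with the
  state count chosen by silhouette. Each state gets a **centroid agent** (the
  member time point closest to the state's mean distance matrix), occurrence
  counts, dwell-time statistics, and a histogram-gap dominance threshold.
* **Level 3 (runs/subjects)** — dominant level-2 agents are vectorized
  (off-diagonal entries) and pooled across runs into weighted k-means, with
  weights equal to occurrence times; the cluster with the largest total weight
  is the group-dominant configuration.

Finally, the behavior GLM `B_ij = α_ij·DEC_ij + β_ij·SEC_ij + ε` relates each
behavioral score to the variance over time of DGC (DEC) and the absolute
static causality (SEC) per connection, with z-tests, Bonferroni correction
(e.g. `0.05/70 = 0.00071`), and explained-variance fractions
`mean((α·DEC)²) / [mean((α·DEC)²) + mean((β·SEC)²)]`.

## Worked example

The package ships a three-scenario simulator of time-varying vector
autoregressions with known block structure (constant coefficients; sinusoidal
modulation with period 200π; block membership circularly shifted every 200
samples). The full chain on the default shifting scenario:

```bash
dgcnet pipeline --seed 7 --out run/
```

prints

```
order=1 forgetting=0.02 th0=0.002993 states=20 dominant level-3 cluster=2
```

meaning: BIC picked a lag-1 model; the residual-variance criterion picked
forgetting factor 0.02; the surrogate null put the significance threshold at
C ≈ 0.003; level-2 clustering found 20 recurring configurations in the run;
and (0-based) cluster 2 carried the largest total occurrence weight at level
3. `run/level2_summary.tsv` then holds the per-run state statistics:

```
n_states  dwell_mean_s  dwell_std_s  time_per_state_desc_s
20        7.54          12.40        205, 122, 115, 95, 90, 87, 60, ...
```

i.e. the run dwells 7.5 s on average in a state before switching, and the
per-state total times fall off steeply — a few dominant states occupy most of
the run, the signature of quasi-stable switching. `run/level3_summary.tsv`
lists members and total occurrence times per group-level cluster, and
`run/level3_agent.tsv` is the representative distance matrix of the dominant
configuration.

Every stage is also available separately (`dgcnet simulate`, `dgc`,
`null-threshold`, `distance`, `cluster1`, `cluster2`, `cluster3`, `behavior`),
and as library functions (`dgcnet.fit_dynamic_mvar`, `dgcnet.cluster_level1`,
…) operating on plain numpy arrays and small dataclasses.

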