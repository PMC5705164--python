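# hiermove

Population-level inference from sparse satellite telemetry with a binary
movement response.

Tracking studies of wide-ranging marine animals (sharks, tunas,
billfish) often end up data-limited: irregular surfacing, tag failure
and Argos-class position error leave tracks too sparse for step-length
or state-space machinery. `hiermove` implements a pipeline that still
supports quantitative *population-level* statements in that regime by
reducing the question to a grouped binary response — e.g. "was the
animal east or west of 125°W?" — and modeling it hierarchically:

    z_i ~ Bernoulli(mu_i)
    logit(mu_i) = beta0 + beta1 Spring_i + beta2 Summer_i + beta3 Winter_i
                  + beta4 L_i + beta5 Sex_i + beta6 MEI_i + u_j(i)
    u_j ~ N(0, 1/tau),   beta_k ~ N(0, 10),   tau ~ Gamma(0.1, 0.01)

where `u_j` is a per-individual random intercept linking individual
tracks to the population, `L` is z-scored body length, and `MEI` is a
slowly varying climate index. The package provides:

- **telemetry preprocessing** — daily best-quality Argos filtering
  (classes ranked D, 3, 2, 1, 0, A, B, Z), east/west response coding,
  season one-hot encoding, z-scoring, track indexing, and error-box
  extraction of gridded covariates;
- **variable screening** — a class-balanced random forest (fixed
  per-class subsamples without replacement) with response-permutation
  p-values and a perfect-predictor guard;
- **linearity checking** — a penalized-spline additive logistic model
  with a per-individual random intercept, reporting effective degrees
  of freedom per term (EDF ≈ 1 ⇒ treat as linear);
- **the hierarchical Bayesian model** — a bespoke multi-chain
  Metropolis-within-Gibbs sampler with adaptation, burn-in, thinning,
  classic Gelman–Rubin diagnostics, posterior summaries, a priors-only
  mode and a prior-influence (vagueness) check with variance expansion;
- **maximum-likelihood counterparts** — Laplace-approximation and PQL
  fitters for the same random-intercept logistic model, plus an
  adaptive Gauss–Hermite quadrature oracle;
- **robustness experiments** — data-paucity subsetting (25 replicates
  at 75/50/25/10%) and simulation-based parameter recovery with a
  synthetic-data generator whose ground truth is recorded.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from hiermove import (
    SimConfig, simulate_dataset, PriorSpec, MCMCConfig,
    sample_posterior, summarize_posterior, gelman_rubin, fit_laplace,
)

# a telemetry-like dataset with known truth: 34 individuals, ~100
# locations each, beta = (-1.0, 0.75, -1.0, 0.0, 1.0, 0.1, -0.5), sigma_u = 2.5
ds = simulate_dataset(SimConfig(seed=1, mean_locations=100))
model = ds.model()

draws = sample_posterior(model, PriorSpec(),
                         MCMCConfig.from_preset("desk", seed=7))
print(summarize_posterior(draws, include_u=False))
print(max(v for k, v in gelman_rubin(draws).items() if k.startswith("B")))
```

Output (abridged):

```
  parameter      mean        sd      q2.5     q97.5
0        B0 -1.522584  0.652353 -2.817543 -0.280822
1        B1  0.805159  0.144899  0.515964  1.088157
2        B2 -1.074640  0.144838 -1.357533 -0.784176
3        B3  0.105313  0.135586 -0.152625  0.376991
4        B4  1.282972  0.438995  0.443383  2.169795
5        B5  1.230737  0.848770 -0.407582  2.899513
6        B6 -0.598914  0.055498 -0.709150 -0.492131
7         s  2.483565  0.370682  1.868949  3.314462
1.0026
```

Reading it: the Spring (`B1`) and Summer (`B2`) coefficients have 95%
credible intervals excluding zero — relative to Fall, spring locations
lean west and summer locations lean east of the boundary — and both
intervals cover the simulating truth (0.75, −1.0). The process sd `s`
recovers the generating 2.5. The final line is the maximum Gelman–Rubin
statistic over the coefficients; values between 1 and 1.01 indicate the
four chains have converged. The Sex coefficient (`B5`) is wide: with one
sex value per individual and strong individual variation, 34 animals
carry little information about it — exactly the kind of honest
uncertainty the hierarchical model is for. The Laplace fit of the same
data (`fit_laplace(model)`) lands within ~0.1 of the posterior means.

The same stages are available from the shell:

```bash
hiermove simulate --seed 1 --out-dir out/
hiermove fit-bayes --input-table out/simulated_table.csv --preset desk --seed 7
hiermove paucity --input-table out/simulated_table.csv --seed 7
```

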