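# Methods

`bfirt` implements a joint hierarchical model of response accuracy (RA) and
response time (RT) for between-item multidimensional tests, in which both
measurement models are bi-factor: every item loads on a general factor shared
by the whole test and on exactly one of several mutually orthogonal specific
factors determined by a loading pattern.

## Model

**Level 1 (measurement).** For person *i* and item *j* with specific
dimension *s(j)*:

* accuracy follows a bi-factor two-parameter logistic model,

  P(u_ij = 1) = logistic( d_j + a_gj θ_gi + a_sj θ_{s(j),i} ),

  with general/specific discriminations a_gj, a_sj > 0 and location d_j;

* log response time is normal,

  ln T_ij = β_j − (α_gj τ_gi + α_sj τ_{s(j),i}) + ε_ij,
  ε_ij ~ N(0, σ_j²),

  with time intensity β_j (expected log-seconds at zero speed), speed
  slopes α_gj, α_sj > 0, and residual SD σ_j whose reciprocal acts as a
  time discrimination.

**Level 2 (population).** Each ability–speed factor pair (θ_g, τ_g) and
(θ_s, τ_s) per dimension is bivariate normal with means 0, variances 1
(the identification constraints) and a free correlation; distinct factor
pairs are independent (bi-factor orthogonality). The item pair (d_j, β_j)
is bivariate normal with free means, scales and correlation.

**Nested variants.** One parameterization covers the whole family:

| variant  | general factors | RA specifics | RT specifics |
|----------|-----------------|--------------|--------------|
| `bfhm`   | yes             | S            | S            |
| `cmhm`   | no              | S            | S            |
| `pmhm`   | no              | S            | 1            |
| `unidim` | no              | 1            | 1            |

Zeroing the general loadings of the full model reproduces the `cmhm`
likelihood exactly (bit-identical), and collapsing the specific dimensions
reproduces `pmhm`/`unidim`; the test suite asserts these identities.

For `pmhm` the level-2 link between one speed factor and several ability
factors is not determined by the bi-factor structure; we let the single
speed regress on all abilities (an arrow-shaped correlation matrix with one
free entry per ability, positive-definiteness enforced by the log-determinant
barrier of the density itself). This variant serves as a comparison
baseline; its within-family ordering is unaffected by this choice.

The RT likelihood is evaluated as a normal density of ln t (no Jacobian to
the seconds scale). Absolute fit indices are therefore on the log-time
scale; every variant shares the transform, so model ordering is unaffected.
Missing cells (empty CSV cells, NaN) contribute zero log likelihood, are
excluded from fit indices, and are counted.

## Priors and identification

Loadings and the time discrimination 1/σ_j have standard-normal priors
truncated to (0, ∞); strict positivity also pins the factor signs, so no
post-hoc reflection is needed. Each 2×2 correlation block has an LKJ(η)
prior, η = 1 by default (uniform on the correlation), implemented in atanh
coordinates with the log(1−ρ²) Jacobian. Hyper-priors: μ_d ~ N(0, 0.5),
μ_β ~ N(4, 0.5) (the second argument is an SD), and half-normal σ_d, σ_β.
Person factors are fixed to mean 0, variance 1. Person traits use the
conditional factorization θ ~ N(0, I), τ | θ ~ N(Pθ, diag(1 − ‖P_k‖²)),
which reproduces unit marginal variances and makes the entries of P the
ability–speed correlations.

## Estimation

The sampler is a self-contained No-U-Turn sampler (multinomial tree
doubling, dual-averaging step size targeting 0.8 acceptance, windowed
diagonal mass-matrix adaptation, divergence flagged at energy error 1000)
driven by a numba-compiled log posterior with hand-derived analytic
gradients. Gradients are verified against central finite differences and
the log posterior against an independent scipy construction in the test
suite (1e-10 relative).

Default protocol: 2 chains, 40,000 total iterations across chains,
first half of each chain warmup, thinning 2 — i.e. the final 20,000
pre-thinning iterations are retained (10,000 draws). Point estimates are
posterior means (EAP); convergence is judged by split-chain PSRF < 1.1 per
parameter (the split form also detects within-chain drift; constant chains
return 1 by convention). Chains initialize from dispersed moment estimates:
d_j at the logit of the observed proportion correct, β_j and 1/σ_j at the
mean and reciprocal SD of the item's observed log times, traits at
standardized overall (general) and per-group (specific) person scores, all
jittered. This keeps short adaptation phases away from the far tails where
items with small residual SD mix slowly.

## Model comparison

WAIC (−2(lppd − p_waic), with the unbiased S−1 variance in p_waic) and
PSIS-LOO are computed from pointwise log-likelihood draws. The pointwise
unit is the person × item *cell*, separately for the RA and RT components;
the two components are conditionally independent given the latent traits, so
component indices add to the total, matching a report layout with RA / RT /
total columns. PSIS follows the standard recipe (20% tail capped at 3√S,
empirical-Bayes generalized-Pareto fit, expected order statistics,
truncation at the raw maximum, k > 0.7 flagged); it reproduces the arviz
reference implementation to 1e-6, while arviz's WAIC differs only by its
1/S variance convention (the suite checks equality after aligning
conventions).

## Synthetic data

The generator draws, per replication: loadings a_g, a_s, α_g, α_s from the
standard normal truncated to (0, ∞); (d_j, β_j) bivariate normal with means
(0, 4), variances (1, 0.25), covariance −0.25; ability–speed correlations
fresh from Uniform(−1, 1) per factor pair (a warning is logged beyond
|ρ| > 0.99, where the pair is near-singular); traits bivariate normal under
those correlations. A response is correct when the model probability is ≥ a
fresh Uniform(0,1) draw; log times are normal with the model mean and σ_j.
All randomness derives from one seed through independent substreams (items,
correlations, persons, RA noise, RT noise), so changing N never perturbs the
item draws, and every dataset is byte-reproducible.

The residual SD σ_j is drawn half-normal on the σ scale. Drawing its
reciprocal instead would give σ no finite second moment: roughly 8% of items
would have σ > 10, and for such items β_j (standard error σ/√N) and σ_j are
essentially unrecoverable, so every RT-side recovery summary would be
dominated by a few degenerate items rather than by estimation quality.
Bounding σ keeps all item parameters identifiable and yields the recovery
profile the quick study reports; the estimation prior remains on 1/σ.

What the generator does *not* emulate: real tests with guessing or
carelessness (no lower asymptote), conditional RA–RT dependence beyond the
trait correlations, aberrant behaviours (speededness, item preknowledge),
within-item multidimensionality, or non-lognormal RT shapes. Passing
recovery tests therefore demonstrates internal consistency of estimator and
generator under the model's own assumptions, not robustness to these
violations.

## Quick-study problem sizes

The full published-style grid ({500, 1000} examinees × {30, 60} items × 30
replications × 2 chains of 20,000 iterations) is an overnight batch. The
package's quick study — what `tests/test_acceptance.py` and
`scripts/acceptance.py` run — uses the same generating process with:

* recovery: (500, 30) with 3 (tests) or 2 (script) replications, plus one
  replication each at (1000, 30) and (500, 60); 2 chains × (300 warmup +
  300 draws), maximum tree depth 7;
* model selection: 3 datasets at (500, 30), each fitted under `bfhm`,
  `cmhm`, `pmhm` with 2 chains × (100 + 100);
* interval calibration: 20 (tests) or 10 (script) replications at
  (150, 15) with ρ_general = −0.5, 2 chains × (125 + 125).

At these chain lengths a handful of parameters in each big fit still sit
above PSRF 1.1 (the fits are flagged, and EAP summaries are barely
affected); comparisons against reference recovery levels use ±2 Monte-Carlo
standard errors estimated from the replications. Tree depth is capped at 7
in the quick study because rare depth-10 trajectories dominate runtime
without changing the estimates.

## Numerical choices and edge cases

* Bernoulli log likelihood via log1p-exp forms; stable to |η| ≈ 700.
* Leapfrog excursions that overflow exp(·) or push a correlation row past
  unit norm get log posterior −∞ (the trajectory is rejected or flagged
  divergent) rather than NaN.
* The simulated-response rule scores a tie (probability equal to the
  uniform draw) as correct; ties have probability zero but the rule is
  fixed for reproducibility.
* PSIS with constant weights returns k = −∞ (nothing to smooth); GPD fits
  need ≥ 5 tail points, otherwise k = ∞ and the weights stay raw.
* `mse`/`bias` denominators count replications × units, with units = items
  for item families and examinees for person families; study-level values
  pool replications (equal unit counts make this the mean of per-replication
  values, whose spread provides the Monte-Carlo SE).
* The recovery study redraws person correlations every replication and
  records each draw; non-converged replications are flagged and excluded
  only when configured.

## Known limitations

* Dense posteriors (N·(K_a+K_t) trait dimensions) make the diagonal-metric
  NUTS slow for items combining a large specific slope with a small residual
  SD; such coordinates can need several thousand iterations to reach
  PSRF < 1.1 even though EAPs stabilize much earlier.
* PSIS-LOO at cell level with person-specific latent parameters yields many
  moderate Pareto-k values (each cell is informative about its person's
  trait); rankings are clear-cut in practice, but absolute LOO values
  should be read with the k diagnostics.
* The CLI writes person-trait draws only on request (`--include-persons`);
  the long-form draws file would otherwise grow by a factor of N.
* `UNIDIM` ignores the pattern's grouping entirely; fitting it to strongly
  multidimensional data is only meaningful as a baseline.
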