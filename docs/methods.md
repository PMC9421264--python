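# Methods

## Model

Binary responses follow the multidimensional 4-parameter logistic model

P(Y_ij = 1 | θ_i) = c_j + (d_j − c_j) σ(a_jᵀ θ_i + b_j),  θ_i ~ N(0, I_K),

with the 3PL (d ≡ 1) and 2PL (c ≡ 0, d ≡ 1) flavors as special cases.
Under local independence the marginal likelihood integrates θ out; the
package never evaluates that integral, it maximizes variational lower
bounds instead.  The asymptotes are stored on the logit scale so ascent is
unconstrained; the loadings carry no constraint (exploratory fitting), so
estimates are identified only up to an oblique rotation, column signs and
column order, which the alignment pipeline resolves post hoc.

Fitting assumes the latent covariance is the identity even when the data
were generated with correlated factors; any factor correlation is
recovered afterwards from the promax rotation's implied correlation
matrix.

## Inference

The encoder is a multilayer perceptron with Tanh hidden layers and two
linear heads producing (μ_i, log σ_i²) of a diagonal Gaussian posterior.
Because every unit is a nonlinearity of a linear combination of its
inputs, zero-filled missing entries contribute nothing; combined with the
mask-multiplied Bernoulli log-likelihood this implements the
input-dropout treatment of missing-at-random data.  Placeholder values at
masked cells are provably irrelevant (tested as an exact invariance).

Three gradient estimators are used:

* **ELBO** with the analytic Gaussian KL; pathwise (reparameterized)
  gradients.  The KL term's weight rises linearly from 0 to 1 during the
  annealing stage to prevent posterior collapse.
* **IW-ELBO** (1/S) Σ_s [log (1/R) Σ_r w_rs − log R] with
  w = p(y, θ|M_p)/q(θ|y).  Decoder gradients use the self-normalized
  weights softmax(v) with v = log w computed on the log scale and combined
  by log-sum-exp.
* **DReG** for the encoder during IW-ELBO training: squared normalized
  weights times the pathwise derivative of v with the variational
  parameters inside v held fixed.  On a 1-D conjugate toy this estimator
  is unbiased (checked against a common-random-number gradient oracle) and
  has ~30× lower variance than the naive weighting at R = 5.

The KL formula implemented is ½ Σ_k (μ_k² + σ_k² − 1 − log σ_k²), i.e.
with the square on μ, and is verified against a 10⁶-draw Monte Carlo
oracle.

## Training schedule

Plain stochastic gradient ascent with fixed step sizes; minibatches of
persons drawn uniformly with replacement; the minibatch reduction is the
mean, so the step size is batch-size invariant.  No gradient clipping or
adaptivity.  Stages:

1. **KL annealing** — ⌈0.01 · T_max⌉ steps of annealed ELBO; the
   asymptotes c, d are frozen (their gradients are computed but not
   applied).
2. **ELBO converging** — ELBO ascent until the windowed rule fires.
3. **IW-ELBO converging** — importance-weighted objective with S·R
   samples and DReG encoder gradients; fresh convergence monitor.

The convergence rule averages the stage's own minibatch objective over
consecutive non-overlapping windows of `window` steps and keeps a running
best; a window that does not strictly exceed the best increments a
patience counter (the first window initializes the best and counts as
non-improving), an improving window resets it; the rule fires at
`patience` consecutive non-improvements.  Comparing to the previous
window instead of the running best is available via `compare_to`.  The
iteration counter is global across the three stages; a fit is *successful*
iff stages 2 and 3 both stopped via the rule rather than by reaching
`max_iter`.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| batch_size | 16 | small minibatch keeps per-step cost N-independent |
| n_mc_samples (S) | 1 | single Monte Carlo draw per step suffices with minibatching |
| n_iw_samples (R) | 5 | tightens the bound materially at modest cost |
| learning_rate | 0.01 | fixed ascent step for encoder, loadings, easiness |
| asymptote_learning_rate | 0.001 | c, d live in (0,1); smaller steps avoid overshoot |
| max_iter | 200,000 | global cap; converged fits typically stop near 40,000–60,000 |
| anneal_fraction | 0.01 | 2,000 annealing steps at the default cap |
| window / patience | 100 / 50 | objective plateau must persist for 5,000 steps |
| hidden_sizes | (130, 65) | ≈ J and J/2 at J = 100; larger nets gain little on CPU |
| encoder init | Glorot uniform, log-variance head at 0 | training starts at the prior scale σ² = 1 |
| item init | A ~ N(0, 0.1²), b = 0, c = 0.1, d = 0.9 | asymptotes start at their generative prior means |

## Synthetic data generator

The generator reproduces the benchmark design: an s-shaped sparse loading
support built from a blocked-diagonal seed (m = max(1, round(J/2K)) rows
per factor, so at least one horizontal flip occurs before J rows are
reached; within-item rows additionally load the cyclically next factor);
free loadings Uniform(0.5, 1.5) with exact structural zeros; c ~ Beta(1,9)
and d ~ Beta(9,1) redrawn as whole vectors until all c_j < d_j; factor
covariance either identity or unit-diagonal with Uniform(0,1)
off-diagonals redrawn until the smallest eigenvalue is ≥ −1e−10.  The
easiness distribution is not part of the published design; b_j ~ N(0, 1)
was chosen as the conventional scale and is configurable.  Missingness
masks exactly round(0.8 · J) uniformly chosen cells per row — exact counts
rather than iid coin flips, so every simulated person answers the same
number of items and count assertions are deterministic.

What the generator does **not** emulate: multistage-adaptive assignment
(its missingness is uniform, not performance-dependent), item content
structure, local dependence violations, polytomous or longitudinal
responses.  Passing recovery tests therefore demonstrate correctness of
the estimator under the stated sampling model, not robustness to adaptive
or informative missingness.

## Evaluation pipeline

Aligned-loading errors use promax (varimax followed by a powered-target
procrustes, kappa = 4, Kaiser row normalization off by default), sign
flips for columns with negative sums (mirrored onto the implied factor
correlation's rows and columns), and an exhaustive search over the K!
column permutations minimizing mean squared deviation (ties break
lexicographically; K ≤ 8).  Item-indexed parameters b, c, d carry no
rotational indeterminacy and are compared directly.  Per-parameter RMSE is
computed across replications, then averaged within each block with the
standard error taken across parameters.  Held-out prediction feeds the
posterior means (not posterior draws) through the IRF and thresholds at
0.5 by default.

## Numerical choices

* IRF probabilities are clamped to [1e−7, 1 − 1e−7] before logs so the
  likelihood stays finite as c → 0 or d → 1; log importance weights are
  clamped at ±1e6 as a last-resort guard (with a warning).
* Asymptote values at exactly 0 or 1 are clamped inward (1e−12) before the
  logit transform, with a warning.
* A column with an exactly zero sum keeps its sign during sign alignment,
  with a warning.
* Rank-deficient loading estimates are rejected by promax with a
  diagnostic rather than producing a singular target regression.
* Non-finite gradients abort the fit with the stage and step in the
  message; degenerate (constant, fully observed) items produce a warning,
  not an abort.

## Problem sizes in the acceptance script

`scripts/acceptance.py` runs the generating and training configuration at
full fidelity (N = 500 or 10,000, J = 100, K = 5, T_max = 200,000) but
with B = 5 refits per experiment rather than 100; per-parameter RMSE over
5 replications estimates the same quantity with a modestly wider sampling
spread.  The acceptance tests use B = 2 for the same reason.

## Known limitations

* At N = 500 with 80% missingness each item is observed ~100 times, which
  barely identifies the asymptotes: guessing estimates improve only
  marginally on the generative prior mean, so their RMSE is governed
  largely by the dataset's realized Beta(1,9) dispersion.
* Promax recovers a planted oblique mixing essentially exactly only when
  the mixing is mild (unit-norm columns, off-diagonal mass ≲ 0.1); under
  strong oblique distortion the powered-target approximation leaves a
  residual column-scale error of several percent.
* Fixed-step SGD leaves trailing-iterate noise in the estimates; no
  averaging or step-size decay is applied, matching the training recipe.
* Amortization and the diagonal posterior bound the achievable likelihood
  from below; no full-covariance or flow posteriors are provided.
* No standard errors or inferential procedures for the estimates.
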