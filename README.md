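# mirtvae

Importance-weighted variational autoencoder estimation of multidimensional
2-, 3- and 4-parameter logistic item response models (M2PL / M3PL / M4PL),
for large sparse binary assessment data.

## The problem

Item response theory models a binary response of person *i* to item *j*
through a latent ability vector θᵢ ∈ ℝᴷ:

    P(Yᵢⱼ = 1 | θᵢ) = cⱼ + (dⱼ − cⱼ) · σ(aⱼᵀθᵢ + bⱼ),     θᵢ ~ N(0, I)

with discriminations (loadings) aⱼ, easiness bⱼ, a lower asymptote cⱼ
(guessing) and an upper asymptote dⱼ (1 − dⱼ is the slipping probability).
M3PL fixes d ≡ 1, M2PL additionally c ≡ 0.  Marginal maximum likelihood
requires a K-dimensional integral per person, which classical methods
(quadrature, Monte Carlo EM, Metropolis–Hastings Robbins–Monro) handle
poorly once N is large, K > 1 and the asymptotes are free.

`mirtvae` instead performs amortized variational inference: a Tanh MLP
*encoder* maps each (zero-filled) response vector to a diagonal Gaussian
posterior q(θ|y) = N(μ, diag(σ²)), and training maximizes first the ELBO
(with linear KL annealing and the analytic Gaussian KL), then the tighter
importance-weighted bound

    IW-ELBO = E[ log (1/R) Σᵣ wᵣ ],   wᵣ = p(y, θᵣ) / q(θᵣ | y),

with R importance samples, log-sum-exp stabilized weights, and the doubly
reparameterized (DReG) gradient for the encoder, whose squared normalized
weights and pathwise-only derivative avoid the signal-to-noise collapse of
the naive estimator as R grows.  Missing responses enter as exact zeros
plus an observation mask, so missing-at-random cells contribute nothing to
either the likelihood or the encoder.  All gradients are derived by hand in
NumPy and checked against finite differences and quadrature oracles in the
test suite.

## Worked example

```python
import numpy as np
from mirtvae import MIRTVAE, SimulationConfig, generate_dataset, align_loadings

cfg = SimulationConfig(n_persons=500, n_items=100, n_factors=5, model="4pl",
                       item_structure="between", missing_proportion=0.8, seed=101)
data, truth = generate_dataset(cfg)          # each person answers 20 of 100 items

X = np.where(data.mask == 1.0, data.y, np.nan)
est = MIRTVAE(n_factors=5, model="4pl", random_state=201).fit(X)
print(est.success_, est.n_iter_per_stage_)

aligned = align_loadings(est.loadings_, truth.params.loadings)
print(round(float(np.sqrt(((aligned.loadings - truth.params.loadings) ** 2).mean())), 3))
print(round(float(np.sqrt(((est.guessing_ - truth.params.guessing) ** 2).mean())), 3))
```

Output:

```
True {'anneal': 2000, 'elbo': 20700, 'iw_elbo': 37400}
0.724
0.11
```

`success_=True` means both converging stages stopped via the windowed rule
(mean objective over 100-step windows failing to improve on its running
best 50 times) rather than hitting the 200,000-step cap.  The two printed
numbers are recovery RMSEs: the loading estimate after promax rotation,
column sign flips and the best column permutation deviates from the
generating loadings by 0.72 RMSE per entry, and the guessing asymptotes by
0.11 — close to the attainable floor at N=500 with 80% missingness, where
each item is observed only ~100 times.  `est.transform(X)` returns the
posterior-mean abilities, `est.predict_proba(X)` the model probabilities.

A command line mirrors the library: `mirtvae simulate`, `fit`, `evaluate`,
`benchmark` (simulate → B fits → RMSE/success report) and
`predict-heldout`; every run writes delimited-text artifacts and a
checksummed manifest.

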