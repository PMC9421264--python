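"""Three-stage stochastic gradient ascent estimator for M2PL/M3PL/M4PL.

Training follows a fixed three-stage schedule:

1. **KL annealing** — for the first ``ceil(anneal_fraction * max_iter)``
   steps the ELBO's KL term is weighted by ``t / T_anl`` (0 -> 1 linearly),
   which counteracts posterior collapse; the asymptote parameters c and d
   are frozen and only the encoder, loadings and easiness move.
2. **ELBO converging** — plain ELBO ascent until the mean objective over
   consecutive non-overlapping 100-step windows stops improving on its
   running best for ``patience`` windows.
3. **IW-ELBO converging** — importance-weighted objective with R importance
   samples, DReG gradients for the encoder, same windowed stopping rule
   with a fresh monitor.

All parameters are updated by plain stochastic gradient ascent with fixed
step sizes (no clipping, no adaptivity); the asymptotes get a smaller step
size because their effective range is narrow.  A fit is *successful* when
both converging stages stop via the windowed rule rather than by running
into the global iteration cap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .encoder import EncoderGradients, EncoderState, encode, init_encoder
from .model import ItemParameters, P_CLAMP, ResponseData, _as_model, irf, unconstrain
from .objectives import elbo_step, iw_elbo_step

logger = logging.getLogger(__name__)

STAGES = ("anneal", "elbo", "iw_elbo")


def anneal_weight(t: int, t_anl: int) -> float:
    """Linear KL annealing weight min(1, t / T_anl) at step t >= 1."""
    if t < 1:
        raise ValueError("step index starts at 1")
    return min(1.0, t / t_anl)


class ConvergenceMonitor:
    """Windowed stopping rule: the objective 'stops increasing' L times.

    Each non-overlapping window's mean objective is compared with the
    running best (or, optionally, the previous window); a window that does
    not strictly exceed the reference increments a patience counter, an
    improving window resets it and updates the reference.  The rule fires
    when the counter reaches ``patience``.
    """

    def __init__(self, patience: int, compare_to: str = "best") -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        if compare_to not in ("best", "previous"):
            raise ValueError("compare_to must be 'best' or 'previous'")
        self.patience = patience
        self.compare_to = compare_to
        self.best_: float | None = None
        self.counter_ = 0
        self.converged_ = False

    def update(self, window_mean: float) -> bool:
        ref = self.best_
        improved = ref is not None and window_mean > ref
        if self.compare_to == "previous":
            self.best_ = window_mean
        elif ref is None or window_mean > ref:
            self.best_ = window_mean
        if improved:
            self.counter_ = 0
        else:
            self.counter_ += 1
        if self.counter_ >= self.patience:
            self.converged_ = True
        return self.converged_


def _check_finite_grads(enc_grads: EncoderGradients, param_grads: dict, where: str):
    for g in (*enc_grads.weights, *enc_grads.biases, enc_grads.w_mu,
              enc_grads.b_mu, enc_grads.w_logvar, enc_grads.b_logvar):
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite encoder gradient at {where}")
    for name, g in param_grads.items():
        if g is not None and not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for {name} at {where}")


def sgd_step(
    state: EncoderState,
    params: ItemParameters,
    enc_grads: EncoderGradients,
    param_grads: dict,
    lr_main: float,
    lr_asymptote: float,
    update_asymptotes: bool = True,
) -> None:
    """One fixed-step gradient *ascent* update, in place.

    Encoder weights, loadings and easiness use ``lr_main``; the logit-scale
    asymptotes use ``lr_asymptote`` and are skipped entirely during the
    annealing stage (``update_asymptotes=False``).
    """
    for w, g in zip(state.weights, enc_grads.weights):
        w += lr_main * g
    for b, g in zip(state.biases, enc_grads.biases):
        b += lr_main * g
    state.w_mu += lr_main * enc_grads.w_mu
    state.b_mu += lr_main * enc_grads.b_mu
    state.w_logvar += lr_main * enc_grads.w_logvar
    state.b_logvar += lr_main * enc_grads.b_logvar
    params.loadings += lr_main * param_grads["loadings"]
    params.intercepts += lr_main * param_grads["intercepts"]
    if update_asymptotes:
        if params.guessing_raw is not None and param_grads["guessing_raw"] is not None:
            params.guessing_raw += lr_asymptote * param_grads["guessing_raw"]
        if params.upper_raw is not None and param_grads["upper_raw"] is not None:
            params.upper_raw += lr_asymptote * param_grads["upper_raw"]


def init_item_parameters(
    n_items: int, n_factors: int, model: str, rng: np.random.Generator
) -> ItemParameters:
    """Random starting values for exploratory fitting.

    Loadings start at small Gaussian noise (no support is assumed), b at 0,
    and the asymptotes at the means of their generative priors
    (c = 0.1, d = 0.9) on the logit scale.
    """
    model = _as_model(model)
    loadings = 0.1 * rng.standard_normal((n_items, n_factors))
    intercepts = np.zeros(n_items)
    guessing_raw = upper_raw = None
    if model in ("3pl", "4pl"):
        guessing_raw = np.full(n_items, unconstrain(np.asarray(0.1)))
    if model == "4pl":
        upper_raw = np.full(n_items, unconstrain(np.asarray(0.9)))
    return ItemParameters(loadings, intercepts, guessing_raw, upper_raw, model)


@dataclass
class FitTrace:
    """Per-window mean objective and iteration counts, by stage."""

    windows: dict = field(default_factory=lambda: {s: [] for s in STAGES})
    n_iter: dict = field(default_factory=lambda: {s: 0 for s in STAGES})
    converged: dict = field(default_factory=lambda: {"elbo": False, "iw_elbo": False})


class MIRTVAE(BaseEstimator, TransformerMixin):
    """Importance-weighted VAE estimator of multidimensional logistic IRT.

    Fits an exploratory M2PL, M3PL or M4PL model to a binary response
    matrix by amortized variational inference: a Tanh MLP encoder maps each
    (zero-filled) response vector to a diagonal Gaussian posterior over the
    K latent abilities, and the decoder is the item response function.
    Missing responses are encoded as ``NaN`` in the input matrix and
    handled by a masked likelihood; missingness is assumed random.

    Parameters
    ----------
    n_factors : int, default=1
        Latent dimension K.
    model : {"2pl", "3pl", "4pl"}, default="2pl"
        Model flavor; "3pl" frees the lower (guessing) asymptote, "4pl"
        additionally frees the upper (slipping) asymptote.
    hidden_sizes : tuple of int, default=(130, 65)
        Widths of the encoder's hidden Tanh layers.
    batch_size : int, default=16
        Minibatch size; persons are drawn uniformly with replacement.
    n_mc_samples : int, default=1
        Monte Carlo samples S per person per step.
    n_iw_samples : int, default=5
        Importance samples R in the final IW-ELBO stage.
    learning_rate : float, default=0.01
        Fixed ascent step for encoder weights, loadings and easiness.
    asymptote_learning_rate : float, default=0.001
        Smaller fixed step for the logit-scale asymptotes c and d.
    max_iter : int, default=200000
        Global cap on gradient steps across all three stages.
    anneal_fraction : float, default=0.01
        The annealing stage runs ceil(anneal_fraction * max_iter) steps.
    window : int, default=100
        Steps per convergence window.
    patience : int, default=50
        Number of non-improving windows that triggers convergence.
    compare_to : {"best", "previous"}, default="best"
        Reference for "non-improving" windows.
    decision_threshold : float, default=0.5
        Probability cut used by :meth:`predict`.
    random_state : int, Generator or None
        Seed for minibatch draws, initialization and reparameterization
        noise; a fixed int makes the fit fully reproducible.

    Attributes
    ----------
    loadings_ : ndarray of shape (J, K)
    intercepts_ : ndarray of shape (J,)
        Easiness parameters b.
    guessing_ : ndarray of shape (J,)
        Lower asymptotes c (zeros for 2PL).
    upper_asymptote_ : ndarray of shape (J,)
        Upper asymptotes d (ones for 2PL/3PL).
    item_parameters_ : ItemParameters
    encoder_ : EncoderState
    trace_ : FitTrace
        Windowed objective trajectory and per-stage iteration counts.
    success_ : bool
        True iff both converging stages stopped via the windowed rule.
    """

    def __init__(
        self,
        n_factors: int = 1,
        model: str = "2pl",
        hidden_sizes: tuple[int, ...] = (130, 65),
        batch_size: int = 16,
        n_mc_samples: int = 1,
        n_iw_samples: int = 5,
        learning_rate: float = 0.01,
        asymptote_learning_rate: float = 0.001,
        max_iter: int = 200_000,
        anneal_fraction: float = 0.01,
        window: int = 100,
        patience: int = 50,
        compare_to: str = "best",
        decision_threshold: float = 0.5,
        random_state=None,
    ):
        self.n_factors = n_factors
        self.model = model
        self.hidden_sizes = hidden_sizes
        self.batch_size = batch_size
        self.n_mc_samples = n_mc_samples
        self.n_iw_samples = n_iw_samples
        self.learning_rate = learning_rate
        self.asymptote_learning_rate = asymptote_learning_rate
        self.max_iter = max_iter
        self.anneal_fraction = anneal_fraction
        self.window = window
        self.patience = patience
        self.compare_to = compare_to
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    # -- data plumbing ----------------------------------------------------

    def _rng(self) -> np.random.Generator:
        if isinstance(self.random_state, np.random.Generator):
            return self.random_state
        return np.random.default_rng(self.random_state)

    @staticmethod
    def _split(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d (persons x items) array")
        mask = np.isfinite(X).astype(float)
        y = np.nan_to_num(X, nan=0.0) * mask
        observed = X[mask == 1.0]
        if observed.size and not np.isin(np.unique(observed), (0.0, 1.0)).all():
            raise ValueError("observed responses must be 0/1 (NaN marks missing)")
        if np.any(mask.sum(axis=1) < 1):
            raise ValueError("every person must have at least one observed response")
        return y, mask

    def _validate_fit_input(self, X):
        y, mask = self._split(X)
        for j in range(y.shape[1]):
            col = y[mask[:, j] == 1.0, j]
            if col.size and (col == col[0]).all() and mask[:, j].all():
                logger.warning(
                    "item %d is constant (%g) and fully observed; its "
                    "parameters are weakly identified", j, col[0])
        return y, mask

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None, mask=None):
        """Fit the model.

        ``X`` is the (persons x items) binary matrix with ``NaN`` at
        unobserved cells; alternatively pass a {0,1} matrix plus an
        explicit ``mask``.
        """
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if mask is not None:
            X = np.where(np.asarray(mask, dtype=bool), np.asarray(X, dtype=float), np.nan)
        resp, obs = self._validate_fit_input(X)
        n, j = resp.shape
        rng = self._rng()

        state = init_encoder(j, self.n_factors, tuple(self.hidden_sizes), rng)
        params = init_item_parameters(j, self.n_factors, self.model, rng)

        t_anl = math.ceil(self.anneal_fraction * self.max_iter)
        trace = FitTrace()
        t = 0

        def draw():
            idx = rng.integers(0, n, self.batch_size)
            return resp[idx], obs[idx]

        # stage 1: KL annealing, asymptotes frozen
        acc = []
        for step in range(1, t_anl + 1):
            t += 1
            yb, mb = draw()
            value, eg, pg = elbo_step(
                yb, mb, state, params, self.n_mc_samples,
                anneal_weight(step, t_anl), rng)
            _check_finite_grads(eg, pg, f"anneal step {step}")
            sgd_step(state, params, eg, pg, self.learning_rate,
                     self.asymptote_learning_rate, update_asymptotes=False)
            acc.append(value)
            if len(acc) == self.window:
                trace.windows["anneal"].append(float(np.mean(acc)))
                logger.info("stage=anneal window=%d mean=%.4f patience=-",
                            len(trace.windows["anneal"]), trace.windows["anneal"][-1])
                acc = []
        trace.n_iter["anneal"] = t_anl

        # stages 2 and 3: windowed convergence on the stage's own objective
        for stage in ("elbo", "iw_elbo"):
            monitor = ConvergenceMonitor(self.patience, self.compare_to)
            acc = []
            start = t
            while t < self.max_iter and not monitor.converged_:
                t += 1
                yb, mb = draw()
                if stage == "elbo":
                    value, eg, pg = elbo_step(
                        yb, mb, state, params, self.n_mc_samples, 1.0, rng)
                else:
                    value, eg, pg = iw_elbo_step(
                        yb, mb, state, params, self.n_mc_samples,
                        self.n_iw_samples, rng)
                _check_finite_grads(eg, pg, f"{stage} step {t}")
                sgd_step(state, params, eg, pg, self.learning_rate,
                         self.asymptote_learning_rate)
                acc.append(value)
                if len(acc) == self.window:
                    m = float(np.mean(acc))
                    acc = []
                    monitor.update(m)
                    trace.windows[stage].append(m)
                    logger.info("stage=%s window=%d mean=%.4f patience=%d",
                                stage, len(trace.windows[stage]), m, monitor.counter_)
            trace.n_iter[stage] = t - start
            trace.converged[stage] = monitor.converged_

        self.item_parameters_ = params
        self.encoder_ = state
        self.loadings_ = params.loadings
        self.intercepts_ = params.intercepts
        self.guessing_ = params.guessing
        self.upper_asymptote_ = params.upper
        self.trace_ = trace
        self.n_iter_ = t
        self.n_iter_per_stage_ = dict(trace.n_iter)
        self.success_ = trace.converged["elbo"] and trace.converged["iw_elbo"]
        self.n_features_in_ = j
        return self

    # -- inference on fitted models --------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "encoder_"):
            raise NotFittedError("this MIRTVAE instance is not fitted yet")

    def encode_posterior(self, X):
        """Variational posterior (mu, logvar) for each row of X."""
        self._check_fitted()
        y, mask = self._split(X)
        return encode(y * mask, self.encoder_)

    def transform(self, X):
        """Posterior mean ability estimates, shape (N, K)."""
        mu, _ = self.encode_posterior(X)
        return mu

    def predict_proba(self, X):
        """IRF probabilities at the posterior mean abilities, shape (N, J)."""
        return irf(self.transform(X), self.item_parameters_)

    def predict(self, X):
        """Thresholded model-based responses in {0, 1}."""
        return (self.predict_proba(X) >= self.decision_threshold).astype(int)

    def score(self, X, y=None):
        """Mean per-observed-cell Bernoulli log-likelihood at posterior means."""
        yv, mask = self._split(X)
        p = np.clip(self.predict_proba(X), P_CLAMP, 1.0 - P_CLAMP)
        cell = mask * (yv * np.log(p) + (1.0 - yv) * np.log1p(-p))
        return float(cell.sum() / mask.sum())


def fit_mirt_vae(data: ResponseData, model: str, n_factors: int, **kwargs) -> MIRTVAE:
    """Functional wrapper: fit a :class:`MIRTVAE` to a :class:`ResponseData`."""
    est = MIRTVAE(n_factors=n_factors, model=model, **kwargs)
    X = np.where(data.mask == 1.0, data.y, np.nan)
    return est.fit(X)
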