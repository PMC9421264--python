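"""Amortized inference network (encoder) and its hand-rolled backward pass.

The encoder is a Tanh multilayer perceptron mapping a zero-filled response
vector to the mean and log-variance of a diagonal-Gaussian variational
posterior q(theta | y) = N(mu, diag(sigma^2)):

    h   = Tanh(b_L + W_L Tanh(... Tanh(b_1 + W_1 y)))
    mu  = W_mu h + b_mu
    log sigma^2 = W_lv h + b_lv

Because every unit computes a nonlinearity of a *linear* combination of its
inputs, zero-filled missing entries contribute nothing, which is what makes
the input-dropout treatment of missing-at-random data work.

No autodiff framework is used: :func:`encoder_backward` implements the
reverse pass explicitly and is verified against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "EncoderState",
    "EncoderGradients",
    "init_encoder",
    "encode",
    "encoder_forward",
    "encoder_backward",
    "reparameterize",
    "analytic_kl",
    "diag_normal_logpdf",
]


@dataclass
class EncoderState:
    """Weights of the Tanh MLP and its two linear output heads."""

    weights: list[np.ndarray]     # W_l of shape (width_l, width_{l-1})
    biases: list[np.ndarray]      # b_l of shape (width_l,)
    w_mu: np.ndarray              # (K, width_L)
    b_mu: np.ndarray              # (K,)
    w_logvar: np.ndarray          # (K, width_L)
    b_logvar: np.ndarray          # (K,)

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_factors(self) -> int:
        return self.w_mu.shape[0]

    def copy(self) -> "EncoderState":
        return EncoderState(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            w_mu=self.w_mu.copy(),
            b_mu=self.b_mu.copy(),
            w_logvar=self.w_logvar.copy(),
            b_logvar=self.b_logvar.copy(),
        )


# gradients share the container layout of the state itself
EncoderGradients = EncoderState


def init_encoder(
    n_inputs: int,
    n_factors: int,
    hidden_sizes: tuple[int, ...],
    rng: np.random.Generator,
) -> EncoderState:
    """Glorot-style symmetric-uniform initialization.

    The log-variance head starts at zero weights and zero bias so the
    initial posterior has unit variance, i.e. training starts at the prior
    scale.
    """
    if not hidden_sizes:
        raise ValueError("hidden_sizes must be nonempty")
    widths = [n_inputs, *hidden_sizes]
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    limit = np.sqrt(6.0 / (widths[-1] + n_factors))
    w_mu = rng.uniform(-limit, limit, size=(n_factors, widths[-1]))
    return EncoderState(
        weights=weights,
        biases=biases,
        w_mu=w_mu,
        b_mu=np.zeros(n_factors),
        w_logvar=np.zeros((n_factors, widths[-1])),
        b_logvar=np.zeros(n_factors),
    )


def encoder_forward(x: np.ndarray, state: EncoderState):
    """Forward pass keeping hidden activations for the backward pass.

    Returns ``(mu, logvar, hidden)`` where ``hidden`` is the list of layer
    activations ``[x, h_1, ..., h_L]``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != state.n_inputs:
        raise ValueError(
            f"encoder expects input width {state.n_inputs}, got shape {x.shape}"
        )
    hidden = [x]
    h = x
    for w, b in zip(state.weights, state.biases):
        h = np.tanh(h @ w.T + b)
        hidden.append(h)
    mu = h @ state.w_mu.T + state.b_mu
    logvar = h @ state.w_logvar.T + state.b_logvar
    return mu, logvar, hidden


def encode(x: np.ndarray, state: EncoderState):
    """Variational posterior parameters ``(mu, logvar)`` for each row of x."""
    mu, logvar, _ = encoder_forward(x, state)
    return mu, logvar


def encoder_backward(
    state: EncoderState,
    hidden: list[np.ndarray],
    g_mu: np.ndarray,
    g_logvar: np.ndarray,
) -> EncoderGradients:
    """Backpropagate head gradients to all encoder weights.

    ``g_mu`` and ``g_logvar`` are the gradients of the objective with
    respect to the head outputs, shape (B, K); the returned structure holds
    the gradient with respect to every weight and bias.
    """
    h_last = hidden[-1]
    gw_mu = g_mu.T @ h_last
    gb_mu = g_mu.sum(axis=0)
    gw_lv = g_logvar.T @ h_last
    gb_lv = g_logvar.sum(axis=0)
    g_h = g_mu @ state.w_mu + g_logvar @ state.w_logvar
    g_weights: list[np.ndarray] = [None] * len(state.weights)  # type: ignore
    g_biases: list[np.ndarray] = [None] * len(state.biases)  # type: ignore
    for l in range(len(state.weights) - 1, -1, -1):
        g_z = g_h * (1.0 - hidden[l + 1] ** 2)  # tanh'
        g_weights[l] = g_z.T @ hidden[l]
        g_biases[l] = g_z.sum(axis=0)
        if l > 0:
            g_h = g_z @ state.weights[l]
    return EncoderGradients(
        weights=g_weights,
        biases=g_biases,
        w_mu=gw_mu,
        b_mu=gb_mu,
        w_logvar=gw_lv,
        b_logvar=gb_lv,
    )


def reparameterize(
    mu: np.ndarray,
    logvar: np.ndarray,
    n_mc: int,
    n_iw: int,
    rng: np.random.Generator,
):
    """Draw ``theta = mu + sigma * e`` with ``e ~ N(0, I)``.

    Returns ``(theta, e)`` of shape (B, S, R, K), where S is the number of
    Monte Carlo samples and R the number of importance samples.  Returning
    the raw noise ``e`` keeps the pathwise dependence on (mu, sigma)
    explicit for gradient computations.
    """
    b, k = mu.shape
    e = rng.standard_normal((b, n_mc, n_iw, k))
    sigma = np.exp(0.5 * logvar)
    theta = mu[:, None, None, :] + sigma[:, None, None, :] * e
    return theta, e


def analytic_kl(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """KL( N(mu, diag(sigma^2)) || N(0, I) ) per row.

    0.5 * sum_k (mu_k^2 + sigma_k^2 - 1 - log sigma_k^2); nonnegative and
    zero exactly at the prior.
    """
    var = np.exp(logvar)
    return 0.5 * np.sum(mu * mu + var - 1.0 - logvar, axis=-1)


def diag_normal_logpdf(theta: np.ndarray, mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Log density of a diagonal Gaussian, broadcasting sample axes.

    ``theta`` has shape (B, ..., K); ``mu``/``logvar`` have shape (B, K).
    """
    extra = theta.ndim - 2
    shape = (mu.shape[0], *([1] * extra), mu.shape[1])
    mu_b = mu.reshape(shape)
    lv_b = logvar.reshape(shape)
    z2 = (theta - mu_b) ** 2 * np.exp(-lv_b)
    return -0.5 * np.sum(np.log(2.0 * np.pi) + lv_b + z2, axis=-1)
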