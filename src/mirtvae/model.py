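"""Measurement (decoder) side of the multidimensional logistic IRT model.

The package fits multidimensional 2-, 3- and 4-parameter logistic models
(M2PL/M3PL/M4PL) for binary responses.  Person ``i`` has a latent ability
vector ``theta_i`` in R^K with a standard-normal prior, and the probability
of a correct response to item ``j`` is the item response function

    P(Y_ij = 1 | theta_i) = c_j + (d_j - c_j) * sigmoid(a_j' theta_i + b_j)

with loadings (discriminations) ``a_j``, easiness ``b_j``, lower asymptote
(guessing) ``c_j`` and upper asymptote ``d_j`` (1 - d_j is the slipping
probability).  M3PL fixes ``d_j = 1``; M2PL additionally fixes ``c_j = 0``.

Asymptotes live on the logit scale internally so that gradient ascent is
unconstrained; :func:`constrain` / :func:`unconstrain` convert between the
two scales.  The likelihood is a masked Bernoulli likelihood: unobserved
cells are multiplied by an observation indicator and contribute exactly
zero regardless of the placeholder value stored there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

MODELS = ("2pl", "3pl", "4pl")

#: probabilities are clamped to [P_CLAMP, 1 - P_CLAMP] before logs so the
#: likelihood stays finite when c -> 0 or d -> 1
P_CLAMP = 1e-7

#: asymptotes this close to 0/1 are clamped before the logit transform
ASYMPTOTE_CLAMP = 1e-12


def _as_model(model: str) -> str:
    m = str(model).lower().lstrip("m")
    if m not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return m


def constrain(raw: np.ndarray) -> np.ndarray:
    """Map unconstrained logit-scale asymptotes to (0, 1)."""
    return expit(raw)


def unconstrain(p: np.ndarray) -> np.ndarray:
    """Map (0, 1) asymptotes to the unconstrained logit scale.

    Values at exactly 0 or 1 are clamped inward with a warning; the
    transform has no finite image there.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        warnings.warn(
            "asymptote values at or beyond {0, 1} clamped before logit",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.clip(p, ASYMPTOTE_CLAMP, 1.0 - ASYMPTOTE_CLAMP)
    return np.log(p) - np.log1p(-p)


@dataclass
class ItemParameters:
    """Item parameters of an M2PL/M3PL/M4PL model.

    ``guessing_raw`` / ``upper_raw`` are on the logit scale and are ``None``
    when the model flavor fixes the corresponding asymptote (c = 0 for 2PL,
    d = 1 for 2PL/3PL).
    """

    loadings: np.ndarray        # (J, K)
    intercepts: np.ndarray      # (J,) easiness b
    guessing_raw: np.ndarray | None = None
    upper_raw: np.ndarray | None = None
    model: str = "2pl"

    def __post_init__(self) -> None:
        self.model = _as_model(self.model)
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.intercepts.shape != (self.n_items,):
            raise ValueError("intercepts must have one entry per item")
        if self.model == "2pl":
            self.guessing_raw = None
            self.upper_raw = None
        elif self.model == "3pl":
            self.upper_raw = None
            if self.guessing_raw is None:
                raise ValueError("3pl requires guessing_raw")
        else:
            if self.guessing_raw is None or self.upper_raw is None:
                raise ValueError("4pl requires guessing_raw and upper_raw")
        for name in ("guessing_raw", "upper_raw"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (self.n_items,):
                    raise ValueError(f"{name} must have one entry per item")
                setattr(self, name, v)

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def guessing(self) -> np.ndarray:
        """Lower asymptote c on the probability scale."""
        if self.guessing_raw is None:
            return np.zeros(self.n_items)
        return constrain(self.guessing_raw)

    @property
    def upper(self) -> np.ndarray:
        """Upper asymptote d on the probability scale."""
        if self.upper_raw is None:
            return np.ones(self.n_items)
        return constrain(self.upper_raw)

    def copy(self) -> "ItemParameters":
        return ItemParameters(
            loadings=self.loadings.copy(),
            intercepts=self.intercepts.copy(),
            guessing_raw=None if self.guessing_raw is None else self.guessing_raw.copy(),
            upper_raw=None if self.upper_raw is None else self.upper_raw.copy(),
            model=self.model,
        )


@dataclass
class ResponseData:
    """Binary response matrix with an observation-indicator mask.

    ``y`` holds {0, 1} at observed cells and an arbitrary placeholder
    (0 by convention, set on ingest) at unobserved cells; ``mask`` is 1
    where observed.  Every row must have at least one observed entry.
    """

    y: np.ndarray               # (N, J)
    mask: np.ndarray            # (N, J) in {0, 1}
    person_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.mask = np.asarray(self.mask, dtype=float)
        if self.y.shape != self.mask.shape or self.y.ndim != 2:
            raise ValueError("y and mask must be equal-shape 2-d arrays")
        if not np.isin(np.unique(self.mask), (0.0, 1.0)).all():
            raise ValueError("mask must be binary")
        obs = self.y[self.mask == 1.0]
        if obs.size and not np.isin(np.unique(obs), (0.0, 1.0)).all():
            raise ValueError("observed responses must be binary")
        rows = self.mask.sum(axis=1)
        if np.any(rows < 1):
            bad = int(np.argmin(rows))
            raise ValueError(f"row {bad} has no observed responses")
        if not self.person_ids:
            self.person_ids = [f"p{i}" for i in range(self.n_persons)]
        if not self.item_ids:
            self.item_ids = [f"item{j}" for j in range(self.n_items)]
        # zero-fill placeholders so encoders can consume y directly
        self.y = self.y * self.mask

    @property
    def n_persons(self) -> int:
        return self.y.shape[0]

    @property
    def n_items(self) -> int:
        return self.y.shape[1]


def irf(theta: np.ndarray, params: ItemParameters) -> np.ndarray:
    """Item response probabilities ``c + (d - c) * sigmoid(A theta + b)``.

    Parameters
    ----------
    theta : array of shape (..., K)
    params : ItemParameters

    Returns
    -------
    array of shape (..., J) with values in [min(c, d), max(c, d)].
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise FloatingPointError("non-finite theta passed to irf")
    z = theta @ params.loadings.T + params.intercepts
    s = expit(z)
    c = params.guessing
    d = params.upper
    return c + (d - c) * s


def log_prior(theta: np.ndarray) -> np.ndarray:
    """Log density of the standard K-variate normal prior at theta (..., K)."""
    theta = np.asarray(theta, dtype=float)
    k = theta.shape[-1]
    return -0.5 * (k * np.log(2.0 * np.pi) + np.sum(theta * theta, axis=-1))


def masked_loglik(
    y: np.ndarray,
    mask: np.ndarray,
    theta: np.ndarray,
    params: ItemParameters,
) -> np.ndarray:
    """Masked Bernoulli log-likelihood, summed over items.

    ``y`` and ``mask`` have shape (B, J); ``theta`` has shape (B, ..., K)
    with any number of sample axes between the person axis and K.  Returns
    shape (B, ...).  Cells with mask 0 contribute exactly zero, so the
    placeholder stored at missing cells is irrelevant.  Probabilities are
    clamped to ``[P_CLAMP, 1 - P_CLAMP]`` before logs.
    """
    p = irf(theta, params)
    p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    extra = p.ndim - 2
    yb = y.reshape(y.shape[0], *([1] * extra), y.shape[1])
    mb = mask.reshape(mask.shape[0], *([1] * extra), mask.shape[1])
    cell = mb * (yb * np.log(p) + (1.0 - yb) * np.log1p(-p))
    return cell.sum(axis=-1)
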