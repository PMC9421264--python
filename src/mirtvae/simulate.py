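"""Synthetic data with the structure of the simulation study.

Datasets are generated from an s-shaped sparse loading matrix: a blocked
diagonal seed block is flipped left-right and stacked repeatedly until J
rows exist (truncating at the bottom), so item-factor dependencies are
distributed evenly across factors.  *Between-item* multidimensionality
loads each item on exactly one factor, *within-item* on two (the block
factor and the cyclically next one).

Free discriminations are Uniform(0.5, 1.5); easiness is standard normal;
guessing and slipping asymptotes are c ~ Beta(1, 9) and d ~ Beta(9, 1),
redrawn jointly until every pair satisfies c_j < d_j.  Abilities are
unit-variance Gaussians, either independent or with Uniform(0, 1)
correlations (redrawn until positive semi-definite).  Finally a fixed
fraction of each person's responses (80% by default) is masked uniformly
at random, with an exact per-row count so every person answers the same
number of items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ItemParameters, ResponseData, _as_model, irf, unconstrain

ITEM_STRUCTURES = ("between", "within")
FACTOR_MODES = ("independent", "correlated")

#: redraw caps for the rejection loops
MAX_REDRAWS = 10_000

#: smallest acceptable eigenvalue for a simulated factor covariance
PSD_TOL = 1e-10


class GenerationError(RuntimeError):
    """A rejection-sampling loop exceeded its redraw cap."""


@dataclass
class SimulationConfig:
    """Configuration of one simulated dataset."""

    n_persons: int
    n_items: int
    n_factors: int
    item_structure: str = "between"
    factor_mode: str = "independent"
    missing_proportion: float = 0.8
    model: str = "4pl"
    seed: int = 0
    block_rows: int | None = None   # rows per factor in the seed block; default J/(2K)

    def __post_init__(self) -> None:
        self.model = _as_model(self.model)
        if self.item_structure not in ITEM_STRUCTURES:
            raise ValueError(f"item_structure must be one of {ITEM_STRUCTURES}")
        if self.factor_mode not in FACTOR_MODES:
            raise ValueError(f"factor_mode must be one of {FACTOR_MODES}")
        if self.n_persons < 1 or self.n_factors < 1 or self.n_items < self.n_factors:
            raise ValueError("need N >= 1 and J >= K >= 1")
        if not 0.0 <= self.missing_proportion < 1.0:
            raise ValueError("missing_proportion must lie in [0, 1)")
        if self.item_structure == "within" and self.n_factors < 2:
            raise ValueError("within-item structure requires K >= 2")


@dataclass
class GroundTruth:
    """Generating parameters of a simulated dataset."""

    params: ItemParameters
    theta: np.ndarray       # (N, K)
    sigma: np.ndarray       # (K, K) factor covariance (unit diagonal)
    pattern: np.ndarray     # (J, K) binary support of the loadings


def build_loading_pattern(
    n_items: int,
    n_factors: int,
    structure: str = "between",
    block_rows: int | None = None,
) -> np.ndarray:
    """Binary support of the s-shaped sparse loading matrix.

    A seed block with ``block_rows`` consecutive rows per factor (default
    ``max(1, round(J / 2K))`` so at least one flip occurs) is alternately
    flipped left-right and stacked until J rows accumulate, then truncated.
    Between-item rows have one nonzero; within-item rows additionally load
    the cyclically next factor.
    """
    if structure not in ITEM_STRUCTURES:
        raise ValueError(f"structure must be one of {ITEM_STRUCTURES}")
    if n_items < n_factors or n_factors < 1:
        raise ValueError("need J >= K >= 1")
    if structure == "within" and n_factors < 2:
        raise ValueError("within-item structure requires K >= 2")
    m = block_rows if block_rows is not None else max(1, round(n_items / (2 * n_factors)))
    if m < 1:
        raise ValueError("block_rows must be >= 1")
    seed = np.zeros((m * n_factors, n_factors))
    for k in range(n_factors):
        seed[k * m:(k + 1) * m, k] = 1.0
        if structure == "within":
            seed[k * m:(k + 1) * m, (k + 1) % n_factors] = 1.0
    blocks = [seed]
    current = seed
    while sum(b.shape[0] for b in blocks) < n_items:
        current = current[:, ::-1]          # flip left-right
        blocks.append(current)
    return np.vstack(blocks)[:n_items]


def sample_item_parameters(
    pattern: np.ndarray,
    model: str,
    rng: np.random.Generator,
    easiness_scale: float = 1.0,
) -> ItemParameters:
    """Draw item parameters on a given loading support.

    Free loadings are Uniform(0.5, 1.5), structural zeros stay exact
    zeros; b ~ Normal(0, easiness_scale^2).  For 4PL, (c, d) are drawn as
    whole vectors from Beta(1, 9) / Beta(9, 1) and the draw is rejected
    until all pairs satisfy c_j < d_j.
    """
    model = _as_model(model)
    pattern = np.asarray(pattern, dtype=float)
    n_items = pattern.shape[0]
    loadings = pattern * rng.uniform(0.5, 1.5, size=pattern.shape)
    intercepts = easiness_scale * rng.standard_normal(n_items)
    guessing_raw = upper_raw = None
    if model == "3pl":
        guessing_raw = unconstrain(rng.beta(1.0, 9.0, size=n_items))
    elif model == "4pl":
        for _ in range(MAX_REDRAWS):
            c = rng.beta(1.0, 9.0, size=n_items)
            d = rng.beta(9.0, 1.0, size=n_items)
            if np.all(c < d):
                break
        else:
            raise GenerationError("c < d rejection loop exceeded its cap")
        guessing_raw = unconstrain(c)
        upper_raw = unconstrain(d)
    return ItemParameters(loadings, intercepts, guessing_raw, upper_raw, model)


def sample_factor_covariance(
    n_factors: int, mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Unit-diagonal factor covariance.

    ``independent`` gives the identity; ``correlated`` fills the
    off-diagonal with iid Uniform(0, 1) values, redrawing until the matrix
    is positive semi-definite (smallest eigenvalue >= -1e-10).
    """
    if mode not in FACTOR_MODES:
        raise ValueError(f"mode must be one of {FACTOR_MODES}")
    if n_factors < 1:
        raise ValueError("need K >= 1")
    if mode == "independent" or n_factors == 1:
        return np.eye(n_factors)
    for _ in range(MAX_REDRAWS):
        sigma = np.eye(n_factors)
        iu = np.triu_indices(n_factors, k=1)
        vals = rng.uniform(0.0, 1.0, size=len(iu[0]))
        sigma[iu] = vals
        sigma[(iu[1], iu[0])] = vals
        if np.linalg.eigvalsh(sigma).min() >= -PSD_TOL:
            return sigma
    raise GenerationError("PSD rejection loop exceeded its cap")


def sample_responses(
    theta: np.ndarray, params: ItemParameters, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli responses from the IRF under local independence."""
    p = irf(theta, params)
    return (rng.random(p.shape) < p).astype(float)


def apply_missingness(
    y: np.ndarray, proportion: float, rng: np.random.Generator
) -> ResponseData:
    """Mask exactly round(proportion * J) uniformly chosen cells per row.

    Exact per-row counts (rather than iid Bernoulli masking) make every
    person answer the same number of items and keep test assertions
    deterministic.
    """
    if not 0.0 <= proportion < 1.0:
        raise ValueError("proportion must lie in [0, 1)")
    n, j = y.shape
    n_missing = round(proportion * j)
    if n_missing >= j:
        n_missing = j - 1
    mask = np.ones((n, j))
    for i in range(n):
        mask[i, rng.permutation(j)[:n_missing]] = 0.0
    return ResponseData(y=y * mask, mask=mask)


def generate_dataset(cfg: SimulationConfig) -> tuple[ResponseData, GroundTruth]:
    """Full generation recipe: pattern, parameters, abilities, responses, mask.

    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    pattern = build_loading_pattern(
        cfg.n_items, cfg.n_factors, cfg.item_structure, cfg.block_rows)
    params = sample_item_parameters(pattern, cfg.model, rng)
    sigma = sample_factor_covariance(cfg.n_factors, cfg.factor_mode, rng)
    if cfg.factor_mode == "independent":
        theta = rng.standard_normal((cfg.n_persons, cfg.n_factors))
    else:
        theta = rng.multivariate_normal(
            np.zeros(cfg.n_factors), sigma, size=cfg.n_persons, method="eigh")
    y = sample_responses(theta, params, rng)
    data = apply_missingness(y, cfg.missing_proportion, rng)
    truth = GroundTruth(params=params, theta=theta, sigma=sigma, pattern=pattern)
    return data, truth
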