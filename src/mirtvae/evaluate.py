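"""Replication-level evaluation: RMSE blocks, success rate, held-out prediction.

The simulation protocol fits the same dataset B times with different
training seeds.  For every scalar parameter xi the root mean squared error
across replications is

    RMSE(xi_hat) = sqrt( (1/B) sum_b (xi_hat_b - xi)^2 )

and reported blocks are the averages of these per-parameter RMSEs over the
loading matrix A, and the vectors b, c, d, with the standard error of that
average taken across parameters.  Loadings are aligned to the generating
matrix by promax + sign flip + best column permutation before the
comparison; the item-indexed parameters b, c, d carry no rotational
indeterminacy and are compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimator import MIRTVAE, fit_mirt_vae
from .model import P_CLAMP, ItemParameters, ResponseData, irf
from .rotation import align_loadings
from .simulate import GroundTruth, SimulationConfig, generate_dataset

__all__ = [
    "rmse",
    "EvaluationReport",
    "evaluate_replications",
    "heldout_predict",
    "run_benchmark",
]


def rmse(estimates: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-parameter RMSE across replications.

    ``estimates`` has shape (B, ...) and ``truth`` shape (...); the result
    has the shape of ``truth``.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.shape[1:] != truth.shape:
        raise ValueError("estimates must stack replications on the first axis")
    return np.sqrt(((estimates - truth) ** 2).mean(axis=0))


@dataclass
class EvaluationReport:
    """RMSE blocks (mean, SE over parameters) and the replication success rate."""

    blocks: dict = field(default_factory=dict)  # name -> (mean, se)
    success_rate: float = 1.0
    n_replications: int = 0

    def summary(self) -> str:
        lines = [f"replications: {self.n_replications}"]
        for name, (mean, se) in self.blocks.items():
            lines.append(f"rmse[{name}]: {mean:.3f} +/- {se:.3f}")
        lines.append(f"success rate: {self.success_rate:.2f}")
        return "\n".join(lines)


def _block(values: np.ndarray) -> tuple[float, float]:
    flat = np.asarray(values, dtype=float).ravel()
    return float(flat.mean()), float(flat.std(ddof=1) / np.sqrt(flat.size))


def evaluate_replications(
    fits: list[MIRTVAE],
    truth: GroundTruth,
    power: int = 4,
) -> EvaluationReport:
    """Align each fit and assemble the RMSE report against the ground truth."""
    if not fits:
        raise ValueError("need at least one fitted replication")
    params: ItemParameters = truth.params
    aligned = np.stack([
        align_loadings(f.loadings_, params.loadings, power=power).loadings
        for f in fits
    ])
    report = EvaluationReport(n_replications=len(fits))
    report.blocks["loadings"] = _block(rmse(aligned, params.loadings))
    report.blocks["intercepts"] = _block(
        rmse(np.stack([f.intercepts_ for f in fits]), params.intercepts))
    if params.model in ("3pl", "4pl"):
        report.blocks["guessing"] = _block(
            rmse(np.stack([f.guessing_ for f in fits]), params.guessing))
    if params.model == "4pl":
        report.blocks["upper"] = _block(
            rmse(np.stack([f.upper_asymptote_ for f in fits]), params.upper))
    report.success_rate = float(np.mean([f.success_ for f in fits]))
    return report


def heldout_predict(
    data: ResponseData,
    heldout_mask: np.ndarray,
    fit: MIRTVAE,
    threshold: float = 0.5,
):
    """Accuracy and per-item log-likelihood on held-out cells.

    ``data.mask`` marks every cell carrying a true response;
    ``heldout_mask`` selects the subset hidden from the encoder, so the
    training-observed cells are ``data.mask & ~heldout_mask`` and are
    disjoint from the held-out set by construction.  The encoder sees only
    the training responses (held-out cells zero-filled); predictions are
    IRF probabilities at the posterior mean, thresholded for accuracy.

    Returns ``(accuracy, per_item_loglik, mean_loglik)`` where the
    per-item vector holds the mean Bernoulli log-likelihood over each
    item's held-out cells (NaN for items with none).
    """
    held = np.asarray(heldout_mask, dtype=float)
    if held.shape != data.y.shape:
        raise ValueError("heldout_mask must match the response matrix shape")
    if np.any(held > data.mask):
        raise ValueError("held-out cells must carry observed responses")
    if held.sum() == 0:
        raise ValueError("empty held-out set")
    train_mask = data.mask * (1.0 - held)
    train = np.where(train_mask == 1.0, data.y, np.nan)
    mu = fit.transform(train)
    p = irf(mu, fit.item_parameters_)
    pred = (p >= threshold).astype(float)
    acc = float((held * (pred == data.y)).sum() / held.sum())
    pc = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    cell = data.y * np.log(pc) + (1.0 - data.y) * np.log1p(-pc)
    counts = held.sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_item = np.where(counts > 0, (held * cell).sum(axis=0) / counts, np.nan)
    mean_ll = float((held * cell).sum() / held.sum())
    return acc, per_item, mean_ll


def run_benchmark(
    sim_cfg: SimulationConfig,
    n_replications: int,
    seed: int | None = None,
    fresh_data: bool = False,
    train_kwargs: dict | None = None,
) -> tuple[EvaluationReport, list[MIRTVAE], GroundTruth]:
    """Simulate one dataset and fit it B times with different training seeds.

    Replication b uses training seed ``seed + 1 + b``.  With
    ``fresh_data=True`` each replication also regenerates the dataset (the
    default keeps one dataset, matching the replication design of the
    simulation study).
    """
    if n_replications < 1:
        raise ValueError("need at least one replication")
    seed = sim_cfg.seed if seed is None else seed
    train_kwargs = dict(train_kwargs or {})
    data, truth = generate_dataset(sim_cfg)
    fits = []
    for b in range(n_replications):
        if fresh_data and b > 0:
            cfg_b = SimulationConfig(**{**sim_cfg.__dict__, "seed": sim_cfg.seed + b})
            data, truth = generate_dataset(cfg_b)
        fits.append(fit_mirt_vae(
            data, truth.params.model, truth.params.n_factors,
            random_state=seed + 1 + b, **train_kwargs))
    return evaluate_replications(fits, truth), fits, truth
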