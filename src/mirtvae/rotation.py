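"""Promax rotation and loading-matrix alignment.

Exploratory loadings are identified only up to rotation, sign and column
order.  Estimates are aligned to a reference in three steps: (1) promax
(varimax followed by an oblique procrustes fit to the powered varimax
target), which also yields an implied factor correlation matrix; (2) sign
flips for columns with negative sums, mirrored onto the corresponding rows
and columns of the factor correlation; (3) an exhaustive search over the
K! column permutations for the one minimizing the mean squared deviation
from the reference.

The varimax/promax procedure follows Hendrickson & White's classical
recipe; the implementation mirrors the reference algorithm used by R's
``stats::varimax``/``stats::promax`` (SVD-based varimax iteration, powered
target regression, column rescaling so the implied factor correlation has
unit diagonal) and is checked against it in the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

MAX_EXHAUSTIVE_K = 8


@dataclass
class PromaxResult:
    loadings: np.ndarray    # (J, K) oblique pattern matrix
    rotation: np.ndarray    # (K, K) total rotation from the input loadings
    phi: np.ndarray         # (K, K) implied factor correlation


@dataclass
class AlignmentResult:
    """Loadings aligned to a reference, with the transform that got there."""

    loadings: np.ndarray        # (J, K) aligned estimate
    rotation: np.ndarray        # (K, K) oblique rotation (pre sign/permutation)
    signs: np.ndarray           # (K,) +/-1 applied after rotation
    permutation: np.ndarray     # (K,) column order applied last
    phi: np.ndarray             # (K, K) factor correlation, sign/permutation adjusted


def varimax(
    loadings: np.ndarray,
    normalize: bool = False,
    eps: float = 1e-5,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation.

    Returns ``(rotated, rotmat)`` with ``rotated = loadings @ rotmat``.
    ``normalize`` applies Kaiser row normalization (as R's default does);
    it is off by default here.
    """
    x = np.asarray(loadings, dtype=float)
    p, k = x.shape
    if k < 2:
        return x.copy(), np.eye(k)
    sc = None
    if normalize:
        sc = np.sqrt((x * x).sum(axis=1))
        x = x / sc[:, None]
    rot = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        z = x @ rot
        b = x.T @ (z ** 3 - z @ np.diag((z * z).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(b)
        rot = u @ vt
        d_old, d = d, s.sum()
        if d < d_old * (1.0 + eps):
            break
    z = x @ rot
    if normalize:
        z = z * sc[:, None]
    return z, rot


def promax(
    loadings: np.ndarray,
    power: int = 4,
    normalize: bool = False,
) -> PromaxResult:
    """Oblique promax rotation.

    Varimax first, then regress the element-wise ``|z|^power * sign(z)``
    target on the varimax solution and rescale columns so the implied
    factor correlation ``phi = inv(U'U)`` has unit diagonal.  ``power`` is
    the Hendrickson-White kappa (4 by default).  K = 1 input is returned
    unchanged.
    """
    x = np.asarray(loadings, dtype=float)
    p, k = x.shape
    if k < 2:
        return PromaxResult(x.copy(), np.eye(k), np.eye(k))
    if np.linalg.matrix_rank(x) < k:
        raise np.linalg.LinAlgError(
            f"loading matrix is rank-deficient (rank < {k}); promax target "
            "regression is singular")
    z, rotmat = varimax(x, normalize=normalize)
    target = z * np.abs(z) ** (power - 1)
    u, *_ = np.linalg.lstsq(z, target, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u * np.sqrt(d)
    rotation = rotmat @ u
    phi = np.linalg.inv(u.T @ u)
    phi = 0.5 * (phi + phi.T)
    return PromaxResult(loadings=x @ rotation, rotation=rotation, phi=phi)


def sign_align(
    loadings: np.ndarray, phi: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip columns whose sum is negative; mirror the flips onto phi.

    Returns ``(flipped_loadings, adjusted_phi, signs)``.  An exactly zero
    column sum keeps its sign with a warning.  Flipping row *and* column k
    of the correlation leaves the unit diagonal untouched.
    """
    a = np.asarray(loadings, dtype=float)
    sums = a.sum(axis=0)
    if np.any(sums == 0.0):
        warnings.warn("column with exactly zero sum; sign kept", RuntimeWarning)
    signs = np.where(sums < 0.0, -1.0, 1.0)
    flipped = a * signs
    if phi is None:
        phi_adj = np.eye(a.shape[1])
    else:
        phi_adj = signs[:, None] * np.asarray(phi, dtype=float) * signs[None, :]
    return flipped, phi_adj, signs


def best_permutation(
    loadings: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive search for the column order minimizing MSE to a reference.

    Ties break lexicographically (the first minimizing permutation in
    itertools order).  Limited to K <= 8.
    """
    a = np.asarray(loadings, dtype=float)
    ref = np.asarray(reference, dtype=float)
    k = a.shape[1]
    if k > MAX_EXHAUSTIVE_K:
        raise ValueError(
            f"exhaustive permutation search is limited to K <= {MAX_EXHAUSTIVE_K}; "
            "use an assignment-based matcher for larger K")
    best = None
    best_mse = np.inf
    for perm in itertools.permutations(range(k)):
        mse = float(((a[:, perm] - ref) ** 2).mean())
        if mse < best_mse:
            best_mse = mse
            best = perm
    perm = np.asarray(best, dtype=int)
    return perm, a[:, perm]


def align_loadings(
    estimate: np.ndarray,
    reference: np.ndarray,
    power: int = 4,
    normalize: bool = False,
) -> AlignmentResult:
    """Full promax -> sign flip -> best permutation alignment pipeline."""
    pro = promax(estimate, power=power, normalize=normalize)
    flipped, phi, signs = sign_align(pro.loadings, pro.phi)
    perm, aligned = best_permutation(flipped, reference)
    phi = phi[np.ix_(perm, perm)]
    return AlignmentResult(
        loadings=aligned,
        rotation=pro.rotation,
        signs=signs,
        permutation=perm,
        phi=phi,
    )
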