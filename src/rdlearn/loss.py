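"""The representational-distance auxiliary error and its gradients.

The auxiliary error between a student layer's RDM ``D`` and a teacher target
RDM ``T`` over a batch of n inputs is the mean squared difference over the
n(n-1)/2 unordered pairs:

    E = 2/(n(n-1)) * sum_{i<j} (D_ij - T_ij)^2

Its exact derivative with respect to unit k of the student's activation for
input x_i, for the summed squared-Euclidean dissimilarity, is

    dE/df_k(x_i) = 8/(n(n-1)) * sum_{j != i} (D_ij - T_ij) (f_k(x_i) - f_k(x_j))

and an unbatched-pairs estimator replaces the full pair sum with a sampled
subset P, normalising per image by the number of sampled pairs it appears in:

    dE/df_k(x_i) ~= 8/(|X_P| |P_{x_i}|) * sum_{(i,j) in P_{x_i}} (D_ij - T_ij) (f_k(x_i) - f_k(x_j))

Images appearing in no sampled pair receive an exactly zero gradient.  For
the other dissimilarities the same chain rule is applied with the
corresponding pair partial dD_ij/df(x_i), so the returned gradient is always
the exact derivative of :func:`rdl_error` (checked against finite
differences in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .rdm import (
    RDM,
    ActivationMatrix,
    DegenerateInputError,
    _check_dissimilarity,
    compute_rdm,
)

__all__ = [
    "AlignmentError",
    "PairSet",
    "all_pairs",
    "sample_pairs",
    "rdl_error",
    "rdl_gradient_full",
    "rdl_gradient_subsampled",
    "combine_gradients",
    "AlphaSchedule",
    "alpha_at",
]


class AlignmentError(ValueError):
    """Student activations and teacher target RDM index different inputs."""


# ---------------------------------------------------------------------------
# Pair sampling

@dataclass(frozen=True)
class PairSet:
    """A subset P of ordered non-self index pairs over a batch of size n.

    ``counts[i]`` is |P_{x_i}|, the number of sampled pairs containing image
    i in either position; ``n_covered`` is |X_P|, the number of distinct
    images appearing in at least one pair.
    """

    n: int
    pairs: np.ndarray  # (m, 2) int array of ordered pairs (i, j), i != j
    counts: np.ndarray  # (n,) per-image pair membership counts
    n_covered: int

    @classmethod
    def from_pairs(cls, n: int, pairs) -> "PairSet":
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        if pairs.size and (pairs.min() < 0 or pairs.max() >= n):
            raise ValueError("pair index out of range for batch size n")
        if np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("self-pairs are not allowed")
        counts = np.zeros(n, dtype=np.intp)
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
        return cls(n=n, pairs=pairs, counts=counts, n_covered=int((counts > 0).sum()))

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


def all_pairs(n: int) -> PairSet:
    """The exhaustive PairSet of all n(n-1) ordered non-self pairs."""
    idx = np.arange(n)
    i, j = np.meshgrid(idx, idx, indexing="ij")
    mask = i != j
    return PairSet.from_pairs(n, np.column_stack([i[mask], j[mask]]))


def sample_pairs(
    n: int,
    fraction: float,
    seed: int | np.random.Generator | None = None,
    pair_count: int | None = None,
) -> PairSet:
    """Uniformly sample ordered non-self pairs without replacement.

    The number of pairs is ``round(fraction * n * (n-1))`` unless
    ``pair_count`` overrides it.  Deterministic given the seed.
    """
    if n < 2:
        raise ValueError("need a batch of at least 2 images to sample pairs")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    total = n * (n - 1)
    m = int(round(fraction * total)) if pair_count is None else int(pair_count)
    if m < 1:
        raise ValueError(
            f"fraction {fraction} of {total} ordered pairs rounds to zero pairs"
        )
    if m > total:
        raise ValueError(f"cannot sample {m} of {total} ordered pairs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = rng.choice(total, size=m, replace=False)
    i = flat // (n - 1)
    r = flat % (n - 1)
    j = np.where(r < i, r, r + 1)
    return PairSet.from_pairs(n, np.column_stack([i, j]))


# ---------------------------------------------------------------------------
# Error and gradients

def _align(acts, target: RDM, dissimilarity: str):
    if isinstance(acts, ActivationMatrix):
        if acts.input_ids != target.input_ids:
            raise AlignmentError(
                "activation input_ids do not match target RDM input_ids"
            )
        F = acts.values
    else:
        F = np.asarray(acts, dtype=float)
    if F.ndim != 2 or F.shape[0] != target.n:
        raise AlignmentError(
            f"activations ({F.shape}) do not align with target RDM (n={target.n})"
        )
    if F.shape[0] < 2:
        raise ValueError("need at least 2 inputs")
    D = compute_rdm(F, dissimilarity=dissimilarity).values
    return F, D


def rdl_error(acts, target: RDM, dissimilarity: str = "squared_euclidean_sum") -> float:
    """Mean squared difference between the student RDM and the target over
    unordered pairs: 2/(n(n-1)) * sum_{i<j} (D_ij - T_ij)^2."""
    _check_dissimilarity(dissimilarity)
    F, D = _align(acts, target, dissimilarity)
    n = F.shape[0]
    iu = np.triu_indices(n, k=1)
    diff = D[iu] - target.values[iu]
    return float(2.0 / (n * (n - 1)) * np.sum(diff**2))


def _weighted_pair_grad(F: np.ndarray, W: np.ndarray, D: np.ndarray, d: str) -> np.ndarray:
    """Rows G_i = sum_j W_ij * dD_ij/dF_i for the chosen dissimilarity.

    W must have a zero diagonal.  For the Euclidean dissimilarity the
    subgradient 0 is used at coincident points (D_ij = 0).
    """
    if d == "squared_euclidean_sum":
        return 2.0 * (W.sum(axis=1)[:, None] * F - W @ F)
    if d == "squared_euclidean_mean":
        return 2.0 / F.shape[1] * (W.sum(axis=1)[:, None] * F - W @ F)
    if d == "euclidean":
        with np.errstate(divide="ignore", invalid="ignore"):
            M = np.where(D > 0.0, W / np.where(D > 0.0, D, 1.0), 0.0)
        return M.sum(axis=1)[:, None] * F - M @ F
    # correlation distance: d_ij = 1 - c_i.c_j / (|c_i||c_j|) on centred rows
    C = F - F.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(C, axis=1)
    if np.any(nrm == 0.0):
        raise DegenerateInputError("zero-variance activation row")
    A = W / (nrm[:, None] * nrm[None, :])
    R = 1.0 - D  # Pearson r matrix
    coef = (W * R).sum(axis=1) / nrm**2
    return -(A @ C) + coef[:, None] * C


def rdl_gradient_full(
    acts, target: RDM, dissimilarity: str = "squared_euclidean_sum"
) -> np.ndarray:
    """Exact gradient of :func:`rdl_error` with respect to the activations,
    using every pair."""
    _check_dissimilarity(dissimilarity)
    F, D = _align(acts, target, dissimilarity)
    n = F.shape[0]
    W = D - target.values
    np.fill_diagonal(W, 0.0)
    return 4.0 / (n * (n - 1)) * _weighted_pair_grad(F, W, D, dissimilarity)


def rdl_gradient_subsampled(
    acts,
    target: RDM,
    pairs: PairSet,
    dissimilarity: str = "squared_euclidean_sum",
) -> np.ndarray:
    """Pair-subsampled gradient estimator.

    Each image's row is normalised by |X_P| * |P_{x_i}|; rows of images
    absent from every sampled pair are exactly zero.
    """
    _check_dissimilarity(dissimilarity)
    F, D = _align(acts, target, dissimilarity)
    n = F.shape[0]
    if pairs.n != n:
        raise ValueError("PairSet batch size does not match activations")
    # multiplicity of each directed neighbour relation (i,j): pair (p,q)
    # contributes to both member rows
    M = np.zeros((n, n))
    np.add.at(M, (pairs.pairs[:, 0], pairs.pairs[:, 1]), 1.0)
    M = M + M.T
    W = (D - target.values) * M
    np.fill_diagonal(W, 0.0)
    G = _weighted_pair_grad(F, W, D, dissimilarity)
    denom = pairs.n_covered * pairs.counts.astype(float)
    scale = np.divide(
        4.0, denom, out=np.zeros_like(denom, dtype=float), where=denom > 0
    )
    G = G * scale[:, None]
    G[pairs.counts == 0, :] = 0.0
    return G


def combine_gradients(
    backprop_grad: np.ndarray, aux_grad: np.ndarray, alpha: float
) -> np.ndarray:
    """Total error gradient at an attachment site: backprop + alpha * aux."""
    backprop_grad = np.asarray(backprop_grad, dtype=float)
    aux_grad = np.asarray(aux_grad, dtype=float)
    if backprop_grad.shape != aux_grad.shape:
        raise ValueError(
            f"gradient shape mismatch: {backprop_grad.shape} vs {aux_grad.shape}"
        )
    return backprop_grad + alpha * aux_grad


# ---------------------------------------------------------------------------
# Alpha decay schedules

@dataclass(frozen=True)
class AlphaSchedule:
    """Epoch-indexed decay of the auxiliary-loss weight alpha.

    ``linear_rdl``: alpha(t) = alpha0 * (1 - t/t_max), reaching 0 at t_max.
    ``multiplicative_dsn``: alpha(t+1) = alpha(t) * 0.1 * (1 - t/t_max),
    iterated from alpha0 (the deep-supervision convention).
    """

    alpha0: float
    t_max: int
    rule: str = "linear_rdl"

    def __post_init__(self):
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be nonnegative")
        if self.t_max < 1:
            raise ValueError("t_max must be at least 1")
        if self.rule not in ("linear_rdl", "multiplicative_dsn"):
            raise ValueError(f"unknown schedule rule {self.rule!r}")


def alpha_at(schedule: AlphaSchedule, t: int) -> float:
    """Alpha at epoch t (0-based; t = t_max is the final endpoint)."""
    if not (0 <= t <= schedule.t_max):
        raise ValueError(f"epoch {t} outside [0, {schedule.t_max}]")
    if schedule.rule == "linear_rdl":
        return schedule.alpha0 * (1.0 - t / schedule.t_max)
    a = schedule.alpha0
    for s in range(t):
        a *= 0.1 * (1.0 - s / schedule.t_max)
    return a
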