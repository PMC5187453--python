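"""Inter-model RDM comparison, bootstrap aggregation, classical MDS, and
the exact McNemar test for paired classifier comparison.

RDMs are compared on their vectorised upper triangles, either by
correlation distance (1 - Pearson r, invariant to affine rescaling of the
dissimilarities) or by normalised Euclidean distance (the Euclidean
distance between the two unit-norm-scaled triangle vectors; alternative
normalisations are selectable).
"""

from __future__ import annotations

import warnings
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import binom

from .rdm import RDM, DegenerateInputError, compute_rdm, rdm_vectorize

__all__ = [
    "rdm_compare",
    "bootstrap_rdm_distances",
    "classical_mds",
    "McNemarResult",
    "mcnemar_exact",
]

RDM_METRICS = ("correlation_distance", "normalized_euclidean")


def rdm_compare(a: RDM, b: RDM, metric: str = "correlation_distance") -> float:
    """Distance between two RDMs over the same inputs."""
    if metric not in RDM_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {RDM_METRICS}")
    if a.n != b.n or a.input_ids != b.input_ids:
        raise ValueError("RDMs must share size and input identifiers")
    va, vb = rdm_vectorize(a), rdm_vectorize(b)
    if metric == "correlation_distance":
        if va.size < 2 or np.var(va) == 0.0 or np.var(vb) == 0.0:
            raise DegenerateInputError(
                "correlation distance undefined for zero-variance RDM triangles"
            )
        ca, cb = va - va.mean(), vb - vb.mean()
        r = float(ca @ cb / np.sqrt((ca @ ca) * (cb @ cb)))
        return 1.0 - r
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    ua = va / na if na > 0 else va
    ub = vb / nb if nb > 0 else vb
    return float(np.linalg.norm(ua - ub))


def bootstrap_rdm_distances(
    sources: Mapping[str, np.ndarray],
    n_boot: int = 20,
    sample_size: int = 100,
    metric: str = "correlation_distance",
    dissimilarity: str = "squared_euclidean_sum",
    seed: int | None = None,
    replace: bool = False,
) -> pd.DataFrame:
    """Mean pairwise inter-RDM distance matrix over bootstrapped image sets.

    ``sources`` maps a model/layer label to its activation matrix on a
    common probe set (rows aligned across sources).  For each of ``n_boot``
    draws of ``sample_size`` probe rows (without replacement within a draw
    by default), every source's RDM is computed on the drawn subset, all
    pairwise distances are taken, and the matrices are averaged element-wise
    across draws.
    """
    labels = list(sources)
    acts = {k: np.asarray(v, dtype=float) for k, v in sources.items()}
    sizes = {v.shape[0] for v in acts.values()}
    if len(sizes) != 1:
        raise ValueError("all sources must cover the same probe set")
    n_probe = sizes.pop()
    if not replace and sample_size > n_probe:
        raise ValueError(
            f"sample_size {sample_size} exceeds probe set of {n_probe} images"
        )
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    rng = np.random.default_rng(seed)
    m = len(labels)
    total = np.zeros((m, m))
    for _ in range(n_boot):
        idx = rng.choice(n_probe, size=sample_size, replace=replace)
        rdms = [
            compute_rdm(acts[k][idx], dissimilarity=dissimilarity) for k in labels
        ]
        for i in range(m):
            for j in range(i + 1, m):
                dist = rdm_compare(rdms[i], rdms[j], metric=metric)
                total[i, j] += dist
                total[j, i] += dist
    return pd.DataFrame(total / n_boot, index=labels, columns=labels)


def classical_mds(dist, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared distance matrix, eigendecomposes it, and
    returns coordinates on the top ``dims`` nonnegative-eigenvalue axes,
    with the deterministic sign convention that each axis's first nonzero
    loading is positive.  If fewer than ``dims`` nonnegative eigenvalues
    exist, the remaining coordinates are zero-padded with a warning.
    """
    if isinstance(dist, pd.DataFrame):
        dist = dist.to_numpy()
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or np.any(D < 0):
        raise ValueError("distance matrix must be symmetric and nonnegative")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, dims))
    tol = max(1e-12, 1e-9 * max(abs(evals[0]), 1.0))
    n_pos = 0
    for axis in range(min(dims, n)):
        if evals[axis] > tol:
            coords[:, axis] = evecs[:, axis] * np.sqrt(evals[axis])
            n_pos += 1
    if n_pos < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; remaining coordinates zero-padded",
            RuntimeWarning,
        )
    for axis in range(dims):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-300)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords


class McNemarResult(NamedTuple):
    p_value: float
    n01: int  # items only the second classifier got right
    n10: int  # items only the first classifier got right


def mcnemar_exact(a, b) -> McNemarResult:
    """Two-sided exact McNemar test on two per-item correctness vectors.

    With discordant counts n01 (b-only correct) and n10 (a-only correct),
    p = min(1, 2 P(X <= min(n01, n10))) for X ~ Binomial(n01 + n10, 1/2);
    with no discordant items p = 1 by convention.
    """
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    if a.size != b.size:
        raise ValueError("correctness vectors must have equal length")
    n01 = int(np.sum(~a & b))
    n10 = int(np.sum(a & ~b))
    m = n01 + n10
    if m == 0:
        return McNemarResult(1.0, n01, n10)
    p = min(1.0, 2.0 * float(binom.cdf(min(n01, n10), m, 0.5)))
    return McNemarResult(p, n01, n10)
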