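"""Representational distance matrices (RDMs).

An RDM characterises the representational geometry of a layer: entry (i, j)
is the dissimilarity d(f(x_i), f(x_j)) between the layer's activation
vectors for inputs i and j.  The matrix is symmetric with an exactly zero
diagonal, and is indexed by input identifiers so that RDMs from different
models can be aligned before comparison.

Four dissimilarities are supported:

``squared_euclidean_sum``
    sum_k (a_k - b_k)^2 — the default for training, whose analytic RDM-loss
    gradient carries the exact 8/(n(n-1)) constant.
``squared_euclidean_mean``
    the same divided by the number of units K (a per-unit mean squared
    difference, scale-stable across layer widths).
``euclidean``
    the square root of the sum variant.
``correlation_distance``
    1 - Pearson r across units; undefined (raises) for zero-variance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "DISSIMILARITIES",
    "DegenerateInputError",
    "ActivationMatrix",
    "RDM",
    "pairwise_dissimilarity",
    "compute_rdm",
    "rdm_vectorize",
    "rdm_devectorize",
    "rdm_to_csv",
    "rdm_from_csv",
    "save_rdm_stack",
    "load_rdm_stack",
]

DISSIMILARITIES = (
    "squared_euclidean_sum",
    "squared_euclidean_mean",
    "euclidean",
    "correlation_distance",
)


class DegenerateInputError(ValueError):
    """Raised when a dissimilarity is undefined for the given input
    (e.g. correlation distance of a zero-variance activation vector)."""


def _check_dissimilarity(d: str) -> str:
    if d not in DISSIMILARITIES:
        raise ValueError(f"unknown dissimilarity {d!r}; choose from {DISSIMILARITIES}")
    return d


def _as_matrix(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"activation matrix must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("activation matrix contains non-finite values")
    return arr


def _default_ids(n: int) -> tuple[str, ...]:
    return tuple(str(i) for i in range(n))


@dataclass(frozen=True)
class ActivationMatrix:
    """Activations of one layer for a batch: n_inputs x n_units, with
    ordered input identifiers."""

    values: np.ndarray
    input_ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        arr = _as_matrix(self.values)
        object.__setattr__(self, "values", arr)
        ids = self.input_ids
        ids = _default_ids(arr.shape[0]) if ids is None else tuple(str(i) for i in ids)
        if len(ids) != arr.shape[0]:
            raise ValueError("input_ids length does not match number of rows")
        object.__setattr__(self, "input_ids", ids)

    @property
    def n_inputs(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RDM:
    """Symmetric n x n dissimilarity matrix with exactly zero diagonal."""

    values: np.ndarray
    input_ids: tuple[str, ...] = None  # type: ignore[assignment]
    dissimilarity: str = "squared_euclidean_sum"

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"RDM must be square, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("RDM contains non-finite values")
        if not np.array_equal(arr, arr.T):
            raise ValueError("RDM must be symmetric")
        if np.any(np.diagonal(arr) != 0.0):
            raise ValueError("RDM diagonal must be exactly zero")
        object.__setattr__(self, "values", arr)
        ids = self.input_ids
        ids = _default_ids(arr.shape[0]) if ids is None else tuple(str(i) for i in ids)
        if len(ids) != arr.shape[0]:
            raise ValueError("input_ids length does not match RDM size")
        object.__setattr__(self, "input_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_dissimilarity(a, b, dissimilarity: str = "squared_euclidean_sum") -> float:
    """Dissimilarity between two activation vectors."""
    _check_dissimilarity(dissimilarity)
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 1:
        raise ValueError("vectors must have equal nonzero length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite activation values")
    if dissimilarity == "squared_euclidean_sum":
        return float(np.sum((a - b) ** 2))
    if dissimilarity == "squared_euclidean_mean":
        return float(np.sum((a - b) ** 2) / a.size)
    if dissimilarity == "euclidean":
        return float(np.sqrt(np.sum((a - b) ** 2)))
    # correlation distance
    if a.size < 2 or np.var(a) == 0.0 or np.var(b) == 0.0:
        raise DegenerateInputError(
            "correlation distance undefined for zero-variance vectors"
        )
    ac, bc = a - a.mean(), b - b.mean()
    r = float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))
    return 1.0 - r


def compute_rdm(
    acts,
    dissimilarity: str = "squared_euclidean_sum",
    input_ids: Sequence | None = None,
) -> RDM:
    """Compute the RDM of an activation matrix (rows = inputs)."""
    _check_dissimilarity(dissimilarity)
    if isinstance(acts, ActivationMatrix):
        if input_ids is None:
            input_ids = acts.input_ids
        acts = acts.values
    X = _as_matrix(acts)
    n = X.shape[0]
    if n < 2:
        raise ValueError("RDM computation needs at least 2 inputs")
    if dissimilarity == "correlation_distance":
        if X.shape[1] < 2 or np.any(np.var(X, axis=1) == 0.0):
            raise DegenerateInputError(
                "correlation distance undefined for zero-variance rows"
            )
        D = cdist(X, X, metric="correlation")
    elif dissimilarity == "euclidean":
        D = cdist(X, X, metric="euclidean")
    else:
        D = cdist(X, X, metric="sqeuclidean")
        if dissimilarity == "squared_euclidean_mean":
            D = D / X.shape[1]
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return RDM(D, input_ids=input_ids, dissimilarity=dissimilarity)


def rdm_vectorize(rdm: RDM) -> np.ndarray:
    """Upper-triangle entries (i < j), row-major — the canonical vector form
    used for inter-RDM comparison and persistence."""
    iu = np.triu_indices(rdm.n, k=1)
    return rdm.values[iu].copy()


def rdm_devectorize(
    vec,
    input_ids: Sequence | None = None,
    dissimilarity: str = "squared_euclidean_sum",
) -> RDM:
    """Inverse of :func:`rdm_vectorize`: rebuild the symmetric matrix."""
    v = np.asarray(vec, dtype=float).ravel()
    m = v.size
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not n(n-1)/2 for integer n")
    D = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    D[iu] = v
    D = D + D.T
    return RDM(D, input_ids=input_ids, dissimilarity=dissimilarity)


# ---------------------------------------------------------------------------
# Persistence

def rdm_to_csv(rdm: RDM, path) -> None:
    """Write an RDM as CSV: first row/column are input identifiers, body is
    the full symmetric matrix at 17 significant digits (lossless for
    doubles)."""
    df = pd.DataFrame(rdm.values, index=rdm.input_ids, columns=rdm.input_ids)
    df.to_csv(path, float_format="%.17g")


def rdm_from_csv(path, dissimilarity: str = "squared_euclidean_sum") -> RDM:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    ids = tuple(str(i) for i in df.index)
    if tuple(str(c) for c in df.columns) != ids:
        raise ValueError("RDM CSV row and column identifiers disagree")
    return RDM(df.to_numpy(dtype=float), input_ids=ids, dissimilarity=dissimilarity)


def save_rdm_stack(path, rdms: Mapping[str, RDM]) -> None:
    """Persist a stack of RDMs as a keyed-array container (``.npz``), one
    key ``rdm/<layer_name>`` per matrix plus its identifiers."""
    arrays = {}
    for name, rdm in rdms.items():
        arrays[f"rdm/{name}"] = rdm.values
        arrays[f"ids/{name}"] = np.array(rdm.input_ids)
        arrays[f"dissimilarity/{name}"] = np.array(rdm.dissimilarity)
    np.savez(path, **arrays)


def load_rdm_stack(path) -> dict[str, RDM]:
    with np.load(path, allow_pickle=False) as data:
        names = [k[len("rdm/"):] for k in data.files if k.startswith("rdm/")]
        return {
            name: RDM(
                data[f"rdm/{name}"],
                input_ids=tuple(data[f"ids/{name}"]),
                dissimilarity=str(data[f"dissimilarity/{name}"]),
            )
            for name in names
        }
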