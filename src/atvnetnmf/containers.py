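"""Core data containers: omics matrices, network triples, graph Laplacians.

An :class:`OmicsMatrix` holds one non-negative feature-by-sample layer (e.g.
methylation beta-values or gene expression) with its identifier axes. A
:class:`NetworkTriple` holds the two within-layer co-expression networks
``R11`` (n1 x n1), ``R22`` (n2 x n2) and the cross-layer network ``R12``
(n1 x n2) that the tri-factorization consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OmicsMatrix", "NetworkTriple", "GraphLaplacian"]

_SYM_ATOL = 1e-12


def _check_unique(ids, name: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {name}: {sorted(set(dups))[:5]}")
    return ids


def _check_nonnegative_finite(values: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"{name} contains non-finite value at {tuple(bad)}")
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{name} contains negative value {values[tuple(bad)]!r} at {tuple(bad)}"
        )


@dataclass
class OmicsMatrix:
    """Non-negative feature x sample matrix for one omics layer.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_samples)
        Non-negative, finite measurements.
    feature_ids, sample_ids : sequence of str
        Unique identifiers for the two axes.
    layer_name : str
        Free-text label, e.g. ``"methylation"`` or ``"expression"``.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    layer_name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.feature_ids = _check_unique(self.feature_ids, "feature_ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} feature_ids x {len(self.sample_ids)} sample_ids"
            )
        _check_nonnegative_finite(self.values, f"{self.layer_name} values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class NetworkTriple:
    """The three non-negative networks entering the tri-factorization."""

    R11: np.ndarray
    R12: np.ndarray
    R22: np.ndarray
    ids1: list[str] = field(default_factory=list)
    ids2: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.R11 = np.asarray(self.R11, dtype=float)
        self.R12 = np.asarray(self.R12, dtype=float)
        self.R22 = np.asarray(self.R22, dtype=float)
        n1, n2 = self.R11.shape[0], self.R22.shape[0]
        if self.R11.shape != (n1, n1) or self.R22.shape != (n2, n2):
            raise ValueError("R11 and R22 must be square")
        if self.R12.shape != (n1, n2):
            raise ValueError(
                f"R12 shape {self.R12.shape} incompatible with R11 ({n1}) and R22 ({n2})"
            )
        for name, mat in (("R11", self.R11), ("R12", self.R12), ("R22", self.R22)):
            _check_nonnegative_finite(mat, name)
        for name, mat in (("R11", self.R11), ("R22", self.R22)):
            if not np.allclose(mat, mat.T, atol=_SYM_ATOL, rtol=0):
                raise ValueError(f"{name} is not symmetric (tolerance {_SYM_ATOL})")
        if not self.ids1:
            self.ids1 = [f"f1_{i}" for i in range(n1)]
        if not self.ids2:
            self.ids2 = [f"f2_{i}" for i in range(n2)]
        self.ids1 = _check_unique(self.ids1, "ids1")
        self.ids2 = _check_unique(self.ids2, "ids2")
        if len(self.ids1) != n1 or len(self.ids2) != n2:
            raise ValueError("identifier lengths do not match network dimensions")

    @property
    def n1(self) -> int:
        return self.R11.shape[0]

    @property
    def n2(self) -> int:
        return self.R22.shape[0]


@dataclass
class GraphLaplacian:
    """Unnormalized graph Laplacian L = D - W of a kNN similarity graph."""

    L: np.ndarray
    adjacency: np.ndarray
    neighbor_count: int

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.L.shape[0]
        if self.L.shape != (n, n) or self.adjacency.shape != (n, n):
            raise ValueError("L and adjacency must be square and same shape")
        if np.any(self.adjacency < 0):
            raise ValueError("adjacency must be non-negative")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.allclose(self.L, self.L.T, atol=1e-10, rtol=0):
            raise ValueError("L must be symmetric")
        rowsums = np.abs(self.L.sum(axis=1))
        if rowsums.max(initial=0.0) > 1e-10:
            raise ValueError("rows of L must sum to 0")
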