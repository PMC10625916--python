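"""Co-expression network construction.

Builds the non-negative similarity networks (absolute Pearson correlation by
default) and the kNN graph Laplacians consumed by the factorization, plus the
low-signal feature filter applied to raw omics layers.
"""

from __future__ import annotations

import numpy as np

from .containers import GraphLaplacian, NetworkTriple, OmicsMatrix

__all__ = [
    "filter_low_signal",
    "build_autocorrelation_network",
    "build_cross_network",
    "build_network_triple",
    "build_graph_laplacian",
]


def filter_low_signal(X: OmicsMatrix, mean_threshold: float) -> OmicsMatrix:
    """Drop features whose row mean falls below ``mean_threshold``.

    Features with mean strictly less than the threshold are removed; row
    order and the sample axis are unchanged.
    """
    if mean_threshold < 0:
        raise ValueError("mean_threshold must be >= 0")
    keep = X.values.mean(axis=1) >= mean_threshold
    if not keep.any():
        raise ValueError(
            f"no features retained in layer {X.layer_name!r} at mean "
            f"threshold {mean_threshold}"
        )
    return OmicsMatrix(
        values=X.values[keep],
        feature_ids=[f for f, k in zip(X.feature_ids, keep) if k],
        sample_ids=list(X.sample_ids),
        layer_name=X.layer_name,
    )


def _standardize_rows(X: OmicsMatrix) -> np.ndarray:
    """Rows centered and scaled to unit norm; zero-variance rows are an error."""
    V = X.values
    centered = V - V.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        names = [X.feature_ids[i] for i in zero[:5]]
        raise ValueError(
            f"zero-variance feature(s) in layer {X.layer_name!r}: {names} "
            "(Pearson correlation undefined); filter or perturb them first"
        )
    return centered / norms[:, None]


def build_autocorrelation_network(
    X: OmicsMatrix, signed: str = "absolute"
) -> np.ndarray:
    """Within-layer similarity network: |Pearson r| between feature pairs.

    Parameters
    ----------
    X : OmicsMatrix
        Layer with at least 3 samples and no zero-variance feature.
    signed : {"absolute", "positive"}
        ``"absolute"`` uses |r| (keeps anticorrelation signal);
        ``"positive"`` uses max(r, 0).

    Returns
    -------
    ndarray of shape (n_features, n_features)
        Symmetric, entries in [0, 1], unit diagonal.
    """
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples to build a correlation network")
    Z = _standardize_rows(X)
    R = Z @ Z.T
    R = _rectify(R, signed)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def _rectify(R: np.ndarray, signed: str) -> np.ndarray:
    if signed == "absolute":
        R = np.abs(R)
    elif signed == "positive":
        R = np.maximum(R, 0.0)
    else:
        raise ValueError(f"signed must be 'absolute' or 'positive', got {signed!r}")
    return np.clip(R, 0.0, 1.0)


def _align_samples(X1: OmicsMatrix, X2: OmicsMatrix) -> OmicsMatrix:
    """Return X2 with columns reordered to X1's sample IDs; error on mismatch."""
    if X1.sample_ids == X2.sample_ids:
        return X2
    missing = sorted(set(X1.sample_ids) ^ set(X2.sample_ids))
    if missing:
        raise ValueError(
            f"sample IDs of layers {X1.layer_name!r} and {X2.layer_name!r} "
            f"do not match; unmatched: {missing[:10]}"
        )
    order = [X2.sample_ids.index(s) for s in X1.sample_ids]
    return OmicsMatrix(
        values=X2.values[:, order],
        feature_ids=list(X2.feature_ids),
        sample_ids=list(X1.sample_ids),
        layer_name=X2.layer_name,
    )


def build_cross_network(
    X1: OmicsMatrix, X2: OmicsMatrix, signed: str = "absolute"
) -> np.ndarray:
    """Cross-layer network: |Pearson r| between layer-1 and layer-2 features.

    Samples are matched by identifier; X2's columns are reordered if needed,
    and any ID mismatch is an error rather than a silent intersection.
    """
    if X1.n_samples < 3:
        raise ValueError("need at least 3 samples to build a correlation network")
    X2 = _align_samples(X1, X2)
    Z1 = _standardize_rows(X1)
    Z2 = _standardize_rows(X2)
    return _rectify(Z1 @ Z2.T, signed)


def build_network_triple(
    X1: OmicsMatrix, X2: OmicsMatrix, signed: str = "absolute"
) -> NetworkTriple:
    """Build R11, R12, R22 from two aligned omics layers."""
    return NetworkTriple(
        R11=build_autocorrelation_network(X1, signed=signed),
        R12=build_cross_network(X1, X2, signed=signed),
        R22=build_autocorrelation_network(X2, signed=signed),
        ids1=list(X1.feature_ids),
        ids2=list(X2.feature_ids),
    )


def build_graph_laplacian(R: np.ndarray, neighbor_count: int = 5) -> GraphLaplacian:
    """Unnormalized Laplacian of the symmetrized binary kNN graph of ``R``.

    Node j is connected to its ``neighbor_count`` most similar nodes under
    the similarity matrix ``R`` (diagonal excluded); the directed kNN graph
    is symmetrized by union, and L = D - W with D the degree diagonal.
    Ties are broken by ascending index (argsort stability).
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n):
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-12, rtol=0):
        raise ValueError("R must be symmetric")
    if np.any(R < 0):
        raise ValueError("R must be non-negative")
    if not 1 <= neighbor_count < n:
        raise ValueError(
            f"neighbor_count must satisfy 1 <= neighbor_count < n (got "
            f"{neighbor_count} with n={n})"
        )
    sim = R.copy()
    np.fill_diagonal(sim, -np.inf)
    # stable top-k per row: argsort descending with index tie-break
    order = np.argsort(-sim, axis=1, kind="stable")
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), neighbor_count)
    cols = order[:, :neighbor_count].ravel()
    W[rows, cols] = 1.0
    W = np.maximum(W, W.T)  # union symmetrization
    L = np.diag(W.sum(axis=1)) - W
    return GraphLaplacian(L=L, adjacency=W, neighbor_count=neighbor_count)
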