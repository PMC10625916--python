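"""Module extraction from factor matrices and module-similarity utilities.

Each factor column is z-scored over features; features whose z-score meets
the threshold (default 2) are the column's module members, and the largest
module is the core module. Module similarity between two module sets,

    msim = sum over pairs (x, y) of |Mx & My| / min(|Mx|, |My|),

is used to choose the graph-regularization weight lambda over a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import NetworkTriple
from .factorization import ATVNetNMF

__all__ = [
    "ModuleSet",
    "zscore_columns",
    "extract_modules",
    "module_similarity",
    "select_lambda",
    "default_lambda_grid",
]


@dataclass
class ModuleSet:
    """Per-component feature modules from thresholded z-scored loadings."""

    modules: list[set[str]]
    z_matrix: np.ndarray
    threshold: float
    feature_ids: list[str] = field(default_factory=list)

    @property
    def core_index(self) -> int:
        """Index of the module with the most members (ties -> smallest index)."""
        sizes = [len(m) for m in self.modules]
        return int(np.argmax(sizes))

    @property
    def core_module(self) -> set[str]:
        return self.modules[self.core_index]

    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]


def zscore_columns(G: np.ndarray) -> np.ndarray:
    """Column z-scores with the (n-1)-denominator standard deviation.

    Constant columns map to all-zeros rather than erroring, since degenerate
    factor columns occur with aggressive rank choices.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise ValueError("G must be 2-D")
    if G.shape[0] < 2:
        raise ValueError("need at least 2 rows to z-score (sd undefined)")
    mean = G.mean(axis=0, keepdims=True)
    sd = G.std(axis=0, ddof=1, keepdims=True)
    Z = np.zeros_like(G)
    np.divide(G - mean, sd, out=Z, where=sd > 0)
    return Z


def extract_modules(
    Z: np.ndarray,
    feature_ids,
    threshold: float = 2.0,
    abs_z: bool = False,
) -> ModuleSet:
    """Members of module j are features with Z(i, j) >= threshold.

    Features may belong to several modules; empty modules are legal. With
    ``abs_z`` the comparison uses |Z| instead of signed z-scores.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    feature_ids = [str(f) for f in feature_ids]
    if len(feature_ids) != Z.shape[0]:
        raise ValueError("feature_ids length must match rows of Z")
    scores = np.abs(Z) if abs_z else Z
    modules = [
        {feature_ids[i] for i in np.flatnonzero(scores[:, j] >= threshold)}
        for j in range(Z.shape[1])
    ]
    return ModuleSet(
        modules=modules, z_matrix=Z, threshold=threshold, feature_ids=feature_ids
    )


def module_similarity(A: ModuleSet, B: ModuleSet) -> float:
    """msim: sum over module pairs of |intersection| / min(sizes).

    Pairs where either module is empty are skipped; identifiers are matched
    across the two sets' shared namespace.
    """
    total = 0.0
    for Mx in A.modules:
        if not Mx:
            continue
        for My in B.modules:
            if not My:
                continue
            total += len(Mx & My) / min(len(Mx), len(My))
    return total


def default_lambda_grid() -> list[float]:
    """The 0 to 0.1 grid in steps of 0.01 (11 points)."""
    return [round(0.01 * i, 2) for i in range(11)]


def select_lambda(
    nets: NetworkTriple,
    grid=None,
    *,
    n_components: int = 8,
    threshold: float = 2.0,
    seed: int = 0,
    laplacians=None,
    **estimator_params,
) -> tuple[float, list[float]]:
    """Pick lambda by maximizing cross-layer module similarity over a grid.

    For each lambda, sets lambda1 = lambda2 = lambda, factorizes with the
    given seed, extracts modules from G1 and G2 at the z threshold, and
    scores msim between the two layers' module sets (intersections over the
    shared feature-ID namespace). Returns the argmax lambda (ties -> the
    smallest) and the full msim curve.
    """
    grid = default_lambda_grid() if grid is None else [float(g) for g in grid]
    if not grid:
        raise ValueError("grid must be non-empty")
    if any(g < 0 for g in grid):
        raise ValueError("grid values must be >= 0")
    curve: list[float] = []
    for lam in grid:
        model = ATVNetNMF(
            n_components=n_components,
            lambda1=lam,
            lambda2=lam,
            random_state=seed,
            **estimator_params,
        )
        try:
            model.fit(nets, laplacians=laplacians)
        except Exception as exc:
            raise RuntimeError(f"factorization failed at lambda={lam}") from exc
        mods1 = extract_modules(zscore_columns(model.G1_), nets.ids1, threshold)
        mods2 = extract_modules(zscore_columns(model.G2_), nets.ids2, threshold)
        curve.append(module_similarity(mods1, mods2))
    best = int(np.argmax(curve))
    return grid[best], curve
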