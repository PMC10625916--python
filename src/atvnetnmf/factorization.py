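"""Network NMF tri-factorization with graph and adaptive-TV regularization.

The model approximates three non-negative networks over two feature spaces
sharing the same samples,

    R11 ~ G1 S11 G1',   R12 ~ G1 G2',   R22 ~ G2 S22 G2',

by minimizing

    ||R11 - G1 S11 G1'||_F^2 + a ||R12 - G1 G2'||_F^2
        + b ||R22 - G2 S22 G2'||_F^2
        + sum_i [ l_i tr(Gi' Li Gi) + 2 ||Gi||_ATV ],     Gi, Sii >= 0,

with multiplicative updates. The graph terms (Laplacians Li of kNN
similarity graphs) pull factor loadings toward smoothness over the feature
networks; the adaptive-TV terms denoise the factor matrices while keeping
sharp loading transitions. Switching both off recovers plain netNMF;
graph-only is the NMFNA variant; TV-only is netNMF+ATV.

Signed terms (the Laplacian, via L = D - W, and the TV divergence) are split
elementwise into their positive and negative parts across the update's
numerator and denominator, the standard rearrangement that keeps every
factor non-negative while preserving fixed points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .containers import GraphLaplacian, NetworkTriple
from .networks import build_graph_laplacian
from .tv import atv_energy, tv_divergence

__all__ = [
    "ATVNetNMF",
    "FactorState",
    "VARIANTS",
    "variant_flags",
    "initialize_factors",
    "objective",
    "update_step",
    "factorize",
    "objective_gradients",
    "kkt_residual",
    "reconstruction_correlation",
]

_logger = logging.getLogger(__name__)

# variant name -> (graph regularization on, adaptive TV on)
VARIANTS: dict[str, tuple[bool, bool]] = {
    "netnmf": (False, False),
    "nmfna": (True, False),
    "netnmf-atv": (False, True),
    "atv-netnmf": (True, True),
}


def variant_flags(variant: str) -> tuple[bool, bool]:
    """Map a variant name to its (graph_enabled, tv_enabled) flags."""
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}"
        ) from None


@dataclass
class FactorState:
    """Factor matrices and the objective trace of one factorization run."""

    G1: np.ndarray
    G2: np.ndarray
    S11: np.ndarray
    S22: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    iterations_run: int = 0


def initialize_factors(
    n1: int, n2: int, k: int, random_state=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seeded uniform(0,1) init; S11/S22 = A'A/k so they start symmetric PSD."""
    rng = check_random_state(random_state)
    G1 = rng.uniform(size=(n1, k))
    G2 = rng.uniform(size=(n2, k))
    A1 = rng.uniform(size=(k, k))
    A2 = rng.uniform(size=(k, k))
    S11 = A1.T @ A1 / k
    S22 = A2.T @ A2 / k
    return G1, G2, S11, S22


def objective(
    R11: np.ndarray,
    R12: np.ndarray,
    R22: np.ndarray,
    G1: np.ndarray,
    G2: np.ndarray,
    S11: np.ndarray,
    S22: np.ndarray,
    *,
    alpha: float,
    beta: float,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    L1: GraphLaplacian | np.ndarray | None = None,
    L2: GraphLaplacian | np.ndarray | None = None,
    tv: bool = False,
    grad_epsilon: float = 1e-8,
) -> float:
    """Full objective value; graph terms included iff L1/L2 given, TV iff tv."""
    _check_shapes(R11, R12, R22, G1, G2, S11, S22)
    obj = float(np.linalg.norm(R11 - G1 @ S11 @ G1.T) ** 2)
    obj += alpha * float(np.linalg.norm(R12 - G1 @ G2.T) ** 2)
    obj += beta * float(np.linalg.norm(R22 - G2 @ S22 @ G2.T) ** 2)
    if L1 is not None:
        M1 = L1.L if isinstance(L1, GraphLaplacian) else np.asarray(L1)
        obj += lambda1 * float(np.trace(G1.T @ M1 @ G1))
    if L2 is not None:
        M2 = L2.L if isinstance(L2, GraphLaplacian) else np.asarray(L2)
        obj += lambda2 * float(np.trace(G2.T @ M2 @ G2))
    if tv:
        obj += 2.0 * atv_energy(G1, grad_epsilon)
        obj += 2.0 * atv_energy(G2, grad_epsilon)
    return obj


def _check_shapes(R11, R12, R22, G1, G2, S11, S22) -> None:
    n1, n2 = R11.shape[0], R22.shape[0]
    k = G1.shape[1]
    checks = {
        "R11": (R11.shape, (n1, n1)),
        "R12": (R12.shape, (n1, n2)),
        "R22": (R22.shape, (n2, n2)),
        "G1": (G1.shape, (n1, k)),
        "G2": (G2.shape, (n2, k)),
        "S11": (S11.shape, (k, k)),
        "S22": (S22.shape, (k, k)),
    }
    for name, (got, want) in checks.items():
        if got != want:
            raise ValueError(f"{name} has shape {got}, expected {want}")


def _graph_parts(L: GraphLaplacian | None, G: np.ndarray):
    """Split L G = D G - W G into the denominator (DG) and numerator (WG) parts."""
    if L is None:
        return None, None
    W = L.adjacency
    deg = W.sum(axis=1)
    return deg[:, None] * G, W @ G


def _tv_parts(G: np.ndarray, grad_epsilon: float):
    """Positive/negative split of the TV diffusion divergence at the current G."""
    div = tv_divergence(G, grad_epsilon=grad_epsilon)
    return np.maximum(div, 0.0), np.maximum(-div, 0.0)


def update_step(
    R11: np.ndarray,
    R12: np.ndarray,
    R22: np.ndarray,
    G1: np.ndarray,
    G2: np.ndarray,
    S11: np.ndarray,
    S22: np.ndarray,
    *,
    alpha: float,
    beta: float,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    L1: GraphLaplacian | None = None,
    L2: GraphLaplacian | None = None,
    tv: bool = False,
    grad_epsilon: float = 1e-8,
    denom_floor: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One multiplicative sweep: S11, S22, then G1, G2, each on fresh factors.

    Each factor is multiplied elementwise by numerator/denominator; the
    divergence and Laplacian contributions are split by sign so both sides
    stay non-negative, and denominators are floored at ``denom_floor``.
    """
    # S updates (the b coefficient cancels in the S22 ratio)
    num = G1.T @ R11 @ G1
    den = np.maximum(G1.T @ G1 @ S11 @ (G1.T @ G1), denom_floor)
    S11 = S11 * (num / den)

    num = G2.T @ R22 @ G2
    den = np.maximum(G2.T @ G2 @ S22 @ (G2.T @ G2), denom_floor)
    S22 = S22 * (num / den)

    # G1 update
    num = alpha * (R12 @ G2) + 2.0 * (R11 @ G1 @ S11)
    den = 2.0 * (G1 @ (S11 @ (G1.T @ G1) @ S11)) + alpha * (G1 @ (G2.T @ G2))
    if L1 is not None:
        dg, wg = _graph_parts(L1, G1)
        num = num + 2.0 * lambda1 * wg
        den = den + 2.0 * lambda1 * dg
    if tv:
        pos, neg = _tv_parts(G1, grad_epsilon)
        num = num + pos
        den = den + neg
    G1 = G1 * (num / np.maximum(den, denom_floor))

    # G2 update (uses the fresh G1)
    num = alpha * (R12.T @ G1) + 2.0 * beta * (R22 @ G2 @ S22)
    den = 2.0 * beta * (G2 @ (S22 @ (G2.T @ G2) @ S22)) + alpha * (G2 @ (G1.T @ G1))
    if L2 is not None:
        dg, wg = _graph_parts(L2, G2)
        num = num + 2.0 * lambda2 * wg
        den = den + 2.0 * lambda2 * dg
    if tv:
        pos, neg = _tv_parts(G2, grad_epsilon)
        num = num + pos
        den = den + neg
    G2 = G2 * (num / np.maximum(den, denom_floor))

    return G1, G2, S11, S22


class ATVNetNMF(BaseEstimator):
    """Adaptive-TV, graph-regularized network NMF tri-factorization.

    Parameters
    ----------
    n_components : int, default=8
        Rank k of the factorization. Must not exceed min(n1, n2); at most
        one tenth of the smaller network is the usual working range.
    max_iter : int, default=200
        Number of multiplicative sweeps.
    lambda1, lambda2 : float, default=0.08
        Graph-regularization weights for the two layers (ignored when
        ``graph=False``).
    alpha, beta : float or "auto", default="auto"
        Weights balancing the three reconstruction residuals. "auto"
        resolves alpha = n1/n2 and beta = (n1/n2)^2 at fit time, equalizing
        the per-entry weight of the three Frobenius terms.
    graph : bool, default=True
        Include the Laplacian smoothness terms (NMFNA lineage).
    tv : bool, default=True
        Include the adaptive total-variation terms.
    n_neighbors : int, default=5
        kNN neighborhood size for the Laplacians built from R11/R22 when
        none are supplied to :meth:`fit`.
    tol : float, default=0.0
        Relative objective-change stopping tolerance; 0 runs all
        ``max_iter`` sweeps.
    grad_epsilon : float, default=1e-8
        Quadrature smoothing of the gradient magnitude in the TV operators.
    denom_floor : float, default=1e-12
        Floor applied to every multiplicative-update denominator.
    eval_every : int, default=1
        Evaluate the objective every this many iterations.
    random_state : int, RandomState or None
        Seeds the uniform factor initialization.

    Attributes
    ----------
    G1_, G2_ : ndarray of shape (n1, k), (n2, k)
        Non-negative feature-loading matrices.
    S11_, S22_ : ndarray of shape (k, k)
        Symmetric non-negative component-interaction matrices.
    objective_trace_ : list of float
        Objective value after each evaluated iteration.
    initial_objective_ : float
        Objective at the initialization.
    n_iter_ : int
        Iterations actually run.

    Examples
    --------
    >>> from atvnetnmf import ATVNetNMF, generate_planted_multiomics
    >>> from atvnetnmf.networks import build_network_triple
    >>> X1, X2, truth = generate_planted_multiomics(seed=7)
    >>> nets = build_network_triple(X1, X2)
    >>> model = ATVNetNMF(n_components=4, random_state=0).fit(nets)
    >>> model.G1_.shape
    (200, 4)
    """

    def __init__(
        self,
        n_components: int = 8,
        *,
        max_iter: int = 200,
        lambda1: float = 0.08,
        lambda2: float = 0.08,
        alpha="auto",
        beta="auto",
        graph: bool = True,
        tv: bool = True,
        n_neighbors: int = 5,
        tol: float = 0.0,
        grad_epsilon: float = 1e-8,
        denom_floor: float = 1e-12,
        eval_every: int = 1,
        random_state=None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.alpha = alpha
        self.beta = beta
        self.graph = graph
        self.tv = tv
        self.n_neighbors = n_neighbors
        self.tol = tol
        self.grad_epsilon = grad_epsilon
        self.denom_floor = denom_floor
        self.eval_every = eval_every
        self.random_state = random_state

    @classmethod
    def from_variant(cls, variant: str, **params) -> "ATVNetNMF":
        """Construct with graph/TV flags set by a named variant."""
        graph, tv = variant_flags(variant)
        return cls(graph=graph, tv=tv, **params)

    # ------------------------------------------------------------------
    def _resolve_weights(self, n1: int, n2: int) -> tuple[float, float]:
        alpha = n1 / n2 if self.alpha == "auto" else float(self.alpha)
        beta = (n1 / n2) ** 2 if self.beta == "auto" else float(self.beta)
        if alpha <= 0 or beta <= 0:
            raise ValueError("alpha and beta must be positive")
        return alpha, beta

    @staticmethod
    def _as_triple(X) -> NetworkTriple:
        if isinstance(X, NetworkTriple):
            return X
        if isinstance(X, (tuple, list)) and len(X) == 3:
            return NetworkTriple(R11=X[0], R12=X[1], R22=X[2])
        raise TypeError(
            "X must be a NetworkTriple or a (R11, R12, R22) triple of arrays"
        )

    def fit(self, X, y=None, laplacians=None):
        """Factorize a network triple.

        Parameters
        ----------
        X : NetworkTriple or (R11, R12, R22)
            The three non-negative networks.
        y : ignored
        laplacians : (GraphLaplacian, GraphLaplacian), optional
            Precomputed Laplacians for the two layers; built from R11/R22
            with ``n_neighbors`` when omitted and ``graph=True``.
        """
        nets = self._as_triple(X)
        n1, n2, k = nets.n1, nets.n2, int(self.n_components)
        if not 1 <= k <= min(n1, n2):
            raise ValueError(
                f"n_components must satisfy 1 <= k <= min(n1, n2) = "
                f"{min(n1, n2)}, got {k}"
            )
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        alpha, beta = self._resolve_weights(n1, n2)

        if self.graph:
            if laplacians is not None:
                L1, L2 = laplacians
            else:
                L1 = build_graph_laplacian(nets.R11, self.n_neighbors)
                L2 = build_graph_laplacian(nets.R22, self.n_neighbors)
        else:
            L1 = L2 = None

        G1, G2, S11, S22 = initialize_factors(n1, n2, k, self.random_state)
        obj_kw = dict(
            alpha=alpha,
            beta=beta,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            L1=L1,
            L2=L2,
            tv=self.tv,
            grad_epsilon=self.grad_epsilon,
        )
        prev = objective(nets.R11, nets.R12, nets.R22, G1, G2, S11, S22, **obj_kw)
        self.initial_objective_ = prev

        trace: list[float] = []
        it = 0
        for it in range(1, self.max_iter + 1):
            G1, G2, S11, S22 = update_step(
                nets.R11,
                nets.R12,
                nets.R22,
                G1,
                G2,
                S11,
                S22,
                alpha=alpha,
                beta=beta,
                lambda1=self.lambda1,
                lambda2=self.lambda2,
                L1=L1,
                L2=L2,
                tv=self.tv,
                grad_epsilon=self.grad_epsilon,
                denom_floor=self.denom_floor,
            )
            for name, F in (("G1", G1), ("G2", G2), ("S11", S11), ("S22", S22)):
                if not np.all(np.isfinite(F)):
                    raise RuntimeError(
                        f"numerical failure: non-finite entries in {name} at "
                        f"iteration {it}"
                    )
            if it % self.eval_every == 0 or it == self.max_iter:
                cur = objective(
                    nets.R11, nets.R12, nets.R22, G1, G2, S11, S22, **obj_kw
                )
                trace.append(cur)
                if it % 10 == 0:
                    _logger.info("iteration %d: objective %.6g", it, cur)
                if self.tol > 0 and abs(prev - cur) <= self.tol * max(
                    abs(prev), self.denom_floor
                ):
                    prev = cur
                    break
                prev = cur

        self.G1_, self.G2_, self.S11_, self.S22_ = G1, G2, S11, S22
        self.alpha_, self.beta_ = alpha, beta
        self.laplacian1_, self.laplacian2_ = L1, L2
        self.objective_trace_ = trace
        self.n_iter_ = it
        self.n_features_in_ = n1 + n2
        return self

    # ------------------------------------------------------------------
    def reconstruct(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Reconstructed networks (R11_hat, R12_hat, R22_hat)."""
        self._check_fitted()
        return (
            self.G1_ @ self.S11_ @ self.G1_.T,
            self.G1_ @ self.G2_.T,
            self.G2_ @ self.S22_ @ self.G2_.T,
        )

    def reconstruction_correlations(self, X) -> dict[str, float]:
        """Pearson correlation between each input network and its reconstruction."""
        nets = self._as_triple(X)
        R11h, R12h, R22h = self.reconstruct()
        return {
            "R11": reconstruction_correlation(nets.R11, R11h),
            "R12": reconstruction_correlation(nets.R12, R12h),
            "R22": reconstruction_correlation(nets.R22, R22h),
        }

    def kkt_residual(self, X) -> float:
        """Complementary-slackness residual of the fitted factors on X."""
        self._check_fitted()
        nets = self._as_triple(X)
        return kkt_residual(
            nets.R11,
            nets.R12,
            nets.R22,
            self.G1_,
            self.G2_,
            self.S11_,
            self.S22_,
            alpha=self.alpha_,
            beta=self.beta_,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            L1=self.laplacian1_,
            L2=self.laplacian2_,
            tv=self.tv,
            grad_epsilon=self.grad_epsilon,
        )

    def to_state(self) -> FactorState:
        self._check_fitted()
        return FactorState(
            G1=self.G1_,
            G2=self.G2_,
            S11=self.S11_,
            S22=self.S22_,
            objective_trace=list(self.objective_trace_),
            iterations_run=self.n_iter_,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "G1_"):
            raise RuntimeError("this ATVNetNMF instance is not fitted yet")


def factorize(
    nets: NetworkTriple,
    L1: GraphLaplacian | None = None,
    L2: GraphLaplacian | None = None,
    **params,
) -> FactorState:
    """Functional front end: fit an :class:`ATVNetNMF` and return its state."""
    model = ATVNetNMF(**params)
    laps = (L1, L2) if (L1 is not None or L2 is not None) else None
    model.fit(nets, laplacians=laps)
    return model.to_state()


def objective_gradients(
    R11,
    R12,
    R22,
    G1,
    G2,
    S11,
    S22,
    *,
    alpha: float,
    beta: float,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    L1: GraphLaplacian | np.ndarray | None = None,
    L2: GraphLaplacian | np.ndarray | None = None,
    tv: bool = False,
    grad_epsilon: float = 1e-8,
) -> dict[str, np.ndarray]:
    """Gradients of the objective w.r.t. each factor (multipliers omitted).

    Symmetric R11/R22 and S11/S22 are assumed. The TV contribution is
    -2 div(grad G / |grad G|_eps^(2-p)) with the exponent map p frozen at
    the current factor, matching the update rules.
    """
    GtG1 = G1.T @ G1
    GtG2 = G2.T @ G2
    g_S11 = 2.0 * (GtG1 @ S11 @ GtG1) - 2.0 * (G1.T @ R11 @ G1)
    g_S22 = beta * (2.0 * (GtG2 @ S22 @ GtG2) - 2.0 * (G2.T @ R22 @ G2))
    g_G1 = 4.0 * (G1 @ (S11 @ GtG1 @ S11)) - 4.0 * (R11 @ G1 @ S11)
    g_G1 = g_G1 + 2.0 * alpha * (G1 @ GtG2 - R12 @ G2)
    g_G2 = 4.0 * beta * (G2 @ (S22 @ GtG2 @ S22) - R22 @ G2 @ S22)
    g_G2 = g_G2 + 2.0 * alpha * (G2 @ GtG1 - R12.T @ G1)
    if L1 is not None:
        M1 = L1.L if isinstance(L1, GraphLaplacian) else np.asarray(L1)
        g_G1 = g_G1 + 2.0 * lambda1 * (M1 @ G1)
    if L2 is not None:
        M2 = L2.L if isinstance(L2, GraphLaplacian) else np.asarray(L2)
        g_G2 = g_G2 + 2.0 * lambda2 * (M2 @ G2)
    if tv:
        g_G1 = g_G1 - 2.0 * tv_divergence(G1, grad_epsilon=grad_epsilon)
        g_G2 = g_G2 - 2.0 * tv_divergence(G2, grad_epsilon=grad_epsilon)
    return {"G1": g_G1, "G2": g_G2, "S11": g_S11, "S22": g_S22}


def kkt_residual(R11, R12, R22, G1, G2, S11, S22, **kwargs) -> float:
    """max over factors of ||min(factor, grad)||_inf.

    At a KKT point of the non-negativity-constrained problem either a factor
    entry is zero (and its gradient non-negative) or the gradient vanishes,
    so min(factor, gradient) -> 0 entrywise as the iterate approaches
    stationarity.
    """
    grads = objective_gradients(R11, R12, R22, G1, G2, S11, S22, **kwargs)
    factors = {"G1": G1, "G2": G2, "S11": S11, "S22": S22}
    return max(
        float(np.max(np.abs(np.minimum(factors[name], grads[name]))))
        for name in factors
    )


def reconstruction_correlation(R: np.ndarray, R_hat: np.ndarray) -> float:
    """Pearson correlation between the flattened entries of R and R_hat."""
    R = np.asarray(R, dtype=float)
    R_hat = np.asarray(R_hat, dtype=float)
    if R.shape != R_hat.shape:
        raise ValueError(f"shape mismatch: {R.shape} vs {R_hat.shape}")
    a = R.ravel() - R.mean()
    b = R_hat.ravel() - R_hat.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined: a matrix has zero variance")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))
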