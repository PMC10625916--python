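"""Synthetic paired-omics generator with planted co-expression modules.

Two feature-by-sample layers share the same samples. k_true latent sample
profiles define the modules: every feature assigned to module m, in either
layer, is signal_strength * profile_m plus Gaussian noise; background
features are pure noise. A configurable fraction of each layer-1 module's
features carries identifiers that also appear in the corresponding layer-2
module, so both the cross-layer network R12 and cross-layer module
similarity carry real signal. Each feature row is shifted by its minimum
plus 0.1 (rather than clipped) to enforce non-negativity without altering
correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import NetworkTriple, OmicsMatrix

__all__ = [
    "SyntheticTruth",
    "generate_planted_multiomics",
    "score_recovery",
    "random_network_triple",
    "truth_module_sets",
]

MIN_MODULE_SIZE = 5


@dataclass
class SyntheticTruth:
    """Planted module labels (0 = background) and generation parameters."""

    layer1_assignments: np.ndarray
    layer2_assignments: np.ndarray
    shared_fraction: float
    k_true: int
    signal_strength: float
    noise_sd: float
    seed: int

    def module_members(self, layer: int, m: int, feature_ids) -> set[str]:
        labels = self.layer1_assignments if layer == 1 else self.layer2_assignments
        return {feature_ids[i] for i in np.flatnonzero(labels == m)}


def _module_sizes(n: int, k_true: int) -> list[int]:
    """Half the features carry signal, split evenly over the k_true modules."""
    size = max(MIN_MODULE_SIZE, (n // 2) // k_true)
    return [size] * k_true


def generate_planted_multiomics(
    n1: int = 200,
    n2: int = 300,
    n_samples: int = 60,
    k_true: int = 4,
    shared_fraction: float = 0.5,
    signal_strength: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 7,
) -> tuple[OmicsMatrix, OmicsMatrix, SyntheticTruth]:
    """Simulate two omics layers with partially shared planted modules.

    Parameters
    ----------
    n1, n2 : int
        Feature counts of the two layers; each must be >= 10 * k_true.
    n_samples : int
        Shared sample count, >= 10.
    k_true : int
        Number of planted modules per layer.
    shared_fraction : float in [0, 1]
        Fraction of each layer-1 module's features given identifiers that
        also label a member of the matching layer-2 module.
    signal_strength : float > 0
        Multiplier on the latent module profile.
    noise_sd : float >= 0
        Standard deviation of the additive Gaussian noise.
    seed : int
        Seeds the generator; identical seeds give identical outputs.
    """
    if n1 < 10 * k_true or n2 < 10 * k_true:
        raise ValueError("need n1, n2 >= 10 * k_true")
    if n_samples < 10:
        raise ValueError("need n_samples >= 10")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    if signal_strength <= 0:
        raise ValueError("signal_strength must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    profiles = rng.standard_normal((k_true, n_samples))

    def build_layer(n: int) -> tuple[np.ndarray, np.ndarray]:
        labels = np.zeros(n, dtype=int)
        start = 0
        for m, size in enumerate(_module_sizes(n, k_true), start=1):
            labels[start : start + size] = m
            start += size
        values = rng.normal(scale=noise_sd, size=(n, n_samples))
        for m in range(1, k_true + 1):
            members = labels == m
            values[members] += signal_strength * profiles[m - 1]
        # shift each feature to non-negative without touching correlations
        values = values - values.min(axis=1, keepdims=True) + 0.1
        return values, labels

    values1, labels1 = build_layer(n1)
    values2, labels2 = build_layer(n2)

    ids1 = [f"f1_{i}" for i in range(n1)]
    ids2 = [f"f2_{i}" for i in range(n2)]
    for m in range(1, k_true + 1):
        idx1 = np.flatnonzero(labels1 == m)
        idx2 = np.flatnonzero(labels2 == m)
        n_shared = int(round(shared_fraction * len(idx1)))
        n_shared = min(n_shared, len(idx2))
        for a, b in zip(idx1[:n_shared], idx2[:n_shared]):
            shared_id = f"shared_m{m}_{b}"
            ids1[a] = shared_id
            ids2[b] = shared_id

    X1 = OmicsMatrix(values1, ids1, [f"s{j}" for j in range(n_samples)], "layer1")
    X2 = OmicsMatrix(values2, ids2, [f"s{j}" for j in range(n_samples)], "layer2")
    truth = SyntheticTruth(
        layer1_assignments=labels1,
        layer2_assignments=labels2,
        shared_fraction=shared_fraction,
        k_true=k_true,
        signal_strength=signal_strength,
        noise_sd=noise_sd,
        seed=seed,
    )
    return X1, X2, truth


def truth_module_sets(truth: SyntheticTruth, layer: int, feature_ids) -> list[set[str]]:
    """Planted modules of one layer as sets of feature identifiers."""
    return [
        truth.module_members(layer, m, list(feature_ids))
        for m in range(1, truth.k_true + 1)
    ]


def score_recovery(truth: SyntheticTruth, found, layer: int, feature_ids) -> float:
    """Best-match Jaccard between planted and found modules, averaged.

    For each planted module the best-matching found module is scored by
    Jaccard index |intersection| / |union|; the mean over planted modules
    lies in [0, 1].
    """
    planted = truth_module_sets(truth, layer, feature_ids)
    found_modules = found.modules if hasattr(found, "modules") else list(found)
    scores = []
    for P in planted:
        best = 0.0
        for F in found_modules:
            union = len(P | F)
            if union:
                best = max(best, len(P & F) / union)
        scores.append(best)
    return float(np.mean(scores))


def random_network_triple(
    n1: int, n2: int, n_samples: int = 30, seed: int = 0
) -> NetworkTriple:
    """Unstructured correlation networks from i.i.d. Gaussian data.

    Convenience for fuzz and monotonicity tests: builds |Pearson| networks
    from random data so the triple satisfies all NetworkTriple invariants.
    """
    from .networks import build_network_triple

    rng = np.random.default_rng(seed)
    X1 = OmicsMatrix(
        np.abs(rng.standard_normal((n1, n_samples))) + 0.01,
        [f"a{i}" for i in range(n1)],
        [f"s{j}" for j in range(n_samples)],
        "rand1",
    )
    X2 = OmicsMatrix(
        np.abs(rng.standard_normal((n2, n_samples))) + 0.01,
        [f"b{i}" for i in range(n2)],
        [f"s{j}" for j in range(n_samples)],
        "rand2",
    )
    return build_network_triple(X1, X2)
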