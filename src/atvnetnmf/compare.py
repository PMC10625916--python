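"""Variant comparison by reconstruction correlation.

Runs the four factorization variants (plain netNMF, graph-regularized
NMFNA, TV-only netNMF+ATV, and the full ATV-netNMF) over seeds and reports
the Pearson correlation between each input network and its reconstruction —
the benchmark layout used to compare the variants.
"""

from __future__ import annotations

import pandas as pd

from .containers import NetworkTriple
from .factorization import ATVNetNMF, VARIANTS

__all__ = ["compare_variants", "summarize_comparison"]


def compare_variants(
    nets: NetworkTriple,
    variants=None,
    seeds=(0,),
    *,
    n_components: int = 8,
    laplacians=None,
    **estimator_params,
) -> pd.DataFrame:
    """Tidy table of reconstruction correlations per variant x seed x matrix.

    Factorization failures are recorded as rows with ``error`` set and NaN
    correlation; the remaining cells still run.
    """
    variants = list(VARIANTS) if variants is None else list(variants)
    unknown = [v for v in variants if v not in VARIANTS]
    if unknown:
        raise ValueError(f"unknown variants: {unknown}")
    rows = []
    for variant in variants:
        for seed in seeds:
            try:
                model = ATVNetNMF.from_variant(
                    variant,
                    n_components=n_components,
                    random_state=seed,
                    **estimator_params,
                )
                model.fit(nets, laplacians=laplacians if model.graph else None)
                corrs = model.reconstruction_correlations(nets)
                for matrix, corr in corrs.items():
                    rows.append(
                        {
                            "variant": variant,
                            "seed": seed,
                            "matrix": matrix,
                            "correlation": corr,
                            "error": "",
                        }
                    )
            except Exception as exc:  # keep other cells running
                for matrix in ("R11", "R12", "R22"):
                    rows.append(
                        {
                            "variant": variant,
                            "seed": seed,
                            "matrix": matrix,
                            "correlation": float("nan"),
                            "error": str(exc),
                        }
                    )
    return pd.DataFrame(rows)


def summarize_comparison(tidy: pd.DataFrame) -> pd.DataFrame:
    """Per-variant mean correlation for each matrix (variant x matrix table)."""
    ok = tidy[tidy["error"] == ""]
    return (
        ok.pivot_table(
            index="matrix", columns="variant", values="correlation", aggfunc="mean"
        )
        .rename_axis(None, axis=1)
        .rename_axis("matrix")
    )
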