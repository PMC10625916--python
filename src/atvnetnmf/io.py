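"""Delimited-text readers and writers for matrices, networks and factors.

Exchange format: TSV (CSV accepted) with feature identifiers in the first
column and sample identifiers in the header row. Networks can also be
stored as a compressed ``.npz`` archive to avoid quadratic text files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import NetworkTriple, OmicsMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_networks",
    "write_networks",
    "write_factors",
    "write_trace",
    "write_metadata",
]

_SEPS = {"tsv": "\t", "csv": ","}


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in _SEPS:
        raise ValueError(f"fmt must be one of {sorted(_SEPS)}, got {fmt!r}")
    return _SEPS[fmt]


def read_matrix(path, fmt: str | None = None, layer_name: str | None = None) -> OmicsMatrix:
    """Read a feature x sample matrix from delimited text.

    The header row holds sample IDs and the first column feature IDs.
    Negative, non-finite or non-numeric entries are rejected with their
    coordinates (1-based, in the data block) in the message.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep_for(path, fmt), index_col=0, float_precision="round_trip"
    )
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate feature or sample identifiers")
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries present")
    bad = np.argwhere(~np.isfinite(values) | (values < 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: invalid entry {values[i, j]!r} at row {i + 1}, "
            f"column {j + 1} (feature {df.index[i]!r}, sample {df.columns[j]!r})"
        )
    return OmicsMatrix(
        values=values,
        feature_ids=[str(x) for x in df.index],
        sample_ids=[str(x) for x in df.columns],
        layer_name=layer_name or path.stem,
    )


def write_matrix(X: OmicsMatrix, path, fmt: str | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame(X.values, index=X.feature_ids, columns=X.sample_ids)
    df.to_csv(path, sep=_sep_for(path, fmt), float_format="%.17g")
    return path


def write_networks(nets: NetworkTriple, out_dir, compress: bool = False) -> Path:
    """Write R11/R12/R22 as labeled TSVs, or a single .npz when ``compress``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if compress:
        target = out_dir / "networks.npz"
        np.savez_compressed(
            target,
            R11=nets.R11,
            R12=nets.R12,
            R22=nets.R22,
            ids1=np.array(nets.ids1),
            ids2=np.array(nets.ids2),
        )
        return target
    for name, mat, rows, cols in (
        ("R11", nets.R11, nets.ids1, nets.ids1),
        ("R12", nets.R12, nets.ids1, nets.ids2),
        ("R22", nets.R22, nets.ids2, nets.ids2),
    ):
        pd.DataFrame(mat, index=rows, columns=cols).to_csv(
            out_dir / f"{name}.tsv", sep="\t", float_format="%.17g"
        )
    return out_dir


def read_networks(path) -> NetworkTriple:
    """Read a network triple written by :func:`write_networks`."""
    path = Path(path)
    npz = path if path.suffix == ".npz" else path / "networks.npz"
    if npz.exists():
        with np.load(npz, allow_pickle=False) as data:
            return NetworkTriple(
                R11=data["R11"],
                R12=data["R12"],
                R22=data["R22"],
                ids1=[str(x) for x in data["ids1"]],
                ids2=[str(x) for x in data["ids2"]],
            )
    frames = {
        name: pd.read_csv(
            path / f"{name}.tsv",
            sep="\t",
            index_col=0,
            float_precision="round_trip",
        )
        for name in ("R11", "R12", "R22")
    }
    return NetworkTriple(
        R11=frames["R11"].to_numpy(),
        R12=frames["R12"].to_numpy(),
        R22=frames["R22"].to_numpy(),
        ids1=[str(x) for x in frames["R11"].index],
        ids2=[str(x) for x in frames["R22"].index],
    )


def write_factors(state, ids1, ids2, out_dir) -> Path:
    """Write G1/G2/S11/S22 as labeled TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    k = state.G1.shape[1]
    comp = [f"c{j}" for j in range(k)]
    pd.DataFrame(state.G1, index=ids1, columns=comp).to_csv(
        out_dir / "G1.tsv", sep="\t", float_format="%.17g"
    )
    pd.DataFrame(state.G2, index=ids2, columns=comp).to_csv(
        out_dir / "G2.tsv", sep="\t", float_format="%.17g"
    )
    pd.DataFrame(state.S11, index=comp, columns=comp).to_csv(
        out_dir / "S11.tsv", sep="\t", float_format="%.17g"
    )
    pd.DataFrame(state.S22, index=comp, columns=comp).to_csv(
        out_dir / "S22.tsv", sep="\t", float_format="%.17g"
    )
    return out_dir


def write_trace(trace, out_path) -> Path:
    out_path = Path(out_path)
    pd.DataFrame(
        {"iteration": np.arange(1, len(trace) + 1), "objective": trace}
    ).to_csv(out_path, sep="\t", index=False)
    return out_path


def write_metadata(out_path, **fields) -> Path:
    """JSON sidecar echoing the run configuration for reproducibility."""
    import atvnetnmf

    out_path = Path(out_path)
    payload = {"package": "atvnetnmf", "version": atvnetnmf.__version__}
    payload.update(fields)
    out_path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return out_path
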