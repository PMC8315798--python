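"""Delimited-text I/O for brain maps and labeled matrices.

Brain maps are two-column files (label, value) and matrices are square
tables with a shared label header row and index column. Labels are the
only cross-file join key; positional order on disk is not significant.
Values round-trip losslessly to full double precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import StructuralConnectome
from .metrics import BrainMap

__all__ = [
    "read_brain_map",
    "write_brain_map",
    "read_matrix",
    "write_matrix",
    "read_connectome",
]


def _sep(path: Path) -> str:
    return "\t" if path.suffix in {".tsv", ".tab"} else ","


def read_brain_map(path: str | Path) -> BrainMap:
    """Read a (label, value) delimited file into a BrainMap."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype={0: str}, float_precision="round_trip")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (label, value)")
    labels = df.iloc[:, 0].tolist()
    dupes = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()
    if dupes:
        first_bad = dupes[0]
        line = labels.index(first_bad, labels.index(first_bad) + 1) + 2
        raise ValueError(f"{path}: duplicate label {first_bad!r} at line {line}")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = np.where(vals.isna() & df.iloc[:, 1].notna())[0]
    if bad.size or vals.isna().any():
        row = int((np.where(vals.isna())[0])[0])
        raise ValueError(f"{path}: non-numeric value at line {row + 2}")
    return BrainMap(values=vals.to_numpy(dtype=float), labels=labels)


def write_brain_map(map_: BrainMap, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"label": map_.labels, "value": map_.values})
    df.to_csv(path, sep=_sep(path), index=False, float_format="%.17g")


def read_matrix(path: str | Path, require_symmetric: bool = False) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square matrix; returns (values, labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({df.shape[0]} x {df.shape[1]})")
    labels = [str(x) for x in df.index]
    if labels != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column labels disagree")
    M = df.to_numpy(dtype=float)
    if require_symmetric and not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{path}: matrix is not symmetric")
    return M, labels


def write_matrix(M: np.ndarray, labels: list[str], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(np.asarray(M, dtype=float), index=labels, columns=labels)
    df.to_csv(path, sep=_sep(path), float_format="%.17g")


def read_connectome(
    weights_path: str | Path, distances_path: str | Path | None = None
) -> StructuralConnectome:
    """Load raw weights (and optional distances), normalize, align by label."""
    W, labels = read_matrix(weights_path)
    D = None
    if distances_path is not None:
        D, dlabels = read_matrix(distances_path, require_symmetric=True)
        if dlabels != labels:
            order = [dlabels.index(lab) for lab in labels]
            D = D[np.ix_(order, order)]
    return StructuralConnectome.from_weights(W, labels=labels, D=D)
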