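"""Readers and writers for count matrices, coordinates and result tables.

Counts are accepted either as a Matrix-Market triplet file with companion
gene/spot ID text files (one id per line) or as a dense delimited table with
gene ids in the first column and spot ids in the header. Coordinates are a
delimited table with columns (spot_id, x, y). All outputs are TSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .preprocess import ExpressionMatrix

__all__ = [
    "read_counts", "write_counts", "read_coords", "write_coords",
    "read_domains", "write_results",
]


def _read_ids(path: Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_counts(
    path: str | Path,
    gene_ids: str | Path | None = None,
    spot_ids: str | Path | None = None,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Load a genes-by-spots count matrix.

    ``.mtx`` input requires the two companion ID files; anything else is
    parsed as a dense delimited table (header row = spot ids, first column =
    gene ids). Entries must be non-negative integers.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if gene_ids is None or spot_ids is None:
            raise ValueError("Matrix-Market input needs gene_ids and spot_ids files")
        try:
            m = mmread(path)
        except ValueError as e:
            raise ValueError(f"malformed Matrix-Market file {path}: {e}") from e
        arr = np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=float)
        genes = _read_ids(gene_ids)
        spots = _read_ids(spot_ids)
        if arr.shape != (len(genes), len(spots)):
            raise ValueError(
                f"matrix shape {arr.shape} does not match "
                f"{len(genes)} gene ids x {len(spots)} spot ids"
            )
    else:
        df = pd.read_csv(path, sep=sep, index_col=0)
        arr = df.to_numpy(dtype=float)
        genes = [str(g) for g in df.index]
        spots = [str(s) for s in df.columns]
    if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
        raise ValueError("counts must be non-negative integers")
    return ExpressionMatrix(arr, genes, spots, layer_tag="counts")


def write_counts(mat: ExpressionMatrix, path: str | Path, sparse: bool = False) -> None:
    """Write a matrix as dense TSV, or as .mtx plus <stem>.genes.txt /
    <stem>.spots.txt when ``sparse=True``."""
    path = Path(path)
    if sparse:
        mmwrite(path.with_suffix(".mtx"), coo_matrix(mat.values))
        path.with_suffix(".genes.txt").write_text("\n".join(mat.gene_ids) + "\n")
        path.with_suffix(".spots.txt").write_text("\n".join(mat.spot_ids) + "\n")
        return
    df = pd.DataFrame(mat.values, index=mat.gene_ids, columns=mat.spot_ids)
    if mat.layer_tag == "counts":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_coords(path: str | Path, spot_ids: list[str], sep: str = "\t") -> np.ndarray:
    """Load spot coordinates and order them to match ``spot_ids``.

    Expects columns (spot_id, x, y); extra columns are ignored with a
    warning. The file's spot id set must equal the expression matrix's.
    """
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValueError("coordinate file needs columns (spot_id, x, y)")
    if df.shape[1] > 3:
        warnings.warn(f"ignoring extra columns {list(df.columns[3:])}", stacklevel=2)
    df = df.iloc[:, :3]
    df.columns = ["spot_id", "x", "y"]
    df["spot_id"] = df["spot_id"].astype(str)
    if df["spot_id"].duplicated().any():
        dups = df.loc[df["spot_id"].duplicated(), "spot_id"].head(5).tolist()
        raise ValueError(f"duplicated spot_id(s): {dups}")
    file_ids = set(df["spot_id"])
    want_ids = set(spot_ids)
    missing = sorted(want_ids - file_ids)
    extra = sorted(file_ids - want_ids)
    if missing or extra:
        raise ValueError(
            f"spot id mismatch: missing {missing[:5]}, unexpected {extra[:5]}"
        )
    df = df.set_index("spot_id").loc[spot_ids]
    return df[["x", "y"]].to_numpy(dtype=float)


def write_coords(coords: np.ndarray, spot_ids: list[str], path: str | Path) -> None:
    pd.DataFrame({"spot_id": spot_ids,
                  "x": coords[:, 0], "y": coords[:, 1]}).to_csv(
        path, sep="\t", index=False)


def read_domains(path: str | Path, spot_ids: list[str], sep: str = "\t") -> np.ndarray:
    """Load per-spot domain labels (columns spot_id, domain), ordered to
    match ``spot_ids``."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("domain file needs columns (spot_id, domain)")
    df = df.iloc[:, :2]
    df.columns = ["spot_id", "domain"]
    df["spot_id"] = df["spot_id"].astype(str)
    unknown = sorted(set(df["spot_id"]) - set(spot_ids))
    if unknown:
        raise ValueError(f"unknown spot id(s) in domain file: {unknown[:5]}")
    missing = sorted(set(spot_ids) - set(df["spot_id"]))
    if missing:
        raise ValueError(f"spot id(s) missing from domain file: {missing[:5]}")
    return df.set_index("spot_id").loc[spot_ids, "domain"].to_numpy()


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
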