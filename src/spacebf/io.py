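"""Data ingestion: expression matrices, coordinates, pair lists, filtering.

Expression matrices are molecules x locations, read from CSV/TSV (first
column = molecule id, header = location ids) or MatrixMarket MTX with
row/column id sidecar files (one id per line).  Coordinates come as a CSV
with columns (id, x, y); the location ids must match the matrix columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "PairList",
    "read_expression",
    "read_coords",
    "read_pairs",
    "write_expression",
    "filter_low_expression",
    "enumerate_pairs",
    "align_locations",
]


@dataclass
class ExpressionMatrix:
    values: np.ndarray                  # molecules x locations, dense
    molecule_ids: list
    location_ids: list
    dtype: str = "counts"               # counts | continuous

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if len(self.molecule_ids) != self.values.shape[0]:
            raise ValueError("molecule id count does not match the matrix")
        if len(self.location_ids) != self.values.shape[1]:
            raise ValueError("location id count does not match the matrix")
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            raise ValueError("molecule ids must be unique")
        if len(set(self.location_ids)) != len(self.location_ids):
            raise ValueError("location ids must be unique")
        if self.dtype == "counts" and np.any(self.values < 0):
            raise ValueError("negative values in a counts matrix")

    @property
    def n_locations(self) -> int:
        return self.values.shape[1]

    def get(self, molecule_id) -> np.ndarray:
        try:
            i = self.molecule_ids.index(molecule_id)
        except ValueError as exc:
            raise KeyError(f"molecule {molecule_id!r} not in the matrix") from exc
        return self.values[i]


@dataclass
class PairList:
    """Ordered (predictor m', outcome m) molecule pairs."""

    pairs: list = field(default_factory=list)
    source: str = ""

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def read_expression(path, fmt: str | None = None,
                    dtype: str = "counts") -> ExpressionMatrix:
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "csv")
    if fmt == "mtx":
        m = scipy.io.mmread(str(path))
        if sp.issparse(m):
            m = m.toarray()
        rows = _read_ids(path.with_suffix(".rows.txt"))
        cols = _read_ids(path.with_suffix(".cols.txt"))
        return ExpressionMatrix(np.asarray(m), rows, cols, dtype)
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(df.to_numpy(), list(df.index.astype(str)),
                            list(df.columns.astype(str)), dtype)


def _read_ids(path: Path) -> list:
    if not path.exists():
        raise FileNotFoundError(
            f"MTX id sidecar {path} not found (expected one id per line)")
    return path.read_text().split()


def write_expression(mat: ExpressionMatrix, path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(mat.values))
        path.with_suffix(".rows.txt").write_text("\n".join(map(str, mat.molecule_ids)) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(map(str, mat.location_ids)) + "\n")
        return
    sep = "\t" if fmt == "tsv" else ","
    pd.DataFrame(mat.values, index=mat.molecule_ids,
                 columns=mat.location_ids).to_csv(path, sep=sep)


def read_coords(path) -> pd.DataFrame:
    """CSV with columns (id, x, y); returns a DataFrame indexed by id."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("id", "x", "y") if c not in cols]
    if missing:
        raise ValueError(f"coordinate file missing columns: {missing}")
    out = df[[cols["id"], cols["x"], cols["y"]]].copy()
    out.columns = ["id", "x", "y"]
    out["id"] = out["id"].astype(str)
    if out["id"].duplicated().any():
        raise ValueError("duplicate location ids in the coordinate file")
    return out.set_index("id")


def read_pairs(path) -> PairList:
    """TSV with two columns: predictor (m', e.g. ligand) then outcome (m)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("pair file needs two tab-separated columns")
    pairs = [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
    return PairList(pairs, source=str(path))


def align_locations(mat: ExpressionMatrix, coords: pd.DataFrame) -> np.ndarray:
    """Coordinates reordered to the matrix's location ids; error on mismatch."""
    missing = [i for i in mat.location_ids if i not in coords.index]
    if missing:
        raise ValueError(
            "locations missing from the coordinate table: "
            + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else ""))
    return coords.loc[mat.location_ids, ["x", "y"]].to_numpy(dtype=float)


def filter_low_expression(mat: ExpressionMatrix, frac: float = 0.2):
    """Drop molecules with total count < frac * n_locations (strict).

    At n = 293 and frac = 0.2 the threshold is 58.6, so a total of exactly
    59 reads survives while 58 is dropped.
    """
    if frac < 0:
        raise ValueError("frac must be nonnegative")
    if mat.dtype != "counts":
        raise ValueError("low-expression filtering applies to counts data")
    totals = mat.values.sum(axis=1)
    thr = frac * mat.n_locations
    keep = totals >= thr
    dropped = [(mid, float(t)) for mid, t, k in
               zip(mat.molecule_ids, totals, keep) if not k]
    kept = ExpressionMatrix(mat.values[keep],
                            [m for m, k in zip(mat.molecule_ids, keep) if k],
                            mat.location_ids, mat.dtype)
    return kept, dropped


def enumerate_pairs(type_a, type_b=None) -> PairList:
    """Molecule pairs to test.

    Bipartite mode (``type_b`` given): all |A| x |B| ordered pairs with the
    A member as the predictor m'.  All-pairs mode: C(n, 2) unordered pairs
    oriented so the lexicographically smaller id is the predictor (the NB
    regression is asymmetric, so the orientation rule must be fixed).
    """
    a = list(dict.fromkeys(type_a))
    if not a:
        raise ValueError("empty molecule list")
    if type_b is None:
        pairs = [(x, y) if str(x) < str(y) else (y, x)
                 for i, x in enumerate(a) for y in a[i + 1:]]
        return PairList(pairs, source="all-pairs")
    b = list(dict.fromkeys(type_b))
    if not b:
        raise ValueError("empty molecule list")
    overlap = set(a) & set(b)
    if overlap:
        warnings.warn(f"molecules in both lists: {sorted(overlap)}", stacklevel=2)
    return PairList([(x, y) for x in a for y in b], source="bipartite")
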