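"""Delimited-text readers and writers for matrices and partitions.

Conventions: time-series files have rows = time points and columns = nodes
(auto-transposing is deliberately refused — a silently transposed matrix is
a worse failure than an error); matrices are written with 17 significant
digits so a read-back reproduces the values bit for bit; missing entries
are serialized as ``NA``; node indices in edge lists are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_timeseries",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_edge_list",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.17g"


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in first else ","


def read_timeseries(
    path: str | Path,
    delimiter: str | None = None,
    has_header: bool | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Read a T x M node time-series table.

    Returns ``(values, node_names)``; names come from the header when one is
    present, otherwise ``n1..nM`` are generated.  ``has_header=None``
    auto-detects by attempting to parse the first row as numbers.  Ragged or
    non-numeric rows raise errors naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: file is empty")
    delim = delimiter or _sniff_delimiter(path)
    rows = [ln.split(delim) for ln in lines]
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        for k, r in enumerate(rows):
            if len(r) != len(rows[0]):
                raise ValueError(f"{path}: ragged row at line {k + 1} "
                                 f"({len(r)} fields, expected {len(rows[0])})")
    def _is_numeric_row(r: list[str]) -> bool:
        try:
            [float(x) for x in r]
            return True
        except ValueError:
            return False

    if has_header is None:
        has_header = not _is_numeric_row(rows[0])
    if has_header:
        names = [c.strip() for c in rows[0]]
        data_rows = rows[1:]
        offset = 2
    else:
        names = [f"n{j + 1}" for j in range(len(rows[0]))]
        data_rows = rows
        offset = 1
    if not data_rows:
        raise ValueError(f"{path}: no data rows")
    values = np.empty((len(data_rows), len(names)))
    for k, r in enumerate(data_rows):
        for j, cell in enumerate(r):
            try:
                values[k, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at line {k + offset}, "
                    f"column {j + 1}"
                ) from None
    return values, names


def write_matrix(
    matrix: np.ndarray,
    path: str | Path,
    labels: list[str] | None = None,
    delimiter: str = ",",
) -> None:
    """Write a labeled square matrix; NaN entries become ``NA``.

    Values are printed with 17 significant digits so that reading the file
    back reproduces them exactly.
    """
    matrix = np.asarray(matrix, dtype=float)
    M = matrix.shape[0]
    if labels is None:
        labels = [f"n{j + 1}" for j in range(M)]
    if len(labels) != M:
        raise ValueError(f"{len(labels)} labels for a {M}-node matrix")
    if np.any(np.isinf(matrix)):
        raise ValueError("matrix contains non-finite (infinite) entries")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(["node"] + list(labels)) + "\n")
        for i in range(M):
            cells = [labels[i]] + [
                "NA" if np.isnan(v) else _FLOAT_FMT % v for v in matrix[i]
            ]
            fh.write(delimiter.join(cells) + "\n")


def read_matrix(
    path: str | Path, delimiter: str | None = None
) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square matrix written by :func:`write_matrix`."""
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, index_col=0, na_values=["NA"],
                     keep_default_na=False, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def read_partition(path: str | Path, delimiter: str | None = None):
    """Read a node -> module table (two columns: node, module).

    Returns a :class:`~climenet.compare.ModulePartition` with nodes in file
    order.
    """
    from .compare import ModulePartition

    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, header=None, comment="#",
                     names=["node", "module"], dtype=str, skipinitialspace=True)
    first = df.iloc[0]
    if first["node"].strip().lower() in ("node", "id", "node_id"):
        df = df.iloc[1:]
    return ModulePartition(node_labels=[m.strip() for m in df["module"]])


def write_edge_list(
    matrix: np.ndarray, path: str | Path, labels: list[str] | None = None
) -> None:
    """Write upper-triangle edges as TSV (node_i, node_j, value), 1-based
    node indices."""
    matrix = np.asarray(matrix, dtype=float)
    M = matrix.shape[0]
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# node indices are 1-based\nnode_i\tnode_j\tvalue\n")
        for i in range(M):
            for j in range(i + 1, M):
                v = matrix[i, j]
                cell = "NA" if np.isnan(v) else _FLOAT_FMT % v
                fh.write(f"{i + 1}\t{j + 1}\t{cell}\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
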