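"""Readers and writers: 10x-style Matrix Market directories, dense CSV/TSV,
and the result tables.

Every result file starts with comment lines (``#``) carrying the package
version, a hash of the run configuration and the seed, so runs are
self-describing.  Matrix Market coordinates are 1-based on disk per the
format standard; all in-memory indices are 0-based.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .residuals import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "write_table",
    "read_pair_list",
    "config_header",
]


def _read_ids(path: Path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return frame.iloc[:, 0].to_numpy(dtype=object)


def _find(directory: Path, names) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {names} found in {directory}")


def read_counts(path, fmt: "str | None" = None) -> CountMatrix:
    """Read raw UMI counts from an .mtx directory or a dense CSV/TSV.

    A directory must contain ``matrix.mtx`` plus ``features.tsv`` (or
    ``genes.tsv``) and ``barcodes.tsv``; orientation is inferred from the id
    list lengths, genes always end up as rows.  A CSV/TSV has gene ids in the
    first column and cell ids as the header.  Non-integer values are
    rejected: the method operates on raw counts only.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx_dir" if path.is_dir() else "csv"
    if fmt == "mtx_dir":
        mat = scipy.io.mmread(str(_find(path, ["matrix.mtx", "matrix.mtx.gz"])))
        genes = _read_ids(_find(path, ["features.tsv", "genes.tsv"]))
        cells = _read_ids(_find(path, ["barcodes.tsv"]))
        mat = sp.csr_matrix(mat)
        if mat.shape == (len(genes), len(cells)):
            pass
        elif mat.shape == (len(cells), len(genes)):
            mat = mat.T.tocsr()
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither features "
                f"({len(genes)}) x barcodes ({len(cells)}) nor its transpose"
            )
        if not np.issubdtype(mat.dtype, np.integer):
            if np.any(mat.data != np.rint(mat.data)):
                raise ValueError("non-integer matrix: raw UMI counts required")
            mat = mat.astype(np.int64)
        return CountMatrix(mat, genes, cells)
    if fmt == "csv":
        if path.stat().st_size == 0:
            raise ValueError(f"empty file: {path}")
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if np.any(values != np.rint(values)):
                raise ValueError("non-integer values: raw UMI counts required")
            values = values.astype(np.int64)
        return CountMatrix(
            values,
            frame.index.to_numpy(dtype=object),
            frame.columns.to_numpy(dtype=object),
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(counts: CountMatrix, directory, truth: "dict | None" = None) -> None:
    """Write a 10x-style triplet directory (plus optional truth.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = counts.counts if sp.issparse(counts.counts) else sp.coo_matrix(counts.counts)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.Series(list(counts.gene_ids)).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(list(counts.cell_ids)).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if truth is not None:
        (directory / "truth.json").write_text(json.dumps(truth))


def config_header(config: "dict | None", seed: "int | None" = None) -> str:
    """Comment header with version, config hash and seed."""
    cfg = {} if config is None else dict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    digest = hashlib.sha1(blob.encode()).hexdigest()[:12]
    lines = [f"# bigsur {__version__}", f"# config_hash {digest}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    for key in sorted(cfg):
        lines.append(f"# config {key}={cfg[key]}")
    return "\n".join(lines) + "\n"


_FORMATS = {
    "p_value": "{:.5e}", "q_value": "{:.5e}",
    "equivalent_pcc": "{:.4f}",
}


def write_table(
    frame: pd.DataFrame,
    path,
    config: "dict | None" = None,
    seed: "int | None" = None,
) -> None:
    """Write a result table as TSV behind a provenance comment header.

    p/q columns use scientific notation with 6 significant digits,
    equivalent PCCs 4 decimals.
    """
    path = Path(path)
    out = frame.copy()
    for col, fmt in _FORMATS.items():
        if col in out.columns:
            out[col] = [fmt.format(x) for x in out[col]]
    with open(path, "w") as fh:
        fh.write(config_header(config, seed))
        out.to_csv(fh, sep="\t", index=False)


def read_pair_list(path) -> set:
    """Two-column TSV of unordered gene pairs (reference lists such as
    paralogs or protein-protein interactions)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return {tuple(sorted((a, b))) for a, b in zip(frame[0], frame[1]) if a != b}
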