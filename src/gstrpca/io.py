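"""Readers and writers for per-slice matrices and decomposition results.

Each omic layer lives in its own file — Matrix Market (``.mtx``) or
delimited text (``.csv``/``.tsv``), feature x cell, no header — and a
decomposition is saved as one file per slice per component (L, E) plus a
JSON sidecar recording shapes and solver metadata.  Sparse inputs are
densified at load (the solver's SVDs need dense arrays); a memory estimate
is logged when that happens.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .tensor import DomainError, IrregularTensor, make_irregular

logger = logging.getLogger(__name__)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read one feature x cell matrix from .mtx, .csv or .tsv."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        m = scipy.io.mmread(path)
        if scipy.sparse.issparse(m):
            est_mb = m.shape[0] * m.shape[1] * 8 / 1e6
            logger.info(
                "densifying sparse %sx%s matrix from %s (~%.1f MB dense)",
                m.shape[0], m.shape[1], path.name, est_mb,
            )
            m = m.toarray()
        return np.asarray(m, dtype=float)
    if suffix in (".csv", ".tsv", ".txt"):
        sep = "," if suffix == ".csv" else "\t"
        return pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)
    raise DomainError(f"unsupported matrix format: {path.name}")


def load_slices(paths: Sequence[str | Path]) -> IrregularTensor:
    """Load an ordered list of per-omic files into an irregular tensor."""
    if not paths:
        raise DomainError("no input files given")
    return make_irregular([read_matrix(p) for p in paths])


def write_matrix(path: str | Path, m: np.ndarray) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m))
    elif suffix in (".csv", ".tsv"):
        sep = "," if suffix == ".csv" else "\t"
        pd.DataFrame(m).to_csv(path, sep=sep, header=False, index=False)
    else:
        raise DomainError(f"unsupported matrix format: {path.name}")


def read_labels(path: str | Path) -> np.ndarray:
    """Headerless one-label-per-line TSV; row i = cell i."""
    return pd.read_csv(path, sep="\t", header=None)[0].to_numpy()


def write_labels(path: str | Path, labels) -> None:
    pd.Series(labels).to_csv(path, sep="\t", header=False, index=False)


def save_decomposition(
    outdir: str | Path,
    L: IrregularTensor,
    E: IrregularTensor,
    metadata: dict | None = None,
    fmt: str = "csv",
) -> None:
    """Write one file per slice per component plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, t in (("L", L), ("E", E)):
        for k, s in enumerate(t.slices):
            write_matrix(outdir / f"{name}_slice{k}.{fmt}", s)
    sidecar = {
        "row_dims": L.row_dims,
        "n_cols": L.n_cols,
        "n_slices": L.n_slices,
        "format": fmt,
        **(metadata or {}),
    }
    (outdir / "decomposition.json").write_text(json.dumps(sidecar, indent=2))


def load_decomposition(outdir: str | Path) -> tuple[IrregularTensor, IrregularTensor]:
    """Read back a decomposition written by :func:`save_decomposition`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / "decomposition.json").read_text())
    k, fmt = meta["n_slices"], meta.get("format", "csv")
    comp = {}
    for name in ("L", "E"):
        comp[name] = make_irregular(
            [read_matrix(outdir / f"{name}_slice{i}.{fmt}") for i in range(k)]
        )
    return comp["L"], comp["E"]
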