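"""Expression-matrix ingestion, log2 normalization and PCA reduction.

Cells are rows everywhere in this package.  CSV/TSV files carry a header
row of gene ids and a first column of cell ids; MatrixMarket input is the
coordinate (triplet) format with companion plain-text id files (one id
per line).  Nonlinear reductions (diffusion maps, LLE, t-SNE) are
supported by supplying already-reduced coordinates — tree fitting is
agnostic to how the low-dimensional space was produced.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .tree import Dataset

__all__ = [
    "ExpressionMatrix",
    "log2_normalize",
    "reduce_pca",
    "read_matrix",
    "write_matrix",
]


@dataclasses.dataclass
class ExpressionMatrix:
    """Cells x genes numeric matrix with row and column ids."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths must match matrix shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids,
                            columns=self.gene_ids)


def log2_normalize(m: ExpressionMatrix,
                   pseudocount: float = 1.0) -> ExpressionMatrix:
    """Entrywise ``log2(count + pseudocount)``; raw counts must be
    nonnegative."""
    if np.any(m.counts < 0):
        raise ValueError("negative entries: raw counts expected")
    return ExpressionMatrix(np.log2(m.counts + pseudocount),
                            list(m.cell_ids), list(m.gene_ids))


def reduce_pca(m: ExpressionMatrix, dims: int) -> Dataset:
    """Centered PCA scores on the first ``dims`` variance-ordered
    components, with a deterministic sign convention (the
    largest-magnitude loading of each component is positive)."""
    n, g = m.counts.shape
    if not (1 <= dims <= min(n, g)):
        raise ValueError(f"dims must lie in [1, {min(n, g)}]")
    pca = PCA(n_components=dims, svd_solver="full")
    scores = pca.fit_transform(m.counts)
    # flip components so the dominant loading is positive
    flip = np.sign(pca.components_[np.arange(dims),
                                   np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return Dataset.from_array(scores * flip, m.cell_ids)


def _read_delimited(path: Path, sep: str) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ValueError(f"{path}: failed to parse: {exc}") from exc
    if not np.issubdtype(df.to_numpy().dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in matrix body")
    return ExpressionMatrix(df.to_numpy(dtype=float),
                            [str(i) for i in df.index],
                            [str(c) for c in df.columns])


def _read_mtx(path: Path) -> ExpressionMatrix:
    """MatrixMarket coordinate triplets with ``<path>.rows`` /
    ``<path>.cols`` id sidecars.  Malformed lines are reported with their
    line number."""
    rows_file = path.with_suffix(path.suffix + ".rows")
    cols_file = path.with_suffix(path.suffix + ".cols")
    for f in (rows_file, cols_file):
        if not f.exists():
            raise FileNotFoundError(f"missing id sidecar {f}")
    cell_ids = rows_file.read_text().split()
    gene_ids = cols_file.read_text().split()

    with open(path) as fh:
        lines = fh.readlines()
    body = [(i + 1, ln.strip()) for i, ln in enumerate(lines)
            if ln.strip() and not ln.lstrip().startswith("%")]
    if not body:
        raise ValueError(f"{path}: empty MatrixMarket file")
    lineno, header = body[0]
    try:
        nr, nc, nnz = (int(t) for t in header.split())
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: bad size header {header!r}") from exc
    if nr != len(cell_ids) or nc != len(gene_ids):
        raise ValueError(f"{path}: size header ({nr}x{nc}) disagrees with "
                         f"id sidecars ({len(cell_ids)}x{len(gene_ids)})")
    counts = np.zeros((nr, nc))
    if len(body) - 1 != nnz:
        raise ValueError(f"{path}: expected {nnz} entries, found {len(body) - 1}")
    for lineno, line in body[1:]:
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'row col value'")
        try:
            r, c, v = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable entry") from exc
        if not (1 <= r <= nr and 1 <= c <= nc):
            raise ValueError(
                f"{path}:{lineno}: index ({r},{c}) out of range for {nr}x{nc}")
        counts[r - 1, c - 1] = v
    return ExpressionMatrix(counts, cell_ids, gene_ids)


def read_matrix(path, format: str | None = None) -> ExpressionMatrix:
    """Load an expression matrix from ``csv``, ``tsv`` or ``mtx``
    (MatrixMarket triplet) files; the format defaults to the file
    extension."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "csv":
        return _read_delimited(path, ",")
    if format == "tsv":
        return _read_delimited(path, "\t")
    if format in ("mtx", "mtx-triplet"):
        return _read_mtx(path)
    raise ValueError(f"unknown format {format!r}")


def write_matrix(m: ExpressionMatrix, path, format: str | None = None) -> None:
    """Inverse of :func:`read_matrix` (round-trips exactly for csv/tsv)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format in ("csv", "tsv"):
        m.to_frame().to_csv(path, sep="," if format == "csv" else "\t")
        return
    if format in ("mtx", "mtx-triplet"):
        nz = np.nonzero(m.counts)
        with open(path, "w") as fh:
            fh.write("%%MatrixMarket matrix coordinate real general\n")
            fh.write(f"{m.counts.shape[0]} {m.counts.shape[1]} {len(nz[0])}\n")
            for r, c in zip(*nz):
                fh.write(f"{r + 1} {c + 1} {m.counts[r, c]:.17g}\n")
        path.with_suffix(path.suffix + ".rows").write_text(
            "\n".join(m.cell_ids) + "\n")
        path.with_suffix(path.suffix + ".cols").write_text(
            "\n".join(m.gene_ids) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")
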