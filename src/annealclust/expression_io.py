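"""Expression-matrix I/O and the minimal preprocessing feeding graph construction.

Matrices are cells x genes, read either from Matrix Market coordinate files
with ``barcodes.tsv`` / ``genes.tsv`` sidecars or from dense CSV (header row of
gene names, first column of cell barcodes).  Preprocessing is deliberately
small: library-size normalization to a fixed total per cell, ``log1p``, and a
principal-component projection with a deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .errors import MatrixIOError, PreprocessingError

__all__ = ["ExpressionMatrix", "read_matrix", "write_matrix", "normalize_and_reduce"]

NORMALIZATION_TARGET = 10_000.0


@dataclass
class ExpressionMatrix:
    """Sparse cells x genes count matrix with unique cell/gene identifiers."""

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise MatrixIOError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise MatrixIOError(
                f"{len(self.gene_ids)} gene ids for {g} matrix columns"
            )
        if len(set(self.cell_ids)) != n:
            raise MatrixIOError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise MatrixIOError("duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise MatrixIOError("negative expression entries are not allowed")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


def _read_ids(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise MatrixIOError(f"missing {what} sidecar file: {path}")
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    return ids


def read_matrix(path, format: str | None = None) -> ExpressionMatrix:
    """Read a cells x genes matrix from ``.mtx`` (plus sidecars) or ``.csv``.

    Matrix Market triplets are 1-based per the standard; scipy converts them
    to 0-based internally.  ``format`` defaults to the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise MatrixIOError(f"no such file: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise MatrixIOError(f"malformed Matrix Market file {path}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        cells = _read_ids(path.parent / "barcodes.tsv", "barcode")
        genes = _read_ids(path.parent / "genes.tsv", "gene")
        if len(cells) != mat.shape[0]:
            raise MatrixIOError(
                f"{path.parent / 'barcodes.tsv'}: {len(cells)} barcodes but the "
                f"matrix has {mat.shape[0]} rows"
            )
        if len(genes) != mat.shape[1]:
            raise MatrixIOError(
                f"{path.parent / 'genes.tsv'}: {len(genes)} genes but the "
                f"matrix has {mat.shape[1]} columns"
            )
        return ExpressionMatrix(counts=mat, cell_ids=cells, gene_ids=genes)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(
            counts=sp.csr_matrix(df.to_numpy(dtype=np.float64)),
            cell_ids=[str(c) for c in df.index],
            gene_ids=[str(g) for g in df.columns],
        )
    raise MatrixIOError(f"unsupported format {fmt!r}; expected 'mtx' or 'csv'")


def write_matrix(m: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write ``m`` as ``.mtx`` (with ``barcodes.tsv``/``genes.tsv`` sidecars) or ``.csv``."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        coo = m.counts.tocoo()
        integral = coo.nnz == 0 or np.all(coo.data == np.round(coo.data))
        scipy.io.mmwrite(path, coo.astype(np.int64) if integral else coo)
        (path.parent / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
        (path.parent / "genes.tsv").write_text("\n".join(m.gene_ids) + "\n")
        return
    if fmt == "csv":
        df = pd.DataFrame(m.counts.toarray(), index=m.cell_ids, columns=m.gene_ids)
        df.to_csv(path)
        return
    raise MatrixIOError(f"unsupported format {fmt!r}; expected 'mtx' or 'csv'")


def normalize_and_reduce(
    m: ExpressionMatrix, n_components: int = 20, seed: int = 0
) -> np.ndarray:
    """Library-size normalize, ``log1p``, project onto principal components.

    Counts are scaled so every cell totals 10,000, removing per-cell depth
    differences, then log-transformed.  The PCA uses a full (deterministic) SVD
    and fixes each component's sign so that its largest-magnitude gene loading
    is positive — without this, downstream nearest-neighbor graphs could
    differ across BLAS builds.  ``seed`` is accepted for interface stability;
    the full solver does not consume randomness.
    """
    if n_components >= min(m.n_cells, m.n_genes):
        raise PreprocessingError(
            f"n_components={n_components} must be below min(cells, genes)="
            f"{min(m.n_cells, m.n_genes)}"
        )
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = ", ".join(m.cell_ids[i] for i in zero[:10])
        raise PreprocessingError(f"cells with zero total count: {bad}")
    scaled = sp.diags(NORMALIZATION_TARGET / totals) @ m.counts
    logged = np.log1p(scaled.toarray())
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(logged)
    # sign convention: largest-|loading| gene of each component loads positively
    for c in range(n_components):
        lead = np.argmax(np.abs(pca.components_[c]))
        if pca.components_[c, lead] < 0:
            scores[:, c] *= -1.0
    return scores
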