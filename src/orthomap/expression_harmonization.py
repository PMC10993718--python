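"""Count-matrix QC, normalisation, nomenclature harmonisation and merging.

The per-cell quality gates follow the strict-inequality reading of the usual
droplet filters: a barcode is removed when it has fewer than ``min_genes`` or
more than ``max_genes`` detected genes, fewer than ``min_counts`` or more
than ``max_counts`` total counts, or more than ``max_mito_pct`` percent of
counts on mitochondrial genes — boundary-equal cells are kept.

``harmonize_genes`` rewrites one species' matrix into the unified (source
species) nomenclature using a bijective ortholog table, after which
``merge_species`` concatenates the two species into one joint object.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import ConfigurationError, IntegrityError
from .ortholog_assignment import OrthologTable

#: Default mitochondrial symbol patterns (human ``MT-``, mouse ``mt-``).
DEFAULT_MITO_PATTERNS: tuple[str, ...] = (r"^MT-", r"^mt-")

_META_COLUMNS = ("sample", "species", "condition")


@dataclass
class CellMatrix:
    """genes × cells counts (sparse or dense) with per-cell metadata."""

    counts: sp.spmatrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = self.counts.tocsr()
        else:
            self.counts = np.asarray(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise IntegrityError(
                f"label/matrix shape mismatch: {self.counts.shape} vs "
                f"{len(self.gene_ids)} genes, {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise IntegrityError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise IntegrityError("cell_ids are not unique")
        self.cell_meta = self.cell_meta.reindex(self.cell_ids)
        for col in _META_COLUMNS:
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = ""

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        return (
            self.counts.toarray() if sp.issparse(self.counts) else self.counts
        )

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        idx = np.flatnonzero(mask)
        kept = [self.cell_ids[i] for i in idx]
        return CellMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=kept,
            cell_meta=self.cell_meta.iloc[idx].copy(),
        )

    def subset_genes(self, indices: np.ndarray, new_names: list[str] | None = None) -> "CellMatrix":
        names = (
            [self.gene_ids[i] for i in indices] if new_names is None else new_names
        )
        return CellMatrix(
            counts=self.counts[indices, :],
            gene_ids=names,
            cell_ids=list(self.cell_ids),
            cell_meta=self.cell_meta.copy(),
        )

    def to_anndata(self):
        """cells × genes AnnData view (copies the data)."""
        import anndata as ad

        X = self.counts.T.tocsr() if sp.issparse(self.counts) else self.counts.T.copy()
        return ad.AnnData(
            X=X,
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 300
    max_genes: int = 6000
    min_counts: int = 500
    max_counts: int = 15000
    max_mito_pct: float = 5.0

    def __post_init__(self) -> None:
        if not (self.min_genes < self.max_genes and self.min_counts < self.max_counts):
            raise ConfigurationError("QC minima must be below maxima")
        if not 0.0 <= self.max_mito_pct <= 100.0:
            raise ConfigurationError("max_mito_pct must be within [0, 100]")


def compute_qc(
    m: CellMatrix, mito_patterns: tuple[str, ...] = DEFAULT_MITO_PATTERNS
) -> pd.DataFrame:
    """Per-cell QC table with columns ``n_genes``, ``n_counts``, ``mito_pct``."""
    try:
        compiled = [re.compile(p) for p in mito_patterns]
    except re.error as exc:
        raise ConfigurationError(f"invalid mitochondrial pattern: {exc}")
    X = m.counts
    if sp.issparse(X):
        n_genes = np.asarray((X > 0).sum(axis=0)).ravel()
        n_counts = np.asarray(X.sum(axis=0)).ravel()
    else:
        n_genes = (X > 0).sum(axis=0)
        n_counts = X.sum(axis=0)
    mito_rows = np.array(
        [any(c.search(g) for c in compiled) for g in m.gene_ids], dtype=bool
    )
    if mito_rows.any():
        sub = X[np.flatnonzero(mito_rows), :]
        mito_counts = (
            np.asarray(sub.sum(axis=0)).ravel() if sp.issparse(sub) else sub.sum(axis=0)
        )
    else:
        mito_counts = np.zeros(m.n_cells)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_pct = np.where(n_counts > 0, 100.0 * mito_counts / n_counts, 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes.astype(int), "n_counts": n_counts, "mito_pct": mito_pct},
        index=pd.Index(m.cell_ids, name="cell_id"),
    )


def apply_qc(
    m: CellMatrix,
    thresholds: QCThresholds = QCThresholds(),
    qc: pd.DataFrame | None = None,
) -> CellMatrix:
    """Drop cells violating any gate; boundary-equal cells are kept."""
    if qc is None:
        qc = compute_qc(m)
    if list(qc.index) != list(m.cell_ids):
        raise IntegrityError("QC table rows do not match the matrix cells")
    t = thresholds
    keep = (
        (qc["n_genes"] >= t.min_genes)
        & (qc["n_genes"] <= t.max_genes)
        & (qc["n_counts"] >= t.min_counts)
        & (qc["n_counts"] <= t.max_counts)
        & (qc["mito_pct"] <= t.max_mito_pct)
    ).to_numpy()
    return m.subset_cells(keep)


def qc_removal_report(
    qc: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> dict[str, int]:
    """Number of cells violating each gate (a cell may violate several)."""
    t = thresholds
    return {
        "low_genes": int((qc["n_genes"] < t.min_genes).sum()),
        "high_genes": int((qc["n_genes"] > t.max_genes).sum()),
        "low_counts": int((qc["n_counts"] < t.min_counts).sum()),
        "high_counts": int((qc["n_counts"] > t.max_counts).sum()),
        "high_mito": int((qc["mito_pct"] > t.max_mito_pct).sum()),
        "removed": int(
            (
                (qc["n_genes"] < t.min_genes)
                | (qc["n_genes"] > t.max_genes)
                | (qc["n_counts"] < t.min_counts)
                | (qc["n_counts"] > t.max_counts)
                | (qc["mito_pct"] > t.max_mito_pct)
            ).sum()
        ),
    }


def lognormalize(m: CellMatrix, scale: float = 10_000.0) -> CellMatrix:
    """Library-size normalisation to *scale* counts per cell, then ln(1 + x)."""
    X = m.counts
    totals = (
        np.asarray(X.sum(axis=0)).ravel() if sp.issparse(X) else X.sum(axis=0)
    ).astype(float)
    if np.any(totals == 0):
        raise ValueError(
            "matrix contains all-zero cells; apply QC before normalising"
        )
    if sp.issparse(X):
        Xn = X.tocsc(copy=True).astype(float)
        Xn = Xn.multiply(scale / totals[np.newaxis, :]).tocsr()
        Xn.data = np.log1p(Xn.data)
    else:
        Xn = np.log1p(X.astype(float) * (scale / totals[np.newaxis, :]))
    return CellMatrix(
        counts=Xn,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        cell_meta=m.cell_meta.copy(),
    )


def harmonize_genes(
    m: CellMatrix, table: OrthologTable, side: str = "target"
) -> CellMatrix:
    """Rewrite *m* into the unified (source-species) nomenclature.

    ``side`` names which side of the table the matrix belongs to.  Genes not
    covered by the table are dropped.  For a target-side matrix the surviving
    genes are renamed to the source symbol; a source-side matrix keeps its
    names and is merely filtered.
    """
    if side not in ("source", "target"):
        raise ConfigurationError("side must be 'source' or 'target'")
    if side == "target":
        rename = {p.target_symbol: p.source_symbol for p in table.pairs}
    else:
        rename = {p.source_symbol: p.source_symbol for p in table.pairs}
    indices: list[int] = []
    names: list[str] = []
    seen: set[str] = set()
    for i, g in enumerate(m.gene_ids):
        new = rename.get(g)
        if new is None:
            continue
        if new in seen:
            warnings.warn(f"duplicate harmonised gene name {new!r}; keeping first")
            continue
        seen.add(new)
        indices.append(i)
        names.append(new)
    if not indices:
        warnings.warn("no genes of the matrix are covered by the ortholog table")
    return m.subset_genes(np.array(indices, dtype=int), new_names=names)


def merge_species(a: CellMatrix, b: CellMatrix) -> CellMatrix:
    """Concatenate two harmonised matrices over their shared gene set.

    Gene order follows *a*; cell ids are prefixed with the cell's sample tag
    to keep them unique across datasets.
    """
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    a_idx = {g: i for i, g in enumerate(a.gene_ids)}
    b_idx = {g: i for i, g in enumerate(b.gene_ids)}
    a_sub = a.subset_genes(np.array([a_idx[g] for g in shared], dtype=int))
    b_sub = b.subset_genes(np.array([b_idx[g] for g in shared], dtype=int))

    def _prefixed(m: CellMatrix) -> list[str]:
        samples = m.cell_meta["sample"].astype(str).tolist()
        return [f"{s}:{c}" for s, c in zip(samples, m.cell_ids)]

    cells = _prefixed(a_sub) + _prefixed(b_sub)
    if len(set(cells)) != len(cells):
        raise IntegrityError("duplicate cell ids after sample prefixing")
    if sp.issparse(a_sub.counts) or sp.issparse(b_sub.counts):
        counts = sp.hstack(
            [sp.csr_matrix(a_sub.counts), sp.csr_matrix(b_sub.counts)]
        ).tocsr()
    else:
        counts = np.hstack([a_sub.counts, b_sub.counts])
    meta = pd.concat([a_sub.cell_meta, b_sub.cell_meta], axis=0)
    meta.index = pd.Index(cells, name="cell_id")
    return CellMatrix(
        counts=counts, gene_ids=shared, cell_ids=cells, cell_meta=meta
    )


# ---------------------------------------------------------------------------
# matrix I/O: MatrixMarket triplet + label files, or dense TSV


def write_matrix_dir(m: CellMatrix, path: str | Path) -> None:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` + ``metadata.tsv``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = m.counts
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    is_int = np.all(np.equal(np.mod(X.data, 1), 0)) if X.nnz else True
    mmwrite(
        str(path / "matrix.mtx"),
        X.tocoo(),
        field="integer" if is_int else "real",
    )
    (path / "genes.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
    (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    meta = m.cell_meta.copy()
    meta.index.name = "cell_id"
    meta.to_csv(path / "metadata.tsv", sep="\t")


def read_matrix_dir(path: str | Path) -> CellMatrix:
    path = Path(path)
    for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not (path / name).exists():
            raise IntegrityError(f"matrix directory {path} is missing {name}")
    counts = sp.csr_matrix(mmread(str(path / "matrix.mtx")))
    gene_ids = (path / "genes.tsv").read_text().splitlines()
    cell_ids = (path / "barcodes.tsv").read_text().splitlines()
    meta_path = path / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="cell_id", dtype=str)
        for col in ("cc_score",):
            if col in meta.columns:
                meta[col] = meta[col].astype(float)
    else:
        meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    return CellMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta)


def read_dense_tsv(
    matrix_path: str | Path, meta_path: str | Path | None = None
) -> CellMatrix:
    """Dense TSV alternative: genes in rows, cells in columns."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = (
        pd.read_csv(meta_path, sep="\t", index_col="cell_id", dtype=str)
        if meta_path is not None
        else pd.DataFrame(index=pd.Index(df.columns, name="cell_id"))
    )
    return CellMatrix(
        counts=sp.csr_matrix(df.to_numpy()),
        gene_ids=list(df.index),
        cell_ids=list(df.columns),
        cell_meta=meta,
    )
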