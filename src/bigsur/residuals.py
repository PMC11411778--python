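"""Corrected Pearson residuals and Fano factors for raw UMI count matrices.

Sequencing depth varies by orders of magnitude across cells, so the counts of
a gene are not draws from a single distribution.  Rather than normalizing the
counts, the expected value of gene *j* in cell *i* is given its own
depth-aware estimate

    mu_ij = (cell i total) * (gene j total) / (grand total),

and the Pearson residual is corrected cell by cell.  Biological expression
noise (lognormal with coefficient of variation ``c``) adds a second variance
component, ``(c * mu_ij)**2``, giving the modified corrected residual

    P'_ij = (x_ij - mu_ij) / sqrt(mu_ij * (1 + c**2 * mu_ij)).

The mean of squared residuals over cells is the (modified corrected) Fano
factor, phi' (phi when c = 0); for counts that are Poisson draws around a
lognormally fluctuating rate its expectation is 1 at every expression level.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "expected_values",
    "modified_residuals",
    "fano_factors",
    "estimate_c",
    "DEFAULT_C_GRID",
]

#: grid searched by :func:`estimate_c` (0.05 .. 0.80 in steps of 0.05)
DEFAULT_C_GRID = tuple(np.round(np.arange(1, 17) * 0.05, 2))


@dataclass
class CountMatrix:
    """Raw (unnormalized, un-log-transformed) UMI counts, genes x cells.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows.  Dense ``ndarray`` or any
        scipy sparse matrix; stored as given.
    gene_ids, cell_ids
        Row / column identifiers.
    """

    counts: "np.ndarray | sp.spmatrix"
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValueError("counts shape does not match id lengths")
        if n_cells < 2:
            raise ValueError("at least 2 cells are required")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        data = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if np.asarray(data).size:
            arr = np.asarray(data)
            if arr.min() < 0:
                raise ValueError("counts must be non-negative")
            if not np.issubdtype(arr.dtype, np.integer) and not np.all(
                arr == np.rint(arr)
            ):
                raise ValueError(
                    "counts must be integers: raw UMI counts are required "
                    "(normalized or transformed data are not accepted)"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self, dtype=np.float64) -> np.ndarray:
        """Counts as a dense array of the requested dtype."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=dtype)
        return np.asarray(self.counts, dtype=dtype)

    def gene_totals(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.sum(axis=1)).ravel().astype(np.float64)
        return np.asarray(self.counts, dtype=np.float64).sum(axis=1)

    def cell_totals(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.sum(axis=0)).ravel().astype(np.float64)
        return np.asarray(self.counts, dtype=np.float64).sum(axis=0)

    def cells_expressing(self) -> np.ndarray:
        """Number of cells with a nonzero count, per gene."""
        if sp.issparse(self.counts):
            return np.asarray((self.counts != 0).sum(axis=1)).ravel()
        return (np.asarray(self.counts) != 0).sum(axis=1)

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        counts = self.counts
        gene_ids, cell_ids = self.gene_ids, self.cell_ids
        if gene_mask is not None:
            counts = counts[gene_mask, :]
            gene_ids = gene_ids[gene_mask]
        if cell_mask is not None:
            counts = counts[:, cell_mask]
            cell_ids = cell_ids[cell_mask]
        return CountMatrix(counts, gene_ids, cell_ids)


def expected_values(counts: CountMatrix) -> np.ndarray:
    """Depth-aware expected counts mu_ij = gene_total * cell_total / grand_total.

    Row sums and column sums of the result equal those of the counts (the
    estimator redistributes each gene's total across cells in proportion to
    sequencing depth).  Genes or cells with zero totals yield zero rows or
    columns; they carry no information and are dropped by downstream steps.
    """
    gt = counts.gene_totals()
    ct = counts.cell_totals()
    grand = gt.sum()
    if grand <= 0:
        raise ValueError("all-zero count matrix")
    n_zero_genes = int((gt == 0).sum())
    n_zero_cells = int((ct == 0).sum())
    if n_zero_genes or n_zero_cells:
        logger.info(
            "expected_values: %d zero-total genes and %d zero-total cells "
            "produce zero expectations", n_zero_genes, n_zero_cells,
        )
    return np.outer(gt, ct) / grand


def modified_residuals(
    counts: CountMatrix, mu: np.ndarray, c: float
) -> np.ndarray:
    """Modified corrected Pearson residuals (x - mu) / sqrt(mu (1 + c^2 mu)).

    With ``c = 0`` this is the corrected Pearson residual (x - mu) / sqrt(mu).
    Entries where ``mu == 0`` must have ``x == 0`` and are set to 0.
    """
    if c < 0:
        raise ValueError("c must be non-negative")
    x = counts.dense()
    if x.shape != mu.shape:
        raise ValueError("mu shape does not match counts")
    zero = mu == 0
    if np.any(zero & (x > 0)):
        raise ValueError("mu_ij = 0 where x_ij > 0: inconsistent expected matrix")
    denom = np.sqrt(mu * (1.0 + (c * c) * mu))
    with np.errstate(invalid="ignore", divide="ignore"):
        res = (x - mu) / denom
    res[zero] = 0.0
    return res


def fano_factors(residuals: np.ndarray) -> np.ndarray:
    """Per-gene Fano factor: sum of squared residuals over (n - 1) cells."""
    n = residuals.shape[1]
    if n < 2:
        raise ValueError("need at least 2 cells")
    return np.einsum("ij,ij->i", residuals, residuals) / (n - 1)


def estimate_c(
    counts: CountMatrix,
    c_grid=DEFAULT_C_GRID,
    high_expr_threshold: float = 1.0,
) -> float:
    """Estimate the expression-noise coefficient of variation ``c``.

    Under the null, phi' should be flat in expression level.  A mis-specified
    ``c`` tilts the high-expression end of a log-log plot of phi' against mean
    expression (too small a ``c`` leaves phi' rising with the mean, too large
    a value pushes it down).  The estimate is the grid value minimizing the
    absolute slope of an ordinary least-squares line of log10 phi' on
    log10 mean over genes whose mean expression is at least
    ``high_expr_threshold`` UMI/cell; ties go to the smaller ``c``.
    """
    c_grid = sorted(float(c) for c in c_grid)
    if not c_grid:
        raise ValueError("empty c grid")
    mu = expected_values(counts)
    mean_expr = counts.gene_totals() / counts.n_cells
    high = mean_expr >= high_expr_threshold
    if high.sum() < 20:
        raise ValueError(
            f"only {int(high.sum())} genes with mean expression >= "
            f"{high_expr_threshold} UMI/cell (need 20); supply c manually"
        )
    sub = counts.subset(gene_mask=high)
    mu_h = mu[high]
    log_mean = np.log10(mean_expr[high])
    x = sub.dense()
    best_c, best_slope = None, np.inf
    for c in c_grid:
        denom = np.sqrt(mu_h * (1.0 + c * c * mu_h))
        res = np.divide(x - mu_h, denom, out=np.zeros_like(x), where=denom > 0)
        phi = np.einsum("ij,ij->i", res, res) / (sub.n_cells - 1)
        ok = phi > 0
        slope = abs(np.polyfit(log_mean[ok], np.log10(phi[ok]), 1)[0])
        if slope < best_slope:  # strict: ties keep the smaller c
            best_c, best_slope = c, slope
    return best_c
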