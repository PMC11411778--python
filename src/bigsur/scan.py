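"""Genome-wide phi' and PCC' significance scan.

The scan filters genes, computes modified corrected residuals for a given
(or estimated) noise CV ``c``, tests every gene's phi' and every gene pair's
PCC' against the analytic Poisson-lognormal null, applies Benjamini-Hochberg
across all pairs, and reports signed equivalent PCCs for the survivors.

Pair statistics are assembled blockwise from five per-gene x per-cell moment
matrices, so the memory footprint is a few matrices of the residual size
regardless of how many pairs are tested, and results are independent of the
block size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import moments
from .fisher import fisher_inverse
from .residuals import (
    CountMatrix,
    estimate_c,
    expected_values,
    fano_factors,
    modified_residuals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "pcc_prime_matrix",
    "bh_fdr",
    "gene_statistics",
    "correlation_scan",
    "n_pairs",
]

_METHOD_NAMES = {0: "cornish_fisher", 1: "normal_fallback", 2: "fast_path"}


def n_pairs(m: int) -> int:
    """Number of unordered gene pairs among m genes."""
    return m * (m - 1) // 2


@dataclass
class ScanConfig:
    """Configuration of :func:`correlation_scan`.

    ``c`` may be a float or ``"auto"`` (slope-flattening estimate).  Gene
    filters: ``min_cells_expressed`` (droplet default, 8 cells) or
    ``min_total_umi`` (alternative used for shallow datasets), plus an
    optional explicit exclusion list (e.g. pseudogene identifiers).
    """

    c: "float | str" = "auto"
    fdr: float = 0.02
    min_cells_expressed: int = 8
    min_total_umi: int = 0
    moments_order: int = 5
    fast_path_floor: float = moments.DEFAULT_FAST_PATH_FLOOR
    exclude: "frozenset | None" = None
    block_size: int = 512
    significant_only: bool = False

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.moments_order not in (4, 5):
            raise ValueError("moments_order must be 4 or 5")


def pcc_prime_matrix(residuals: np.ndarray, fano_mod: np.ndarray) -> np.ndarray:
    """Modified corrected correlation matrix (unit diagonal).

    PCC'_{ab} = sum_i P'_{ia} P'_{ib} / ((n-1) sqrt(phi'_a phi'_b)).
    """
    if np.any(fano_mod <= 0):
        raise ValueError("phi' must be positive for all retained genes")
    n = residuals.shape[1]
    z = residuals / np.sqrt((n - 1) * fano_mod)[:, None]
    return z @ z.T


def bh_fdr(p_values, alpha: float):
    """Benjamini-Hochberg step-up over ``p_values`` at level ``alpha``.

    Returns ``(q_values, reject, p_threshold)`` where ``p_threshold`` is the
    largest rejected p-value (0.0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool), 0.0
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    p_threshold = float(p[reject].max()) if reject.any() else 0.0
    return q, reject, p_threshold


def _filter_counts(counts: CountMatrix, config: ScanConfig) -> CountMatrix:
    cell_keep = counts.cell_totals() > 0
    if not cell_keep.all():
        logger.info("dropping %d zero-total cells", int((~cell_keep).sum()))
        counts = counts.subset(cell_mask=cell_keep)
    keep = counts.gene_totals() > 0
    if config.min_cells_expressed:
        keep &= counts.cells_expressing() >= config.min_cells_expressed
    if config.min_total_umi:
        keep &= counts.gene_totals() >= config.min_total_umi
    if config.exclude:
        excluded = np.array([g in config.exclude for g in counts.gene_ids])
        keep &= ~excluded
    logger.info(
        "gene filter: %d of %d genes retained (%d cells)",
        int(keep.sum()), counts.n_genes, counts.n_cells,
    )
    return counts.subset(gene_mask=keep)


def gene_statistics(
    counts: CountMatrix,
    c: float,
    alpha: float = 0.05,
    moments_order: int = 5,
    fast_path_floor: float = moments.DEFAULT_FAST_PATH_FLOOR,
    block_size: int = 256,
):
    """Per-gene phi, phi' and phi' significance against the analytic null.

    Returns ``(DataFrame, residuals, mu)``; the frame holds mean expression,
    the plain corrected Fano factor (c = 0), phi', the Cornish-Fisher
    two-sided p-value and its BH q-value across genes.
    """
    mu = expected_values(counts)
    res0 = modified_residuals(counts, mu, 0.0)
    res = res0 if c == 0 else modified_residuals(counts, mu, c)
    phi = fano_factors(res0)
    phi_mod = fano_factors(res)
    n_genes = counts.n_genes
    p = np.empty(n_genes)
    method = np.empty(n_genes, dtype=np.int8)
    for start in range(0, n_genes, block_size):
        sl = slice(start, min(start + block_size, n_genes))
        kappa = moments.phi_null_cumulants(mu[sl], c, order=moments_order)
        p[sl], _, _, method[sl] = moments.cornish_fisher_pvalues(
            phi_mod[sl], kappa, fast_path_floor=fast_path_floor
        )
    q, _, _ = bh_fdr(p, alpha)
    frame = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "mean": counts.gene_totals() / counts.n_cells,
            "fano": phi,
            "fano_mod": phi_mod,
            "p_value": p,
            "q_value": q,
            "method": [_METHOD_NAMES[m] for m in method],
        }
    )
    return frame, res, mu


def _pair_moment_matrices(mu: np.ndarray, c: float, order: int):
    """Standardized residual moment matrices M_k (k = 3..order), genes x cells."""
    std = moments.residual_null_moments(mu, c, order=order)
    return [std[k - 1] for k in range(3, order + 1)]


def correlation_scan(counts: CountMatrix, config: ScanConfig, seed: int = 0):
    """Run the full scan; returns ``(pairs DataFrame, genes DataFrame)``.

    Deterministic given the counts and config (``seed`` is recorded for
    provenance only; no step is randomized).
    """
    counts = _filter_counts(counts, config)
    if counts.n_genes < 2:
        raise ValueError("fewer than 2 genes retained after filtering")
    if config.c == "auto":
        try:
            c = estimate_c(counts)
        except ValueError as err:
            raise ValueError(
                f"automatic estimation of c failed ({err}); pass c explicitly"
            ) from err
        logger.info("estimated c = %.2f", c)
    else:
        c = float(config.c)

    genes, res, mu = gene_statistics(
        counts, c,
        moments_order=config.moments_order,
        fast_path_floor=config.fast_path_floor,
    )
    ok = genes["fano_mod"].to_numpy() > 0
    if not ok.all():
        logger.warning("dropping %d zero-variance genes from the pair scan",
                       int((~ok).sum()))
        counts = counts.subset(gene_mask=ok)
        res, mu = res[ok], mu[ok]
    phi_mod = genes.loc[ok, "fano_mod"].to_numpy()

    m, n = res.shape
    total_pairs = n_pairs(m)
    mats = _pair_moment_matrices(mu, c, config.moments_order)

    pcc = np.empty(total_pairs, dtype=np.float64)
    pvals = np.empty(total_pairs, dtype=np.float64)
    meth = np.empty(total_pairs, dtype=np.int8)
    ia = np.empty(total_pairs, dtype=np.int32)
    ib = np.empty(total_pairs, dtype=np.int32)

    scale = 1.0 / np.sqrt((n - 1) * phi_mod)  # per-gene; product gives Eq. 2
    sqrt_n = np.sqrt(float(n))
    pos = 0
    bs = config.block_size
    for i0 in range(0, m, bs):
        i1 = min(i0 + bs, m)
        for j0 in range(i0, m, bs):
            j1 = min(j0 + bs, m)
            t_sum = res[i0:i1] @ res[j0:j1].T
            s3 = mats[0][i0:i1] @ mats[0][j0:j1].T
            s4 = mats[1][i0:i1] @ mats[1][j0:j1].T
            s5 = (
                mats[2][i0:i1] @ mats[2][j0:j1].T
                if config.moments_order >= 5
                else None
            )
            ii, jj = np.meshgrid(
                np.arange(i0, i1), np.arange(j0, j1), indexing="ij"
            )
            upper = ii < jj
            a_idx, b_idx = ii[upper], jj[upper]
            t_obs = t_sum[upper] / sqrt_n
            g1 = s3[upper] / n**1.5
            g2 = (s4[upper] - 3.0 * n) / n**2
            kap = [np.zeros_like(t_obs), np.full_like(t_obs, 1.0), g1, g2]
            if s5 is not None:
                kap.append((s5[upper] - 10.0 * s3[upper]) / n**2.5)
            # cumulants expressed for the standardized numerator T/sqrt(n)
            p_two, _, _, mth = moments.cornish_fisher_pvalues(
                t_obs, np.stack(kap), fast_path_floor=config.fast_path_floor
            )
            k = a_idx.size
            sl = slice(pos, pos + k)
            pcc[sl] = t_sum[upper] * scale[a_idx] * scale[b_idx]
            pvals[sl] = p_two
            meth[sl] = mth
            ia[sl], ib[sl] = a_idx, b_idx
            pos += k
    assert pos == total_pairs
    # canonical (gene_a, gene_b) order regardless of block layout
    order = np.lexsort((ib, ia))
    pcc, pvals, meth = pcc[order], pvals[order], meth[order]
    ia, ib = ia[order], ib[order]

    q, reject, p_threshold = bh_fdr(pvals, config.fdr)
    logger.info(
        "%d of %d pairs significant at FDR %.3g (p threshold %.3g)",
        int(reject.sum()), total_pairs, config.fdr, p_threshold,
    )
    sel = reject if config.significant_only else slice(None)
    eq = fisher_inverse(np.clip(pvals[sel], 5e-324, 1.0), n) * np.sign(pcc[sel])
    pairs = pd.DataFrame(
        {
            "gene_a": counts.gene_ids[ia[sel]],
            "gene_b": counts.gene_ids[ib[sel]],
            "pcc_prime": pcc[sel],
            "p_value": pvals[sel],
            "q_value": q[sel],
            "equivalent_pcc": eq,
            "significant": reject[sel],
            "method": pd.Categorical.from_codes(
                meth[sel], categories=[_METHOD_NAMES[i] for i in range(3)]
            ),
        }
    )
    return pairs, genes
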