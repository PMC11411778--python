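"""Metacell correlation-inflation benchmark on null synthetic data.

Six processing pipelines are applied to the same independent (null) counts
and the number of gene pairs each declares significantly correlated is
counted.  An accurate method should find none.  Pipelines:

``raw_pcc``
    Pearson correlations of the raw counts; Fisher-formula threshold.
``normalized_pcc``
    Counts scaled per cell to the mean sequencing depth, then as above.
``lognorm_pcc``
    Depth-normalized counts, ln(x + 1), then as above.
``metacell_pcc``
    Depth-normalized + log counts averaged within similarity groups
    ("metacells"); correlations across the grouped columns, Fisher threshold
    at the reduced sample size.
``pcc_prime_fisher``
    Modified corrected correlations (PCC') from raw counts; Fisher threshold.
``pcc_prime_bigsur``
    PCC' with analytic Cornish-Fisher p-values and Benjamini-Hochberg FDR.

Aggregating cells by similarity inflates correlations generically: cells
grouped because they look alike share sampling noise, and averaging hides
the per-cell variability that the Fisher formula assumes remains.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .fisher import fisher_inverse, fisher_p
from .residuals import CountMatrix, expected_values, fano_factors, modified_residuals
from .scan import ScanConfig, bh_fdr, correlation_scan, n_pairs
from .simulate import SimulationSpec, simulate_null

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineReport",
    "normalize_depth",
    "log_transform",
    "group_metacells",
    "run_benchmark",
    "ALL_PIPELINES",
]

ALL_PIPELINES = (
    "raw_pcc",
    "normalized_pcc",
    "lognorm_pcc",
    "metacell_pcc",
    "pcc_prime_fisher",
    "pcc_prime_bigsur",
)


@dataclass(frozen=True)
class PipelineReport:
    pipeline: str
    n_significant_total: int
    n_significant_positive: int
    n_significant_negative: int
    threshold_used: float
    n_pairs: int


def normalize_depth(counts: CountMatrix) -> np.ndarray:
    """Scale each cell's counts to the mean sequencing depth.

    Zero-total cells are dropped with a warning (they carry no counts).
    """
    totals = counts.cell_totals()
    keep = totals > 0
    x = counts.dense()
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-total cells")
        x, totals = x[:, keep], totals[keep]
    return x * (totals.mean() / totals)[None, :]


def log_transform(matrix: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Natural log of (x + pseudocount).  The log base only rescales values
    and cannot change Pearson correlations."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if np.any(matrix < 0):
        raise ValueError("log_transform requires non-negative entries")
    return np.log(matrix + pseudocount)


def group_metacells(matrix: np.ndarray, n_groups: int, seed: int = 0) -> np.ndarray:
    """Average cells within similarity groups ("metacells").

    Cells (columns) are embedded with PCA (up to 20 components), clustered by
    k-means, and then assigned greedily to their nearest centroid under a
    per-group capacity of ceil(n_cells / n_groups), giving near-equal
    occupancy.  Returns the genes x n_groups matrix of within-group means.
    The inflation this produces is generic to similarity grouping, not to a
    particular clustering algorithm.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n_cells = matrix.shape[1]
    if not 1 <= n_groups < n_cells:
        raise ValueError("need 1 <= n_groups < n_cells")
    cells = matrix.T
    n_comp = int(min(20, n_cells - 1, matrix.shape[0]))
    emb = PCA(n_components=n_comp, svd_solver="randomized",
              random_state=seed).fit_transform(cells)
    km = KMeans(n_clusters=n_groups, n_init=4, random_state=seed).fit(emb)
    dist = np.linalg.norm(emb[:, None, :] - km.cluster_centers_[None], axis=2)
    capacity = int(np.ceil(n_cells / n_groups))
    counts_per = np.zeros(n_groups, dtype=int)
    labels = np.empty(n_cells, dtype=int)
    order = np.argsort(dist.min(axis=1), kind="stable")
    for cell in order:
        for g in np.argsort(dist[cell], kind="stable"):
            if counts_per[g] < capacity:
                labels[cell] = g
                counts_per[g] += 1
                break
    used = np.flatnonzero(counts_per > 0)
    if used.size < n_groups:
        warnings.warn(f"{n_groups - used.size} empty metacell groups merged away")
    out = np.empty((matrix.shape[0], used.size))
    for k, g in enumerate(used):
        out[:, k] = matrix[:, labels == g].mean(axis=1)
    return out


def _count_fisher_significant(
    matrix: np.ndarray,
    p_threshold: float,
    center: bool = True,
    block: int = 2048,
    collect_r: bool = False,
):
    """Count row pairs whose Pearson correlation passes the Fisher threshold.

    Rows are standardized to unit norm so each block product is a correlation
    block; zero-variance rows are excluded.  Returns
    ``(n_pos, n_neg, n_pairs_tested, r_threshold, n_samples, r_values|None)``.
    """
    x = np.asarray(matrix, dtype=np.float64)
    scale = np.abs(x).max(axis=1, initial=0.0)
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    # relative tolerance: constant rows leave O(eps) centering residue
    keep = norms > 1e-12 * np.sqrt(x.shape[1]) * (1.0 + scale)
    if not keep.all():
        logger.info("excluding %d zero-variance rows", int((~keep).sum()))
        x, norms = x[keep], norms[keep]
    z = x / norms[:, None]
    m, n = z.shape
    r_th = fisher_inverse(p_threshold, n)
    n_pos = n_neg = 0
    collected = [] if collect_r else None
    for i0 in range(0, m, block):
        i1 = min(i0 + block, m)
        prod = z[i0:i1] @ z[i0:].T  # columns start at i0
        for row in range(i1 - i0):
            seg = prod[row, row + 1 :]
            n_pos += int((seg > r_th).sum())
            n_neg += int((seg < -r_th).sum())
            if collect_r:
                collected.append(np.clip(seg, -0.9999999, 0.9999999))
    r_values = np.concatenate(collected) if collect_r else None
    return n_pos, n_neg, n_pairs(m), float(r_th), n, r_values


def _report(name, n_pos, n_neg, thr, pairs_tested) -> PipelineReport:
    return PipelineReport(
        pipeline=name,
        n_significant_total=n_pos + n_neg,
        n_significant_positive=n_pos,
        n_significant_negative=n_neg,
        threshold_used=thr,
        n_pairs=pairs_tested,
    )


def _fisher_pipeline(name, matrix, p_threshold, center=True, use_bh=False):
    if use_bh:
        n_pos, n_neg, pairs_tested, _, n, r = _count_fisher_significant(
            matrix, p_threshold, center=center, collect_r=True
        )
        p = fisher_p(r, n)
        _, reject, p_cut = bh_fdr(p, p_threshold)
        n_pos = int((reject & (r > 0)).sum())
        n_neg = int((reject & (r < 0)).sum())
        return _report(name, n_pos, n_neg, p_cut, pairs_tested)
    n_pos, n_neg, pairs_tested, r_th, _, _ = _count_fisher_significant(
        matrix, p_threshold, center=center
    )
    return _report(name, n_pos, n_neg, r_th, pairs_tested)


def run_benchmark(
    spec: SimulationSpec,
    p_threshold: float = 0.02,
    n_metacells: int = 100,
    seed: "int | None" = None,
    pipelines=ALL_PIPELINES,
    use_bh: bool = False,
    c: "float | None" = None,
    counts: "CountMatrix | None" = None,
):
    """Run the requested pipelines on one null simulation.

    ``seed`` steers only the metacell clustering (default: the simulation
    seed); ``c`` is the noise CV used for PCC' (default: the simulated one).
    ``use_bh`` applies Benjamini-Hochberg at ``p_threshold`` to the PCC
    pipelines instead of the plain per-pair threshold.
    """
    if counts is None:
        counts, _ = simulate_null(spec)
    seed = spec.seed if seed is None else seed
    c = spec.c if c is None else c
    reports = []
    norm = logn = None
    for name in pipelines:
        if name == "raw_pcc":
            reports.append(
                _fisher_pipeline(name, counts.dense(), p_threshold, use_bh=use_bh)
            )
        elif name == "normalized_pcc":
            norm = normalize_depth(counts) if norm is None else norm
            reports.append(_fisher_pipeline(name, norm, p_threshold, use_bh=use_bh))
        elif name == "lognorm_pcc":
            norm = normalize_depth(counts) if norm is None else norm
            logn = log_transform(norm) if logn is None else logn
            reports.append(_fisher_pipeline(name, logn, p_threshold, use_bh=use_bh))
        elif name == "metacell_pcc":
            norm = normalize_depth(counts) if norm is None else norm
            logn = log_transform(norm) if logn is None else logn
            grouped = group_metacells(logn, n_metacells, seed=seed)
            reports.append(_fisher_pipeline(name, grouped, p_threshold, use_bh=use_bh))
        elif name == "pcc_prime_fisher":
            mu = expected_values(counts)
            res = modified_residuals(counts, mu, c)
            phi = fano_factors(res)
            ok = phi > 0
            z = res[ok]  # rows already mean ~0; PCC' = uncentered unit-norm product
            reports.append(
                _fisher_pipeline(name, z, p_threshold, center=False, use_bh=use_bh)
            )
        elif name == "pcc_prime_bigsur":
            cfg = ScanConfig(
                c=c, fdr=p_threshold, min_cells_expressed=0, min_total_umi=0
            )
            pairs, _ = correlation_scan(counts, cfg)
            sig = pairs[pairs["significant"]]
            n_pos = int((sig["pcc_prime"] > 0).sum())
            n_neg = int((sig["pcc_prime"] < 0).sum())
            reports.append(
                _report(name, n_pos, n_neg, p_threshold, len(pairs))
            )
        else:
            raise ValueError(f"unknown pipeline {name!r}")
    return reports
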