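"""Synthetic null and planted-correlation scRNA-seq count matrices.

The generator emulates droplet scRNA-seq counts with no gene-gene structure:
gene target means on a deterministic log-uniform grid, a lognormal
sequencing-depth factor per cell, a lognormal expression-noise multiplier per
gene and cell (CV ``c``), and Poisson sampling of the resulting latent rate,

    count_ij ~ Poisson( LN(mean = target_j * depth_i, CV = c) ).

Defaults mirror a 10x-Chromium-like experiment: 1000 genes x 999 cells,
targets spanning 0.0351 to 3467 transcripts per cell, c = 0.5, depth factors
of mean 1 and CV 0.75.  Lognormals are parameterized by (mean m, CV c):
log-scale variance ln(1 + c^2), log-scale mean ln m - ln(1 + c^2)/2.

Each gene consumes its own RNG stream derived from (seed, gene index), so
gene subsets reproduce exactly; the whole matrix is reproducible to the byte.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .residuals import CountMatrix

__all__ = ["SimulationSpec", "simulate_null", "simulate_correlated"]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the null simulator (defaults: the 1000 x 999
    benchmark grid; the large variant uses 15369 genes x 3570 cells)."""

    n_genes: int = 1000
    n_cells: int = 999
    mean_low: float = 0.0351
    mean_high: float = 3467.0
    c: float = 0.5
    depth_mean: float = 1.0
    depth_cv: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_cells < 2:
            raise ValueError("need n_genes >= 1 and n_cells >= 2")
        if not 0 < self.mean_low < self.mean_high:
            raise ValueError("need 0 < mean_low < mean_high")
        if self.c < 0 or self.depth_cv < 0 or self.depth_mean <= 0:
            raise ValueError("invalid noise/depth parameters")

    def gene_targets(self) -> np.ndarray:
        """Deterministic log-uniform grid of per-gene target means."""
        return np.logspace(
            np.log10(self.mean_low), np.log10(self.mean_high), self.n_genes
        )


def _lognormal_params(mean: float, cv: float):
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _depth_factors(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.depth_cv == 0:
        return np.full(spec.n_cells, spec.depth_mean)
    m, s = _lognormal_params(spec.depth_mean, spec.depth_cv)
    return rng.lognormal(m, s, size=spec.n_cells)


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    # stream 0 is reserved for the depth factors; gene j uses stream j + 1
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index + 1,)))


def _sample_gene(
    rng: np.random.Generator, base_rate: np.ndarray, c: float
) -> np.ndarray:
    """One gene's counts given its per-cell base rate target*depth."""
    if c == 0:
        return rng.poisson(base_rate)
    sigma = np.sqrt(np.log1p(c * c))
    noise = rng.lognormal(-sigma * sigma / 2.0, sigma, size=base_rate.shape)
    return rng.poisson(base_rate * noise)


def simulate_null(spec: SimulationSpec):
    """Simulate an independent (null) count matrix.

    Returns ``(CountMatrix, truth)`` where ``truth`` records the spec, the
    gene target means and the realized depth factors.
    """
    depth_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    depths = _depth_factors(spec, depth_rng)
    targets = spec.gene_targets()
    counts = np.empty((spec.n_genes, spec.n_cells), dtype=np.int64)
    for j in range(spec.n_genes):
        counts[j] = _sample_gene(_gene_rng(spec.seed, j), targets[j] * depths, spec.c)
    cm = CountMatrix(
        counts,
        gene_ids=np.array([f"gene{j:05d}" for j in range(spec.n_genes)], dtype=object),
        cell_ids=np.array([f"cell{i:05d}" for i in range(spec.n_cells)], dtype=object),
    )
    truth = {"spec": asdict(spec), "targets": targets.tolist(), "depths": depths.tolist()}
    return cm, truth


def simulate_correlated(spec: SimulationSpec, pairs):
    """Null matrix with planted latent correlations for selected gene pairs.

    ``pairs`` is a list of ``(gene_a, gene_b, rho)`` index pairs with
    |rho| < 1.  Each planted pair shares a bivariate-normal draw on the log
    of its expression-noise multipliers (a Gaussian copula on the latents),
    inducing latent correlation ~rho; all other genes follow the identical
    per-gene streams as :func:`simulate_null` with the same seed.
    """
    planted: dict[int, tuple[int, int, float, int]] = {}
    for k, (a, b, rho) in enumerate(pairs):
        if not abs(rho) < 1:
            raise ValueError("|rho| must be < 1")
        if a == b or a in planted or b in planted:
            raise ValueError("planted pairs must involve disjoint genes")
        planted[a] = (a, b, rho, k)
        planted[b] = (a, b, rho, k)

    depth_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    depths = _depth_factors(spec, depth_rng)
    targets = spec.gene_targets()
    counts = np.empty((spec.n_genes, spec.n_cells), dtype=np.int64)

    sigma = np.sqrt(np.log1p(spec.c * spec.c))
    done = set()
    for j in range(spec.n_genes):
        if j not in planted:
            counts[j] = _sample_gene(_gene_rng(spec.seed, j), targets[j] * depths, spec.c)
            continue
        a, b, rho, k = planted[j]
        if k in done:
            continue
        done.add(k)
        # pair stream keyed by the pair's first gene so it is order-stable
        rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(spec.n_genes + 1 + k,))
        )
        z = rng.standard_normal((2, spec.n_cells))
        z_b = rho * z[0] + np.sqrt(1 - rho * rho) * z[1]
        for gene, zg in ((a, z[0]), (b, z_b)):
            if spec.c == 0:
                latent = targets[gene] * depths
            else:
                latent = targets[gene] * depths * np.exp(sigma * zg - sigma * sigma / 2)
            counts[gene] = rng.poisson(latent)
    cm = CountMatrix(
        counts,
        gene_ids=np.array([f"gene{j:05d}" for j in range(spec.n_genes)], dtype=object),
        cell_ids=np.array([f"cell{i:05d}" for i in range(spec.n_cells)], dtype=object),
    )
    truth = {
        "spec": asdict(spec),
        "targets": targets.tolist(),
        "depths": depths.tolist(),
        "planted": [list(p) for p in pairs],
    }
    return cm, truth
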