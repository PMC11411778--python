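"""PCC' matrix, BH FDR and the full correlation scan."""
import numpy as np
import pandas as pd
import pytest

from bigsur import (
    CountMatrix,
    ScanConfig,
    bh_fdr,
    correlation_scan,
    expected_values,
    fano_factors,
    modified_residuals,
    n_pairs,
    pcc_prime_matrix,
    simulate_correlated,
    simulate_null,
    SimulationSpec,
)


class TestPccPrimeMatrix:
    def test_toy_anticorrelated_pair(self, toy_counts):
        mu = expected_values(toy_counts)
        res = modified_residuals(toy_counts, mu, 0.5)
        phi = fano_factors(res)
        m = pcc_prime_matrix(res, phi)
        assert m[0, 1] == pytest.approx(-1.0)

    def test_unit_diagonal(self, null_small):
        counts, _, _ = null_small
        keep = counts.gene_totals() > 0
        counts = counts.subset(gene_mask=keep)
        res = modified_residuals(counts, expected_values(counts), 0.5)
        phi = fano_factors(res)
        ok = phi > 0
        m = pcc_prime_matrix(res[ok], phi[ok])
        np.testing.assert_allclose(np.diag(m), 1.0, rtol=1e-10)

    def test_null_mean_near_zero(self, null_small):
        """Independent genes: PCC' centers on ~0 (the plug-in mu estimate
        leaves a small O(1/n) bias, so the band is absolute, not SE-based:
        pair statistics sharing genes are also not independent)."""
        counts, _, _ = null_small
        keep = counts.gene_totals() > 0
        counts = counts.subset(gene_mask=keep)
        res = modified_residuals(counts, expected_values(counts), 0.5)
        phi = fano_factors(res)
        m = pcc_prime_matrix(res[phi > 0], phi[phi > 0])
        off = m[np.triu_indices_from(m, 1)]
        assert abs(off.mean()) <= 0.25 * off.std()

    def test_zero_fano_rejected(self):
        with pytest.raises(ValueError):
            pcc_prime_matrix(np.zeros((2, 4)), np.array([0.0, 1.0]))


class TestBhFdr:
    def test_all_rejected(self):
        q, rej, thr = bh_fdr([0.01, 0.02, 0.03, 0.04], 0.05)
        assert rej.all() and thr == 0.04

    def test_one_rejected(self):
        q, rej, thr = bh_fdr([0.001, 0.8, 0.9], 0.05)
        assert list(rej) == [True, False, False]
        assert thr == 0.001

    def test_none_rejected(self):
        q, rej, thr = bh_fdr([1.0, 1.0, 1.0], 0.05)
        assert not rej.any() and thr == 0.0
        assert np.all(q == 1.0)

    def test_empty_input(self):
        q, rej, thr = bh_fdr([], 0.05)
        assert q.size == 0 and rej.size == 0 and thr == 0.0


class TestCorrelationScan:
    def test_null_scan_finds_nothing(self, null_small):
        counts, _, spec = null_small
        pairs, genes = correlation_scan(
            counts, ScanConfig(c=spec.c, fdr=0.02, min_cells_expressed=8)
        )
        assert pairs["significant"].sum() == 0
        # phi' is also unremarkable everywhere
        assert (genes["q_value"] < 0.05).sum() == 0

    def test_pair_count_matches_retained_genes(self, null_small):
        counts, _, spec = null_small
        cfg = ScanConfig(c=spec.c, min_cells_expressed=8)
        pairs, genes = correlation_scan(counts, cfg)
        m = genes.shape[0]
        assert len(pairs) == n_pairs(m)

    def test_planted_correlation_detected(self):
        spec = SimulationSpec(n_genes=200, n_cells=999, c=0.5, seed=13)
        # plant a strong positive pair among well-expressed genes
        a, b = 180, 190
        counts, truth = simulate_correlated(spec, [(a, b, 0.9)])
        pairs, _ = correlation_scan(
            counts, ScanConfig(c=0.5, fdr=0.02, min_cells_expressed=8)
        )
        ga, gb = counts.gene_ids[a], counts.gene_ids[b]
        row = pairs[(pairs["gene_a"] == ga) & (pairs["gene_b"] == gb)]
        assert len(row) == 1
        assert bool(row["significant"].iloc[0])
        assert row["pcc_prime"].iloc[0] > 0.3
        assert row["equivalent_pcc"].iloc[0] > 0

    def test_results_independent_of_block_size(self, null_small):
        counts, _, spec = null_small
        small = correlation_scan(
            counts, ScanConfig(c=spec.c, block_size=37, min_cells_expressed=8)
        )[0]
        large = correlation_scan(
            counts, ScanConfig(c=spec.c, block_size=4096, min_cells_expressed=8)
        )[0]
        pd.testing.assert_frame_equal(small, large)

    def test_deterministic_given_inputs(self, null_small):
        counts, _, spec = null_small
        cfg = ScanConfig(c=spec.c, min_cells_expressed=8)
        p1, g1 = correlation_scan(counts, cfg, seed=1)
        p2, g2 = correlation_scan(counts, cfg, seed=999)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_equivalent_pcc_sign_matches_pcc_prime(self, null_small):
        counts, _, spec = null_small
        pairs, _ = correlation_scan(
            counts, ScanConfig(c=spec.c, min_cells_expressed=8)
        )
        # at p = 1 the equivalent magnitude is exactly 0 and carries no sign
        nz = pairs[(pairs["pcc_prime"] != 0) & (pairs["p_value"] < 1)]
        assert np.all(
            np.sign(nz["equivalent_pcc"]) == np.sign(nz["pcc_prime"])
        )

    def test_exclusion_list_removes_genes(self, null_small):
        counts, _, spec = null_small
        drop = frozenset(counts.gene_ids[:50])
        pairs, genes = correlation_scan(
            counts,
            ScanConfig(c=spec.c, min_cells_expressed=8, exclude=drop),
        )
        assert not (set(genes["gene_id"]) & drop)

    def test_four_moment_variant_agrees_with_five(self, null_small):
        """With the fifth-cumulant term zeroed the p-values shift only
        modestly for moderate deviations (the configurable-order contract)."""
        counts, _, spec = null_small
        p5, _ = correlation_scan(
            counts, ScanConfig(c=spec.c, min_cells_expressed=8, moments_order=5)
        )
        p4, _ = correlation_scan(
            counts, ScanConfig(c=spec.c, min_cells_expressed=8, moments_order=4)
        )
        mid = (p5["p_value"] > 1e-4).to_numpy()
        ratio = p4["p_value"].to_numpy()[mid] / p5["p_value"].to_numpy()[mid]
        assert np.median(np.abs(np.log10(ratio))) < 0.2

    def test_auto_c_failure_message(self):
        spec = SimulationSpec(
            n_genes=30, n_cells=100, mean_low=0.01, mean_high=0.2, seed=2
        )
        counts, _ = simulate_null(spec)
        with pytest.raises(ValueError, match="pass c explicitly"):
            correlation_scan(counts, ScanConfig(c="auto", min_cells_expressed=0))
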