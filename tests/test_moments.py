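"""Poisson-lognormal null moments and Cornish-Fisher tail probabilities."""
import numpy as np
import pytest
from scipy import special, stats

from bigsur.moments import (
    MomentVector,
    PoissonLogNormalParams,
    cornish_fisher_pvalue,
    cornish_fisher_pvalues,
    fast_path_gate,
    phi_null_cumulants,
    pln_central_moments,
    pln_raw_moments,
    residual_null_moments,
    statistic_null_moments,
)


def pln_moment_quadrature(mu, c, k, n_nodes=201, x_max=None):
    """Independent oracle: E[X^k] for X ~ PLN(mu, c) by Gauss-Hermite
    quadrature over the lognormal latent and exact Poisson moments."""
    if c == 0:
        lam = np.array([mu])
        w = np.array([1.0])
    else:
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
        sigma = np.sqrt(np.log1p(c * c))
        w = weights / np.sqrt(2 * np.pi)
        keep = w > 1e-14 * w.max()  # extreme nodes carry no mass
        lam = mu * np.exp(sigma * nodes[keep] - sigma * sigma / 2)
        w = w[keep]
    # direct summation over the count support, vectorized over nodes
    x_max = x_max or int(lam.max() + 40 * np.sqrt(lam.max() + 1) + 50)
    xs = np.arange(0, x_max)
    pmf = stats.poisson.pmf(xs[None, :], lam[:, None])
    return float((w[:, None] * pmf * xs[None, :] ** k).sum())


class TestPlnMoments:
    def test_poisson_limit_exact(self):
        mv = pln_raw_moments(PoissonLogNormalParams(1.0, 0.0), 2)
        assert mv.values[0] == pytest.approx(1.0)
        assert mv.values[1] == pytest.approx(2.0)

    def test_factorial_moment_identity(self):
        mv = pln_raw_moments(PoissonLogNormalParams(2.0, 0.5), 2)
        assert mv.values[1] == pytest.approx(7.0)  # mu^2 (1+c^2) + mu
        var = mv.values[1] - mv.values[0] ** 2
        assert var == pytest.approx(2.0 + 0.25 * 4.0)

    def test_mean_preserved_by_mixing(self):
        for mu, c in [(0.1, 0.9), (5.0, 0.2)]:
            assert pln_raw_moments(PoissonLogNormalParams(mu, c), 1).mean() == (
                pytest.approx(mu)
            )

    @pytest.mark.parametrize("mu,c", [(0.3, 0.5), (2.0, 0.5), (10.0, 0.3),
                                      (100.0, 0.2), (1.0, 0.0)])
    def test_raw_moments_match_quadrature_oracle(self, mu, c):
        mv = pln_raw_moments(PoissonLogNormalParams(mu, c), 6)
        for k in range(1, 7):
            oracle = pln_moment_quadrature(mu, c, k)
            assert mv.values[k - 1] == pytest.approx(oracle, rel=1e-6)

    def test_central_moments_cancellation_free_at_large_mu(self):
        """The frozen polynomial expansion agrees with quadrature where the
        naive raw-to-central sum would lose most of its digits."""
        mu, c = 3000.0, 0.5
        cen = pln_central_moments(mu, c, 6)
        v = c * c
        # closed forms for mixed-Poisson central moments: m2 = mu + m2L,
        # m3 = mu + 3 m2L + m3L with lognormal central moments
        # m2L = v mu^2 and m3L = mu^3 (W-1)^2 (W+2), W = 1+v
        assert cen[1] == pytest.approx(mu + v * mu**2, rel=1e-12)
        m3L = mu**3 * v**2 * (v + 3)
        assert cen[2] == pytest.approx(mu + 3 * v * mu**2 + m3L, rel=1e-12)

    def test_order_cap(self):
        with pytest.raises(ValueError):
            pln_raw_moments(PoissonLogNormalParams(1.0, 0.1), 11)


class TestResidualNullMoments:
    def test_first_two_moments_exact(self):
        for mu, c in [(0.2, 0.0), (3.0, 0.5), (50.0, 0.3)]:
            mv = residual_null_moments(mu, c, 4)
            cen = mv.central()
            assert cen[0] == pytest.approx(0.0)
            assert cen[1] == pytest.approx(1.0)

    def test_poisson_skewness_closed_form(self):
        mv = residual_null_moments(0.5, 0.0, 3)
        assert mv.central()[2] == pytest.approx(0.5**-0.5, rel=1e-12)

    def test_brute_force_summation_oracle(self):
        """Standardized moments vs direct summation over the count support."""
        mu, c = 2.0, 0.5
        mv = residual_null_moments(mu, c, 5)
        sd = np.sqrt(mu * (1 + c * c * mu))
        for k in (3, 4, 5):
            num = sum(
                (-1) ** (k - j) * special.comb(k, j, exact=True)
                * pln_moment_quadrature(mu, c, j) * mu ** (k - j)
                for j in range(0, k + 1)
            )
            assert mv.central()[k - 1] == pytest.approx(num / sd**k, rel=1e-6)


class TestStatisticNullMoments:
    def test_fano_chi_square_limit(self):
        """Large mu, c=0: phi' null ~ chi2_n / (n-1)."""
        n = 200
        kap = phi_null_cumulants(np.full(n, 100.0), 0.0, 5)
        assert kap[0] == pytest.approx(n / (n - 1), rel=1e-6)
        assert kap[1] == pytest.approx(2 * n / (n - 1) ** 2, rel=0.02)

    def test_pcc_first_moment_zero_and_variance(self):
        n = 500
        std = residual_null_moments(np.full(n, 1.0), 0.0, 5)
        per_cell = [
            (
                MomentVector(tuple(std[:, i]), basis="central"),
                MomentVector(tuple(std[:, i]), basis="central"),
            )
            for i in range(n)
        ]
        mv = statistic_null_moments(per_cell, "pcc", n, fano_pair=(1.0, 1.0))
        cen = mv.central()
        assert cen[0] == pytest.approx(0.0)
        # numerator variance is n; statistic divides by (n-1) sqrt(phi phi)
        assert cen[1] == pytest.approx(n / (n - 1) ** 2, rel=1e-9)

    def test_pcc_statistic_matches_monte_carlo(self):
        """Moments 2..4 of the PCC' null against replicate simulations."""
        rng = np.random.default_rng(5)
        n, mu = 500, 1.0
        reps = 100_000
        t = np.empty(reps)
        for start in range(0, reps, 10_000):
            x = rng.poisson(mu, size=(2, 10_000, n)).astype(float)
            res = (x - mu) / np.sqrt(mu)
            t[start : start + 10_000] = np.einsum("rn,rn->r", res[0], res[1])
        std = residual_null_moments(np.full(n, mu), 0.0, 5)
        per_cell = [
            (
                MomentVector(tuple(std[:, i]), basis="central"),
                MomentVector(tuple(std[:, i]), basis="central"),
            )
            for i in range(n)
        ]
        mv = statistic_null_moments(per_cell, "pcc", n, fano_pair=(1.0, 1.0))
        cen = np.asarray(mv.central())
        d = (n - 1) * 1.0
        s = t / d
        for k, an in [(2, cen[1]), (3, cen[2]), (4, cen[3])]:
            mc = (s**k).mean()
            se = (s**k).std() / np.sqrt(reps)
            assert abs(an - mc) <= 3 * se, (k, an, mc, se)

    def test_infeasible_moments_rejected(self):
        bad = MomentVector((0.0, 1.0, 5.0, 2.0, 0.0), basis="central")
        with pytest.raises(ValueError, match="kurtosis"):
            bad.check_feasible()


class TestCornishFisher:
    def test_gaussian_reduces_to_identity(self):
        mv = MomentVector((0.0, 1.0, 0.0, 3.0, 0.0), basis="central")
        res = cornish_fisher_pvalue(1.959964, mv)
        assert res.p_two_sided == pytest.approx(0.05, rel=1e-5)
        assert res.direction == "positive"
        assert res.method == "cornish_fisher"

    def test_observation_at_null_mean(self):
        mv = MomentVector((2.0, 1.0, 0.1, 3.0, 0.5), basis="central")
        res = cornish_fisher_pvalue(2.0, mv)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_phi_prime_null_calibration(self):
        """CF p at the empirical 99th percentile of simulated phi' values
        (Poisson null, mu=5, n=200) sits in the loose calibration band."""
        rng = np.random.default_rng(99)
        n, mu = 200, 5.0
        reps = 200_000
        phi = np.empty(reps)
        for start in range(0, reps, 50_000):
            x = rng.poisson(mu, size=(50_000, n)).astype(float)
            phi[start : start + 50_000] = (
                ((x - mu) / np.sqrt(mu)) ** 2
            ).sum(axis=1) / (n - 1)
        kap = phi_null_cumulants(np.full(n, mu), 0.0, 5)
        q99 = np.quantile(phi, 0.99)
        res = cornish_fisher_pvalue(q99, MomentVector(
            (kap[0], kap[1], kap[2], kap[3] + 3 * kap[1] ** 2,
             kap[4] + 10 * kap[1] * kap[2]), basis="central"))
        assert 0.005 <= res.p_one_sided <= 0.02

    def test_negative_direction(self):
        mv = MomentVector((0.0, 1.0, 0.0, 3.0, 0.0), basis="central")
        res = cornish_fisher_pvalue(-2.5, mv)
        assert res.direction == "negative"
        assert res.p_one_sided == pytest.approx(special.ndtr(-2.5), rel=1e-6)

    def test_two_sided_is_double_one_sided(self):
        rng = np.random.default_rng(0)
        kap = np.vstack([np.zeros(50), np.ones(50),
                         rng.uniform(-0.2, 0.2, 50),
                         rng.uniform(-0.1, 0.3, 50),
                         rng.uniform(-0.5, 0.5, 50)])
        obs = rng.normal(size=50)
        p2, p1, _, _ = cornish_fisher_pvalues(obs, kap)
        np.testing.assert_allclose(p2, np.minimum(1.0, 2 * p1))

    def test_fast_path_gate_boundary(self):
        assert fast_path_gate(1e-30, 1e-20)
        assert not fast_path_gate(1e-5, 1e-20)
        assert not fast_path_gate(1e-20, 1e-20)  # strict inequality

    def test_fast_path_flagged_in_vector_route(self):
        """A mildly skewed null with an extreme observation skips the exact
        root solve; the cheap skew-adjusted tail is reported and flagged."""
        kap = np.array([[0.0], [1.0], [0.01], [0.0], [0.0]])
        p2, p1, _, method = cornish_fisher_pvalues(np.array([12.0]), kap)
        assert method[0] == 2 and p2[0] < 1e-20

    def test_fast_path_not_taken_for_strong_skew(self):
        """For a strongly skewed null the cheap normal-like tail may be many
        orders too small; the gate must fall through to the exact solve."""
        kap = np.array([[0.0], [1.0], [2.0], [8.0], [40.0]])
        p2, p1, _, method = cornish_fisher_pvalues(np.array([12.0]), kap)
        # here the expansion is decreasing at t, so no branch is trusted:
        # the result is flagged normal_fallback, never silently fast_path
        assert method[0] == 1
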