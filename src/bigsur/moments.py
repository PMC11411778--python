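"""Analytic null moments and Cornish-Fisher tail probabilities.

The null model for a single count is the Poisson-lognormal (PLN) compound:
X ~ Poisson(L) with the latent rate L lognormal of mean ``mu`` and coefficient
of variation ``c``.  No closed-form pmf exists, but every moment does: the
r-th factorial moment of a mixed Poisson equals the r-th raw moment of the
mixing distribution, E[(X)_r] = mu**r * (1 + c**2)**(r*(r-1)/2), and raw
moments follow by Stirling-number conversion.

From per-cell moments of the modified corrected residual P' (zero mean, unit
variance by construction) the cumulants of the statistics are assembled:

* phi' is a scaled sum of independent squared residuals, so its cumulants are
  sums of per-cell cumulants of (P')**2 divided by (n-1)**r;
* the PCC' numerator is a sum of independent products P'_a * P'_b whose
  per-cell moments factorize under the null; the phi' denominator is treated
  as a constant.

Tail p-values come from the Cornish-Fisher adjustment of normal quantiles:
the standardized observation t is matched to a normal deviate z by solving
the degree-4 polynomial built from standardized cumulants k3, k4, k5, taking
the real root nearest t.  Where the expansion fails (no real root, locally
decreasing) the plain normal tail is reported and flagged, and observations
whose normal tail is already far below any threshold of interest skip the
polynomial solve entirely (``fast_path``).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import special

from ._pln_tables import MAX_ORDER, PLN_CENTRAL, STIRLING2

__all__ = [
    "PoissonLogNormalParams",
    "MomentVector",
    "TailPValue",
    "pln_raw_moments",
    "pln_central_moments",
    "residual_null_moments",
    "statistic_null_moments",
    "cornish_fisher_pvalue",
    "cornish_fisher_pvalues",
    "fast_path_gate",
    "phi_null_cumulants",
    "DEFAULT_FAST_PATH_FLOOR",
]

DEFAULT_FAST_PATH_FLOOR = 1e-20

_METHOD_NAMES = {0: "cornish_fisher", 1: "normal_fallback", 2: "fast_path"}
_TINY_P = 5e-324  # smallest positive float; p-values are clamped into (0, 1]


@dataclass(frozen=True)
class PoissonLogNormalParams:
    """Mean ``mu`` and lognormal noise CV ``c`` of one PLN count. ``c = 0``
    degenerates to Poisson(mu)."""

    mu: float
    c: float

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.c < 0:
            raise ValueError("c must be non-negative")


@dataclass(frozen=True)
class MomentVector:
    """Moments of orders 1..order with a basis tag.

    ``basis`` is ``raw`` (E[X^k]), ``central`` (mean followed by central
    moments of orders 2..order) or ``standardized`` (mean, sd, then
    standardized central moments of orders 3..order stored as plain central
    moments of the standardized variable).
    """

    values: tuple
    basis: Literal["raw", "central", "standardized"] = "raw"

    def __post_init__(self):
        if len(self.values) < 2:
            raise ValueError("need at least orders 1..2")
        object.__setattr__(self, "values", tuple(float(x) for x in self.values))

    @property
    def order(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return self.values[0]

    def central(self) -> tuple:
        """(mean, c2, c3, ...) regardless of stored basis."""
        if self.basis == "central":
            return self.values
        if self.basis == "standardized":
            m, sd = self.values[0], self.values[1]
            return (m, sd * sd) + tuple(
                s * sd**k for k, s in enumerate(self.values[2:], start=3)
            )
        return _raw_to_central(self.values)

    def cumulants(self) -> tuple:
        return _central_to_cumulants(self.central())

    def check_feasible(self) -> None:
        """Moment feasibility: standardized kurtosis >= 1 + skewness**2."""
        cen = self.central()
        if cen[1] < 0:
            raise ValueError("negative variance in moment vector")
        if len(cen) >= 4 and cen[1] > 0:
            skew = cen[2] / cen[1] ** 1.5
            kurt = cen[3] / cen[1] ** 2
            if kurt < 1 + skew * skew - 1e-8:
                raise ValueError("infeasible moment vector (kurtosis bound)")


@dataclass(frozen=True)
class TailPValue:
    p_one_sided: float
    p_two_sided: float
    direction: Literal["positive", "negative"]
    method: Literal["cornish_fisher", "normal_fallback", "fast_path"]


# ---------------------------------------------------------------------------
# moment algebra helpers (orders up to 5)
# ---------------------------------------------------------------------------

def _raw_to_central(raw: Sequence[float]) -> tuple:
    m = list(raw)
    m1 = m[0]
    out = [m1]
    for k in range(2, len(m) + 1):
        ck = sum(
            special.comb(k, j, exact=True) * m[j - 1] * (-m1) ** (k - j)
            for j in range(1, k + 1)
        ) + (-m1) ** k
        out.append(float(ck))
    return tuple(out)


def _central_to_cumulants(central: Sequence[float]) -> tuple:
    """(mean, c2, c3, c4, c5) -> (k1..k5); truncated to the available order."""
    out = list(central[:3])  # k1 = mean, k2 = c2, k3 = c3
    if len(central) >= 4:
        out.append(central[3] - 3.0 * central[1] ** 2)
    if len(central) >= 5:
        out.append(central[4] - 10.0 * central[1] * central[2])
    return tuple(out)


def _cumulants_to_central(kappa: Sequence[float]) -> tuple:
    out = list(kappa[:3])
    if len(kappa) >= 4:
        out.append(kappa[3] + 3.0 * kappa[1] ** 2)
    if len(kappa) >= 5:
        out.append(kappa[4] + 10.0 * kappa[1] * kappa[2])
    return tuple(out)


# ---------------------------------------------------------------------------
# Poisson-lognormal moments
# ---------------------------------------------------------------------------

def pln_raw_moments(params: PoissonLogNormalParams, k: int) -> MomentVector:
    """Raw moments E[X], .., E[X^k] of the PLN distribution.

    E[(X)_r] = mu**r (1+c**2)**(r(r-1)/2); raw moments via Stirling numbers.
    """
    if not 1 <= k <= MAX_ORDER:
        raise ValueError(f"moment order must be in 1..{MAX_ORDER}")
    mu, w = params.mu, 1.0 + params.c**2
    vals = []
    for m in range(1, k + 1):
        s = STIRLING2[m]
        vals.append(
            sum(s[r] * mu**r * w ** (r * (r - 1) / 2.0) for r in range(1, m + 1))
        )
    if k == 1:
        vals = vals + [mu * mu * w + mu]  # MomentVector requires >= 2 orders
        return MomentVector(tuple(vals[:2]), basis="raw")
    return MomentVector(tuple(vals), basis="raw")


def pln_central_moments(mu, c: float, order: int) -> np.ndarray:
    """Central moments of PLN, vectorized over ``mu``.

    Returns an array of shape ``(order,) + shape(mu)`` holding orders 1..order
    (the first entry, E[X - mu], is identically 0).  Uses the exact frozen
    polynomial expansion in (mu, c**2), which is cancellation-free.
    """
    if not 1 <= order <= MAX_ORDER:
        raise ValueError(f"order must be in 1..{MAX_ORDER}")
    mu = np.asarray(mu, dtype=np.float64)
    v = float(c) * float(c)
    out = np.zeros((order,) + mu.shape, dtype=np.float64)
    for m in range(2, order + 1):
        acc = np.zeros_like(mu)
        # Horner in mu over the stored powers (contiguous from some a_min)
        entry = PLN_CENTRAL[m]
        powers = sorted(entry)
        coef_of_v = {a: float(np.polyval(list(reversed(cs)), v)) for a, cs in entry.items()}
        for a in reversed(range(powers[0], powers[-1] + 1)):
            acc *= mu
            if a in coef_of_v:
                acc += coef_of_v[a]
        acc *= mu ** powers[0]
        out[m - 1] = acc
    return out


def residual_null_moments(mu_ij, c: float, order: int = 5):
    """Null moments of the modified corrected residual P'.

    P' = (X - mu)/sqrt(mu (1 + c^2 mu)) has mean 0 and variance exactly 1
    (the denominator is the PLN variance).  For scalar ``mu_ij`` returns a
    :class:`MomentVector` (central basis); for array input returns the raw
    array of shape ``(order,) + shape``.
    """
    scalar = np.isscalar(mu_ij)
    mu = np.asarray(mu_ij, dtype=np.float64)
    if np.any(mu <= 0):
        raise ValueError("mu_ij must be positive")
    cen = pln_central_moments(mu, c, order)
    sd = np.sqrt(cen[1])
    std = np.zeros_like(cen)
    for k in range(2, order + 1):
        std[k - 1] = cen[k - 1] / sd**k
    if scalar:
        return MomentVector(tuple(float(s) for s in std), basis="central")
    return std


# ---------------------------------------------------------------------------
# statistics: phi' and PCC'
# ---------------------------------------------------------------------------

def _phi_cumulants_from_std(std: np.ndarray, n: int, order: int) -> np.ndarray:
    """Cumulants of phi' from standardized residual moments.

    ``std`` holds E[(P')^k] for k = 1..2*order along axis 0, per cell along the
    last axis.  Cumulants of independent summands add; phi' divides by (n-1).
    """
    q = [std[2 * k - 1] for k in range(1, order + 1)]  # E[Q^k], Q = (P')^2
    m1, m2 = q[0], q[1]
    kap = [m1, m2 - m1**2]
    if order >= 3:
        m3 = q[2]
        kap.append(m3 - 3 * m2 * m1 + 2 * m1**3)
    if order >= 4:
        m4 = q[3]
        kap.append(m4 - 4 * m3 * m1 - 3 * m2**2 + 12 * m2 * m1**2 - 6 * m1**4)
    if order >= 5:
        m5 = q[4]
        kap.append(
            m5 - 5 * m4 * m1 - 10 * m3 * m2 + 20 * m3 * m1**2
            + 30 * m2**2 * m1 - 60 * m2 * m1**3 + 24 * m1**5
        )
    scale = float(n - 1)
    return np.stack(
        [k.sum(axis=-1) / scale**r for r, k in enumerate(kap, start=1)]
    )


def phi_null_cumulants(mu, c: float, order: int = 5) -> np.ndarray:
    """Null cumulants of phi' for one or many genes.

    ``mu``: expected values, shape ``(cells,)`` or ``(genes, cells)``.
    Returns cumulants 1..order, shape ``(order,)`` or ``(order, genes)``.
    """
    orig_ndim = np.asarray(mu).ndim
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    if 2 * order > MAX_ORDER:
        raise ValueError("order too large for available PLN moments")
    if not np.all(mu > 0):
        raise ValueError("mu must be positive for retained genes/cells")
    std = residual_null_moments(mu, c, order=2 * order)
    kap = _phi_cumulants_from_std(std, mu.shape[-1], order)
    return kap[:, 0] if orig_ndim == 1 else kap


def statistic_null_moments(
    per_cell_moments: Iterable,
    kind: Literal["fano", "pcc"],
    n: int,
    fano_pair: "tuple[float, float] | None" = None,
    order: int = 5,
) -> MomentVector:
    """Null moments of phi' or PCC' assembled from per-cell residual moments.

    For ``kind="fano"`` each element of ``per_cell_moments`` is the
    :class:`MomentVector` of P' for one cell with moments up to ``2*order``.
    For ``kind="pcc"`` each element is a pair ``(mv_a, mv_b)`` of residual
    moment vectors for the two genes; per-cell product moments factorize
    under independence, and the denominator ``(n-1) sqrt(phi'_a phi'_b)``
    (``fano_pair`` holds the observed phi' values) is treated as a constant.
    """
    if n < 4:
        raise ValueError("need n >= 4 cells")
    mvs = list(per_cell_moments)
    if kind == "fano":
        std = np.stack([np.asarray(mv.central()) for mv in mvs], axis=-1)
        if std.shape[0] < 2 * order:
            raise ValueError("per-cell moments must reach order 2*order")
        kap = _phi_cumulants_from_std(std, n, order)
        kappa = tuple(float(k) for k in kap)
    elif kind == "pcc":
        if fano_pair is None:
            raise ValueError("fano_pair required for kind='pcc'")
        prod = []
        for mv_a, mv_b in mvs:
            ca, cb = np.asarray(mv_a.central()), np.asarray(mv_b.central())
            prod.append(ca[:order] * cb[:order])
        m = np.stack(prod, axis=-1)  # E[(P'a P'b)^k], k=1..order, per cell
        # E[P'] = 0 per cell, so raw product moments are central and cumulant
        # formulas collapse: k2 = m2, k3 = m3, k4 = m4 - 3 m2^2, k5 = m5 - 10 m3 m2
        k = [m[0].sum(-1), m[1].sum(-1)]
        if order >= 3:
            k.append(m[2].sum(-1))
        if order >= 4:
            k.append((m[3] - 3 * m[1] ** 2).sum(-1))
        if order >= 5:
            k.append((m[4] - 10 * m[2] * m[1]).sum(-1))
        d = (n - 1) * np.sqrt(float(fano_pair[0]) * float(fano_pair[1]))
        kappa = tuple(float(kk) / d**r for r, kk in enumerate(k, start=1))
    else:
        raise ValueError(f"unknown statistic kind {kind!r}")
    mv = MomentVector(_cumulants_to_central(kappa), basis="central")
    try:
        mv.check_feasible()
    except ValueError as err:
        raise ValueError(f"infeasible null moments for {kind} statistic: {err}")
    return mv


# ---------------------------------------------------------------------------
# Cornish-Fisher tail probabilities
# ---------------------------------------------------------------------------

def fast_path_gate(normal_approx_p: float, floor: float = DEFAULT_FAST_PATH_FLOOR) -> bool:
    """True iff the cheap normal tail already falls strictly below ``floor``
    (such p-values are far beyond any significance threshold, so the slow
    polynomial solve is skipped and the approximation reported as-is)."""
    if not 0 < floor < 1:
        raise ValueError("floor must be in (0, 1)")
    return normal_approx_p < floor


def _cf_coefficients(g1, g2, g3):
    """Coefficients a0..a4 of the Cornish-Fisher quantile polynomial f(z)."""
    a0 = -g1 / 6 + g3 / 40 - g1 * g2 / 12 + 17 * g1**3 / 324
    a1 = 1 - g2 / 8 + 5 * g1**2 / 36
    a2 = g1 / 6 - g3 / 20 + 5 * g1 * g2 / 24 - 53 * g1**3 / 324
    a3 = g2 / 24 - g1**2 / 18
    a4 = g3 / 120 - g1 * g2 / 24 + g1**3 / 27
    return a0, a1, a2, a3, a4


def _companion_nearest_root(t, coeffs):
    """Real root nearest ``t`` of sum_k coeffs[k] z^k = t, NaN where none.

    ``coeffs`` is a list of arrays [c0, c1, .., cd]; batched companion-matrix
    eigenvalues of the monic polynomial of degree d.
    """
    d = len(coeffs) - 1
    n = t.shape[0]
    lead = coeffs[d]
    comp = np.zeros((n, d, d))
    if d > 1:
        comp[:, np.arange(1, d), np.arange(0, d - 1)] = 1.0
    comp[:, 0, d - 1] = -(coeffs[0] - t) / lead
    for k in range(1, d):
        comp[:, k, d - 1] = -coeffs[k] / lead
    roots = np.linalg.eigvals(comp)
    real = np.abs(roots.imag) <= 1e-6 * (1.0 + np.abs(roots.real))
    dist = np.where(real, np.abs(roots.real - t[:, None]), np.inf)
    best = np.argmin(dist, axis=1)
    z = roots.real[np.arange(n), best]
    z[~real.any(axis=1)] = np.nan
    return z


def _solve_cf_quartic(t, a0, a1, a2, a3, a4):
    """Real root of the Cornish-Fisher polynomial f(z) = t nearest t.

    The effective degree is chosen per observation (a vanishing quartic or
    cubic coefficient would otherwise plant an enormous spurious root and
    overflow the companion matrix).
    """
    z = np.full(t.shape, np.nan)
    tol = 1e-14
    deg4 = np.abs(a4) > tol
    deg3 = ~deg4 & (np.abs(a3) > tol)
    deg2 = ~deg4 & ~deg3 & (np.abs(a2) > tol)
    deg1 = ~deg4 & ~deg3 & ~deg2
    for mask, degree in ((deg4, 4), (deg3, 3), (deg2, 2)):
        if np.any(mask):
            cs = [a0[mask], a1[mask], a2[mask], a3[mask], a4[mask]][: degree + 1]
            z[mask] = _companion_nearest_root(t[mask], cs)
    if np.any(deg1):
        with np.errstate(divide="ignore", invalid="ignore"):
            z[deg1] = (t[deg1] - a0[deg1]) / a1[deg1]
    return z


def cornish_fisher_pvalues(
    observed,
    kappa: np.ndarray,
    fast_path_floor: float = DEFAULT_FAST_PATH_FLOOR,
    batch: int = 200_000,
):
    """Vectorized Cornish-Fisher tail p-values.

    Parameters
    ----------
    observed
        Observed statistic values, shape ``(n,)``.
    kappa
        Null cumulants, shape ``(order, n)`` with order 4 or 5 (orders beyond
        the third enter through the standardized cumulants; order 4 zeroes the
        fifth-cumulant term).
    Returns
    -------
    p_two, p_one : ndarray
        Two-sided (``min(1, 2 p_one)``) and one-sided tail p-values.
    direction : ndarray of {+1, -1}
    method : int ndarray (0 cornish_fisher, 1 normal_fallback, 2 fast_path)
    """
    x = np.asarray(observed, dtype=np.float64).ravel()
    kappa = np.asarray(kappa, dtype=np.float64)
    if kappa.shape[0] not in (4, 5):
        raise ValueError("need cumulants of orders 1..4 or 1..5")
    k1, k2 = kappa[0], kappa[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(k2)
        t = (x - k1) / sd
        g1 = kappa[2] / sd**3
        g2 = kappa[3] / k2**2
        g3 = kappa[4] / sd**5 if kappa.shape[0] >= 5 else np.zeros_like(t)

    z = np.array(t)  # fallback deviate
    method = np.ones(x.shape, dtype=np.int8)  # start as normal_fallback
    ok = np.isfinite(t) & (k2 > 0)
    z[~ok] = 0.0

    trivial = ok & (np.abs(g1) + np.abs(g2) + np.abs(g3) < 1e-12)
    method[trivial] = 0  # expansion is the identity map
    # an observation at the null mean carries no evidence in either direction
    at_mean = ok & (t == 0)
    method[at_mean] = 0

    # fast path: one Newton step of the expansion inversion, z1 = t -
    # (f(t) - t)/f'(t), is quartic-free and already carries the skew
    # correction; where its tail is far below any threshold of interest the
    # exact root solve is skipped.  (The raw normal deviate is NOT a safe
    # gate: for strongly skewed nulls it can undershoot the true p-value by
    # many orders of magnitude.)
    a0, a1, a2, a3, a4 = _cf_coefficients(g1, g2, g3)
    ft = a0 + a1 * t + a2 * t**2 + a3 * t**3 + a4 * t**4
    fpt = a1 + 2 * a2 * t + 3 * a3 * t**2 + 4 * a4 * t**3
    with np.errstate(invalid="ignore", divide="ignore"):
        z1 = t - (ft - t) / fpt
    p1 = 2.0 * special.ndtr(-np.abs(z1))
    fast = (
        ok & ~trivial & ~at_mean & (fpt > 0) & np.isfinite(z1)
        & (p1 < fast_path_floor)
    )
    z[fast] = z1[fast]
    method[fast] = 2
    todo = np.flatnonzero(ok & ~fast & ~trivial & ~at_mean)

    for start in range(0, todo.size, batch):
        idx = todo[start : start + batch]
        b0, b1, b2, b3, b4 = (arr[idx] for arr in (a0, a1, a2, a3, a4))
        zr = _solve_cf_quartic(t[idx], b0, b1, b2, b3, b4)
        deriv = b1 + 2 * b2 * zr + 3 * b3 * zr**2 + 4 * b4 * zr**3
        good = np.isfinite(zr) & (deriv > 0)
        sel = idx[good]
        z[sel] = zr[good]
        method[sel] = 0

    direction = np.where(x >= k1, 1, -1).astype(np.int8)
    signed = np.where(direction > 0, z, -z)  # tail deviate toward the observation
    p_one = special.ndtr(-signed)
    p_one = np.clip(p_one, _TINY_P, 1.0)
    p_one[~ok] = 1.0
    p_two = np.minimum(1.0, 2.0 * p_one)
    return p_two, p_one, direction, method


def cornish_fisher_pvalue(
    observed: float,
    null_moments: MomentVector,
    fast_path_floor: float = DEFAULT_FAST_PATH_FLOOR,
) -> TailPValue:
    """Tail p-value of one observation against a moment-specified null."""
    kappa = np.asarray(null_moments.cumulants(), dtype=np.float64)
    if kappa.shape[0] < 4:
        raise ValueError("need null moments of orders 1..4 at least")
    p_two, p_one, direction, method = cornish_fisher_pvalues(
        np.asarray([observed]), kappa[:, None], fast_path_floor=fast_path_floor
    )
    return TailPValue(
        p_one_sided=float(p_one[0]),
        p_two_sided=float(p_two[0]),
        direction="positive" if direction[0] > 0 else "negative",
        method=_METHOD_NAMES[int(method[0])],
    )
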