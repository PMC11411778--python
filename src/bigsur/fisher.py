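"""The Fisher formula for correlation p-values, and its inverse.

For a Pearson correlation r of n approximately normal samples,

    p(|r|) = erfc( sqrt((n - 3) / 2) * arctanh(|r|) )

(the classical z-transform tail, two-sided).  The inverse maps a p-value back
to the correlation magnitude that would have produced it at the same n — the
"equivalent PCC", a length-adjusted effect size for reporting.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import special

__all__ = ["fisher_p", "fisher_inverse", "pcc_uncorrected"]


def fisher_p(r, n: int):
    """Two-sided Fisher-formula p-value for correlation(s) ``r`` at ``n`` samples."""
    if n < 4:
        raise ValueError("need n >= 4 samples")
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r_arr) >= 1):
        raise ValueError("|r| must be < 1")
    out = special.erfc(np.sqrt((n - 3) / 2.0) * np.arctanh(np.abs(r_arr)))
    return out if isinstance(r, np.ndarray) else float(out)


def _erfcinv_stable(p):
    """erfc^{-1}(p) for p down to (and below) the subnormal range.

    scipy's erfcinv is accurate for normal doubles; below ~1e-280 an
    asymptotic seed x ~ sqrt(L - ln(pi L)/2), L = -ln p, is polished with
    Newton steps on log erfc (evaluated stably through erfcx).
    """
    p = np.asarray(p, dtype=np.float64)
    out = np.empty_like(p)
    normal = p > 1e-280
    out[normal] = special.erfcinv(p[normal])
    small = ~normal
    if np.any(small):
        logp = np.log(p[small])
        L = -logp
        x = np.sqrt(L - 0.5 * np.log(np.pi * L))
        for _ in range(4):
            # log erfc(x) = log erfcx(x) - x^2 ; d/dx log erfc = -2/(sqrt(pi) erfcx)
            f = np.log(special.erfcx(x)) - x * x - logp
            x = x + f * np.sqrt(np.pi) * special.erfcx(x) / 2.0
        out[small] = x
    return out


def fisher_inverse(p, n: int):
    """|r| such that ``fisher_p(r, n) == p``; 0 at p = 1.

    Stable for p down to ~1e-300 (an asymptotic branch of the inverse erfc).
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    p_arr = np.asarray(p, dtype=np.float64)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("p must be in (0, 1]")
    out = np.tanh(_erfcinv_stable(p_arr) * np.sqrt(2.0 / (n - 3)))
    return out if isinstance(p, np.ndarray) else float(out)


def pcc_uncorrected(matrix: np.ndarray):
    """Pearson correlations between rows of ``matrix`` (e.g. normalized counts).

    Zero-variance rows are excluded with a warning; returns
    ``(corr, kept_row_indices)`` where ``corr`` has unit diagonal.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    var = matrix.var(axis=1)
    scale = np.abs(matrix).max(axis=1, initial=0.0)
    keep = np.flatnonzero(var > (1e-12 * (1.0 + scale)) ** 2)
    if keep.size < matrix.shape[0]:
        warnings.warn(
            f"excluding {matrix.shape[0] - keep.size} zero-variance rows "
            "from correlation"
        )
    corr = np.corrcoef(matrix[keep])
    return np.atleast_2d(corr), keep
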