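#!/usr/bin/env python
"""Regenerate src/bigsur/_pln_tables.py (exact PLN moment coefficients).

For X ~ Poisson(L), L lognormal with mean mu and squared CV v:
E[(X)_r] = mu**r (1+v)**(r(r-1)/2); raw moments via Stirling numbers; the
central-moment binomial sum is expanded symbolically so the large-mu
cancellation is done exactly, and the integer coefficients are frozen.

Requires sympy (not a runtime dependency of the package).
"""
from pathlib import Path

import sympy as sp
from sympy.functions.combinatorial.numbers import stirling

MAX_ORDER = 10
OUT = Path(__file__).resolve().parent.parent / "src" / "bigsur" / "_pln_tables.py"


def main() -> None:
    mu, v = sp.symbols("mu v", positive=True)
    w = 1 + v
    raw = {
        k: sp.expand(
            sum(
                stirling(k, r) * mu**r * w ** sp.Rational(r * (r - 1), 2)
                for r in range(0, k + 1)
            )
        )
        for k in range(0, MAX_ORDER + 1)
    }
    central = {}
    for m in range(2, MAX_ORDER + 1):
        cm = sp.expand(
            sum(
                sp.binomial(m, k) * (-mu) ** (m - k) * raw[k]
                for k in range(0, m + 1)
            )
        )
        entry = {}
        for (a,), coeff in sp.Poly(cm, mu).terms():
            entry[a] = [int(c) for c in reversed(sp.Poly(coeff, v).all_coeffs())]
        central[m] = dict(sorted(entry.items()))

    stirling2 = {
        k: [int(stirling(k, r)) for r in range(0, k + 1)]
        for k in range(0, MAX_ORDER + 1)
    }

    lines = [
        '"""Exact coefficient tables for Poisson-lognormal moments.',
        "",
        "For X ~ Poisson(L) with L lognormal of mean mu and squared coefficient of",
        "variation v = c**2 (so E[L**r] = mu**r * (1+v)**(r*(r-1)/2)):",
        "",
        "* ``STIRLING2[k][r]`` are Stirling numbers of the second kind, converting",
        "  factorial moments to raw moments: E[X**k] = sum_r S(k,r) E[(X)_r].",
        "* ``PLN_CENTRAL[m]`` maps each power a of mu to the integer coefficients",
        "  (low order first) of a polynomial in v, such that the m-th central",
        "  moment E[(X-mu)**m] = sum_a mu**a * poly_a(v).",
        "",
        "The central-moment table is the symbolically expanded binomial sum; the",
        "expansion is frozen here because evaluating the alternating raw-moment sum",
        "in floating point loses ~m*log10(mu) digits to cancellation at high mu.",
        "Regenerate with scripts/generate_pln_tables.py.",
        '"""',
        "",
        f"MAX_ORDER = {MAX_ORDER}",
        "",
        f"STIRLING2 = {stirling2!r}",
        "",
        "PLN_CENTRAL = {",
    ]
    for m, entry in central.items():
        lines.append(f"    {m}: {entry!r},")
    lines += ["}", ""]
    OUT.write_text("\n".join(lines))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
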