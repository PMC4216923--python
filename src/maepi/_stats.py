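"""Shared statistical helpers: cached Fisher tests and BH adjustment."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

_lnfact = np.array([0.0])


def _lnfact_table(n: int) -> np.ndarray:
    """ln(k!) lookup table for k in [0, n], grown on demand."""
    global _lnfact
    if n >= len(_lnfact):
        _lnfact = gammaln(np.arange(max(n + 1, 2 * len(_lnfact))) + 1.0)
    return _lnfact


@lru_cache(maxsize=1_000_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    # Exact two-sided hypergeometric enumeration: sum the probabilities of
    # all tables with the observed margins that are no more likely than the
    # observed one, with the conventional 1 + 1e-7 tie tolerance.
    r1, r2, n = a + b, c + d, a + c
    N = r1 + r2
    lg = _lnfact_table(N)
    lo, hi = max(0, n - r2), min(n, r1)
    k = np.arange(lo, hi + 1)
    logp = (lg[r1] - lg[k] - lg[r1 - k]
            + lg[r2] - lg[n - k] - lg[r2 - n + k]
            - (lg[N] - lg[n] - lg[N - n]))
    pmf = np.exp(logp)
    pexact = pmf[a - lo]
    pmode = pmf.max()
    eps = 1e-7
    if abs(pexact - pmode) <= eps * max(pexact, pmode):
        return 1.0
    return float(min(1.0, pmf[pmf <= pexact * (1 + eps)].sum()))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Count tables recur heavily in genome-wide scans, so results are
    memoised on the four counts.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    if a + b == 0 or c + d == 0:
        raise ValueError("each sample needs nonzero depth")
    return _fisher_cached(int(a), int(b), int(c), int(d))


def fisher_vector(a, b, c, d) -> np.ndarray:
    """Vectorised (memoised) two-sided Fisher p over parallel count arrays."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    out = np.empty(len(a))
    for i in range(len(a)):
        out[i] = _fisher_cached(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
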