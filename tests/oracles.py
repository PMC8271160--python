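"""Independent brute-force oracles used by the test suite only."""

import numpy as np
from scipy import stats


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Fixing the margins of [[a, b], [c, d]], sum the probabilities of every
    table whose point probability does not exceed the observed one.
    """
    row1, col1, total = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, total, col1, row1)
    observed = stats.hypergeom.pmf(a, total, col1, row1)
    return float(pmf[pmf <= observed * (1 + 1e-9)].sum())


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values, written independently of the package."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
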