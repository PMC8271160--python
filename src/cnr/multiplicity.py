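"""Storey q-value false-discovery-rate control, implemented from its definition.

The q-value of a test is the minimum positive FDR at which it would be
called significant:

    q_(i) = min_{k >= i}  pi0 * m * p_(k) / k        (on sorted p-values)

where pi0, the proportion of true nulls, is estimated from the flat part of
the p-value histogram:  pi0(lmb) = #{p > lmb} / (m (1 - lmb)) over the grid
lmb = 0, 0.05, ..., 0.90, smoothed by a cubic fit and read off at the grid
maximum.  With pi0 = 1 the procedure reduces exactly to Benjamini-Hochberg.

Small inputs carry too little histogram information to estimate pi0, so for
m < 30 the estimate falls back to the conservative pi0 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import DataError

_LAMBDA_GRID = np.arange(0.0, 0.9001, 0.05)
_SMALL_M = 30


@dataclass
class QValueResult:
    p_values: np.ndarray
    q_values: np.ndarray
    pi0_hat: float
    lambda_grid: np.ndarray

    def __iter__(self):  # allow q, pi0 unpacking in quick scripts
        yield self.q_values
        yield self.pi0_hat


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("p must be a nonempty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")
    return p


def estimate_pi0(p) -> float:
    """Estimate the proportion of true null hypotheses from a p-value vector."""
    p = _check_p(p)
    m = p.size
    if m < _SMALL_M:
        return 1.0
    grid = _LAMBDA_GRID
    pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in grid])
    # Cubic smoother over the trajectory, evaluated at the largest lambda.
    coeffs = np.polynomial.polynomial.polyfit(grid, pi0_lam, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(grid[-1], coeffs))
    return float(min(max(pi0, 1e-8), 1.0))


def qvalues(p, pi0: float | None = None) -> QValueResult:
    """Storey q-values for a p-value vector (pi0 estimated unless given)."""
    p = _check_p(p)
    m = p.size
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise DataError(f"pi0 must lie in (0, 1], got {pi0}")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(
        p_values=p, q_values=q, pi0_hat=float(pi0), lambda_grid=_LAMBDA_GRID.copy()
    )
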