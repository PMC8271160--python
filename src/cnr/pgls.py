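"""Phylogenetic generalized least squares with Pagel's-lambda ML estimation.

Under Brownian-motion trait evolution on a rooted tree, the covariance of
two tips equals the branch length they share from the root to their most
recent common ancestor.  Pagel's lambda rescales the off-diagonal of that
matrix, interpolating between phylogenetic independence (lambda = 0, a star
phylogeny) and the full Brownian structure (lambda = 1).  A PGLS fit
maximizes the profile Gaussian likelihood over lambda in [0, 1]; regression
coefficients, their standard errors and two-sided t tests (df = n - p) are
reported at the maximizing lambda.

Estimation choices:

* ML (not REML) likelihood for lambda; coefficient standard errors use the
  unbiased n - p residual-variance denominator.
* lambda is located by a 21-point coarse grid followed by bounded scalar
  refinement around the best grid point; ties break toward smaller lambda.
* a near-singular covariance gets a single jitter of 1e-10 * mean(diag); if
  factorization still fails, the error says whether V or X is the culprit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .data_io import DataError, Phylogeny, SpeciesRecord, LIFE_FORMS

logger = logging.getLogger(__name__)

_GRID = np.linspace(0.0, 1.0, 21)
_JITTER = 1e-10


class FitError(RuntimeError):
    """Numerical failure inside the PGLS machinery."""


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance: C_ab = shared root-to-MRCA path length."""

    species: list[str]
    matrix: np.ndarray

    @property
    def n(self) -> int:
        return len(self.species)


@dataclass
class DesignMatrix:
    """Fixed-effects design with an intercept first column."""

    names: list[str]
    X: np.ndarray
    baseline: str | None = None


@dataclass
class PGLSFit:
    """One fitted phylogenetic regression."""

    lambda_hat: float
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    sigma2_hat: float
    loglik: float
    df_resid: int
    names: list[str]
    grid_loglik: dict[float, float] = field(default_factory=dict)

    @property
    def lambda_at_boundary(self) -> bool:
        """True when the lambda optimum sits on 0 or 1 (flat/boundary profile)."""
        return self.lambda_hat <= 1e-6 or self.lambda_hat >= 1.0 - 1e-6

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])


def phylo_covariance(tree: Phylogeny, species_order: Sequence[str]) -> PhyloCovariance:
    """Build the n x n shared-path-length matrix in the given species order."""
    order = list(species_order)
    tips = set(tree.tip_labels)
    missing = [s for s in order if s not in tips]
    if missing:
        raise DataError(f"species missing from tree: {missing}")
    index = {s: i for i, s in enumerate(order)}
    n = len(order)
    C = np.zeros((n, n))

    # Postorder sweep: each node contributes its depth as the covariance of
    # every tip pair split between two of its child subtrees.
    dtree = tree.dendropy_tree
    depths: dict = {}
    for node in dtree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = (
            0.0 if parent is None else depths[parent] + (node.edge.length or 0.0)
        )
    below: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            idx = [index[label]] if label in index else []
            if idx:
                C[idx[0], idx[0]] = depths[node]
            below[node] = idx
        else:
            children = [below[c] for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = d
                            C[j, i] = d
            below[node] = [i for ch in children for i in ch]
    return PhyloCovariance(species=order, matrix=C)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale the off-diagonal of C by lambda, keeping the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise DataError(f"lambda must lie in [0, 1], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(species=list(C.species), matrix=M)


def gls_solve(
    y: np.ndarray, X: DesignMatrix | np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Generalized least squares: returns (beta, se, sigma2_ml, loglik).

    beta = (X' V^-1 X)^-1 X' V^-1 y, computed through a Cholesky whitening of
    V.  sigma2_ml uses the n denominator (it enters the ML likelihood);
    standard errors use the unbiased n - p residual variance.
    """
    Xmat = X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xmat.shape
    if np.linalg.matrix_rank(Xmat) < p:
        raise FitError("design matrix X is rank deficient")
    L = _chol(V)
    Xt = linalg.solve_triangular(L, Xmat, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    XtX = Xt.T @ Xt
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise FitError("design matrix X is singular after whitening") from exc
    beta = XtX_inv @ (Xt.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    sigma2_unb = rss / (n - p) if n > p else np.nan
    with np.errstate(invalid="ignore"):
        se = np.sqrt(sigma2_unb * np.diag(XtX_inv))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    # Guard the exact-fit degeneracy (rss == 0): report a large finite loglik.
    s2 = max(sigma2_ml, 1e-300)
    loglik = -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)
    return beta, se, sigma2_ml, loglik


def pgls_fit(
    y: np.ndarray,
    X: DesignMatrix,
    C: PhyloCovariance,
    lam: float | None = None,
) -> PGLSFit:
    """Fit y ~ X with residual covariance sigma^2 * V(lambda).

    lambda is profiled out by ML over [0, 1] unless ``lam`` pins it.  Fields
    follow the conventions documented in the module docstring.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise DataError("response contains non-finite values")
    n, p = X.X.shape
    if not (len(y) == n == C.n):
        raise DataError("y, X and C dimensions disagree")
    if n < p + 2:
        raise DataError(f"need at least p + 2 = {p + 2} observations, got {n}")

    def negll(lmb: float) -> float:
        V = lambda_transform(C, lmb).matrix
        return -gls_solve(y, X, V)[3]

    grid_ll: dict[float, float] = {}
    if lam is None:
        try:
            for g in _GRID:
                grid_ll[float(g)] = -negll(float(g))
        except FitError as exc:
            raise FitError(
                f"likelihood evaluation failed on the lambda grid: {exc}; "
                f"grid so far: {grid_ll}"
            ) from exc
        # np.argmax returns the first (smallest-lambda) maximizer on ties.
        gvals = np.array([grid_ll[float(g)] for g in _GRID])
        best = float(_GRID[int(np.argmax(gvals))])
        lo, hi = max(0.0, best - 0.05), min(1.0, best + 0.05)
        lam_hat, ll_hat = best, grid_ll[best]
        try:
            res = optimize.minimize_scalar(
                negll, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-7},
            )
            if np.isfinite(res.fun) and -res.fun > ll_hat:
                lam_hat, ll_hat = float(res.x), float(-res.fun)
        except FitError:
            logger.debug("lambda refinement failed; keeping grid optimum")
        # Snap to the boundary when the refined point is within tolerance.
        if lam_hat < 1e-7:
            lam_hat = 0.0
        elif lam_hat > 1.0 - 1e-7:
            lam_hat = 1.0
    else:
        lam_hat = float(lam)

    V = lambda_transform(C, lam_hat).matrix
    beta, se, sigma2, loglik = gls_solve(y, X, V)
    df = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return PGLSFit(
        lambda_hat=lam_hat,
        beta=beta,
        se=se,
        t_stat=t,
        p_value=pvals,
        sigma2_hat=sigma2,
        loglik=loglik,
        df_resid=df,
        names=list(X.names),
        grid_loglik=grid_ll,
    )


def encode_lifeforms(
    species: Sequence[SpeciesRecord], baseline: str = "tree"
) -> DesignMatrix:
    """Intercept + one indicator column per non-baseline life form present.

    With trees as baseline, each indicator coefficient is that life form's
    mean offset from trees, so a family expanded in trees shows negative herb
    coefficients.
    """
    forms = [s.life_form for s in species]
    present = [f for f in LIFE_FORMS if f in forms]
    if baseline not in present:
        raise DataError(f"baseline life form {baseline!r} absent from data")
    others = [f for f in present if f != baseline]
    if not others:
        logger.warning("only one life form present; design is intercept-only")
    n = len(species)
    X = np.ones((n, 1 + len(others)))
    for k, form in enumerate(others, start=1):
        X[:, k] = [1.0 if f == form else 0.0 for f in forms]
    return DesignMatrix(names=["intercept"] + others, X=X, baseline=baseline)


def _chol(V: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        jitter = _JITTER * float(np.mean(np.diag(V)))
        try:
            return np.linalg.cholesky(V + jitter * np.eye(V.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise FitError("covariance matrix V is singular (after jitter)") from exc
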