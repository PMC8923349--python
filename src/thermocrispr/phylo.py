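"""Phylogenetic covariance, Pagel's-λ signal estimation and PGLS regression.

Under a Brownian-motion model of trait evolution on a rooted tree, the
covariance of the trait values at two tips is proportional to the shared
branch length from the root to their most recent common ancestor.  Pagel's
λ rescales the off-diagonal entries of that matrix: λ=0 means tip values
are phylogenetically independent, λ=1 the full Brownian structure.

Both the signal estimate (trait ~ intercept) and the PGLS regression
(trait ~ covariate) are maximum-likelihood fits of

    y ~ Normal(X beta, sigma^2 * V(lambda)),   V(lambda) = lambda*C + (1-lambda)*diag(C)

profiled over lambda in [0, 1].  The profile is computed in a basis that
diagonalizes V(lambda) for every lambda simultaneously: with D = diag(C)
and M = D^{-1/2} C D^{-1/2} = Q W Q^T, V(lambda) is diagonal after the fixed
rotation Q^T D^{-1/2}, so each candidate lambda costs O(n) after one
symmetric eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize, stats

__all__ = [
    "PhyloCovariance",
    "SignalEstimate",
    "PGLSFit",
    "phylo_covariance",
    "lambda_transform",
    "estimate_lambda_signal",
    "pgls_fit",
]

_LAMBDA_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class PhyloCovariance:
    """Shared root-to-MRCA path lengths between every pair of tips."""

    matrix: np.ndarray
    tip_order: list[str]

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, dtype=float)
        if C.shape[0] != C.shape[1] or C.shape[0] != len(self.tip_order):
            raise ValueError("covariance shape does not match tip order")
        if not np.allclose(C, C.T):
            raise ValueError("covariance must be symmetric")
        self.matrix = C

    def submatrix(self, labels: list[str]) -> "PhyloCovariance":
        idx = [self.tip_order.index(l) for l in labels]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(labels))


@dataclass
class SignalEstimate:
    """Pagel's-λ phylogenetic signal with a likelihood-ratio test vs λ=0."""

    lambda_hat: float
    loglik_at_hat: float
    loglik_at_zero: float
    p_value: float
    n: int
    method: str = "ML"


@dataclass
class PGLSFit:
    """One PGLS regression y = b0 + b1*x under the λ model (ML)."""

    slope: float
    intercept: float
    lambda_hat: float
    sigma2_hat: float
    slope_p: float
    slope_se: float
    loglik: float
    n: int
    method: str = "ML"

    def to_row(self) -> dict:
        return {
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "p": self.slope_p,
            "lambda_hat": self.lambda_hat,
            "sigma2_hat": self.sigma2_hat,
            "loglik": self.loglik,
        }


def phylo_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Build the Brownian covariance C[i,j] = depth of MRCA(i, j).

    Polytomies are accepted; each internal node contributes its depth to all
    tip pairs split across distinct child subtrees.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tip_idx = [index[id(node)]]
            continue
        if node.edge.length is not None and node.edge.length < 0:
            raise ValueError("negative branch length")
        depth = node.root_distance
        child_sets = [ch._tip_idx for ch in node.child_nodes()]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                C[np.ix_(child_sets[a], child_sets[b])] = depth
                C[np.ix_(child_sets[b], child_sets[a])] = depth
        node._tip_idx = [i for s in child_sets for i in s]
    for lf in leaves:
        C[index[id(lf)], index[id(lf)]] = lf.root_distance
    return PhyloCovariance(C, labels)


def lambda_transform(cov: PhyloCovariance, lam: float) -> np.ndarray:
    """Multiply off-diagonal covariances by λ, keeping the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = cov.matrix
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


class _LambdaProfile:
    """Profile likelihood over λ for y ~ N(X beta, sigma^2 V(lambda)).

    One symmetric eigendecomposition of the unit-diagonal correlation
    analogue M = D^{-1/2} C D^{-1/2}; every λ then gives a diagonal GLS
    problem with weights w_k(λ) = 1 - λ + λ e_k (e_k eigenvalues of M).
    """

    def __init__(self, C: np.ndarray, X: np.ndarray, y: np.ndarray):
        self.n = len(y)
        d = np.diag(C).copy()
        if np.any(d <= 0):
            raise ValueError("zero-depth tip: covariance diagonal must be positive")
        s = np.sqrt(d)
        M = C / np.outer(s, s)
        evals, Q = np.linalg.eigh(M)
        evals = np.clip(evals, 0.0, None)  # tolerate tiny negative roundoff
        self.evals = evals
        self.logdet_d = float(np.sum(np.log(d)))
        self.yt = Q.T @ (y / s)
        self.Xt = Q.T @ (X / s[:, None])

    #: relative ridge applied to the correlation eigenvalues; keeps V(λ)
    #: invertible when a near-zero-length cherry makes it numerically singular
    JITTER = 1e-10

    def _weights(self, lam: float) -> np.ndarray | None:
        w = 1.0 - lam + lam * self.evals
        floor = self.JITTER * max(1.0, float(np.max(w)))
        if np.min(w) < -1e-8:
            return None  # genuinely invalid covariance at this lambda
        return np.maximum(w, floor)

    def fit_at(self, lam: float):
        """GLS at fixed λ: returns (loglik, beta, sigma2_ml, XtX_inv, rss)."""
        w = self._weights(lam)
        if w is None:
            return -np.inf, None, None, None, None
        sw = np.sqrt(w)
        Xw = self.Xt / sw[:, None]
        yw = self.yt / sw
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        n = self.n
        sigma2 = rss / n
        if sigma2 <= 0:
            sigma2 = np.finfo(float).tiny
        logdet_v = self.logdet_d + float(np.sum(np.log(w)))
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_v + n)
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        return ll, beta, sigma2, XtX_inv, rss

    def loglik(self, lam: float) -> float:
        return self.fit_at(lam)[0]

    def maximize(self) -> tuple[float, float]:
        """Grid search over λ plus bounded local refinement."""
        lls = np.array([self.loglik(l) for l in _LAMBDA_GRID])
        k = int(np.argmax(lls))
        best_lam, best_ll = float(_LAMBDA_GRID[k]), float(lls[k])
        lo = _LAMBDA_GRID[max(k - 1, 0)]
        hi = _LAMBDA_GRID[min(k + 1, len(_LAMBDA_GRID) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda l: -self.loglik(l),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-7},
            )
            if -res.fun > best_ll:
                best_lam, best_ll = float(res.x), float(-res.fun)
        return best_lam, best_ll


def _prepare(tree_or_cov, order: list[str] | None = None) -> PhyloCovariance:
    if isinstance(tree_or_cov, PhyloCovariance):
        cov = tree_or_cov
    else:
        cov = phylo_covariance(tree_or_cov)
    if order is not None and order != cov.tip_order:
        cov = cov.submatrix(order)
    return cov


def estimate_lambda_signal(
    y,
    tree_or_cov,
    species: list[str] | None = None,
    chisq_mixture: bool = True,
) -> SignalEstimate:
    """ML estimate of Pagel's λ for one trait, with an LR test against λ=0.

    ``species`` gives the order of ``y``; defaults to the tree's tip order.
    The boundary-respecting null for the LR statistic is the 50:50 mixture
    of a point mass at 0 and chi-square(1); set ``chisq_mixture=False`` for
    the plain chi-square(1) reference.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance trait")
    cov = _prepare(tree_or_cov, species)
    X = np.ones((len(y), 1))
    prof = _LambdaProfile(cov.matrix, X, y)
    lam_hat, ll_hat = prof.maximize()
    ll0 = prof.loglik(0.0)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    if chisq_mixture:
        p = 0.5 * p if lr > 0 else 1.0
    return SignalEstimate(lam_hat, ll_hat, ll0, p, n=len(y))


def pgls_fit(
    y,
    x,
    tree_or_cov,
    species: list[str] | None = None,
    fixed_lambda: float | None = None,
) -> PGLSFit:
    """PGLS regression of y on x under the λ model (joint ML over β, σ², λ).

    The slope p-value is from a t statistic with n-2 degrees of freedom,
    using the unbiased residual-variance estimate at the fitted λ.
    ``fixed_lambda`` skips the profile and conditions on the given λ.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("y and x lengths differ")
    if len(y) < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    cov = _prepare(tree_or_cov, species)
    X = np.column_stack([np.ones_like(x), x])
    prof = _LambdaProfile(cov.matrix, X, y)
    if fixed_lambda is not None:
        if not 0.0 <= fixed_lambda <= 1.0:
            raise ValueError("fixed_lambda must be in [0, 1]")
        lam_hat = float(fixed_lambda)
        ll = prof.loglik(lam_hat)
        if not np.isfinite(ll):
            raise ValueError(f"V(lambda) singular at lambda={lam_hat}")
    else:
        lam_hat, ll = prof.maximize()
    ll, beta, sigma2_ml, XtX_inv, rss = prof.fit_at(lam_hat)
    n = len(y)
    sigma2_unbiased = rss / (n - 2)
    se = float(np.sqrt(sigma2_unbiased * XtX_inv[1, 1]))
    tstat = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
    p = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
    return PGLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        lambda_hat=lam_hat,
        sigma2_hat=float(sigma2_ml),
        slope_p=p,
        slope_se=se,
        loglik=float(ll),
        n=n,
    )
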