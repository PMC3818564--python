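"""Phylogenetic signal estimation.

Two estimators, one per trait type:

* Pagel's lambda for continuous traits — the multiplier of the off-diagonal
  entries of the Brownian variance-covariance matrix, fitted by maximum
  likelihood over [0, 1] and tested against lambda = 0 with a likelihood
  ratio test (chi-square, 1 df).
* The Fritz-Purvis D statistic for binary traits — the observed sum of
  sister-clade differences scaled between its expectations under a
  prevalence-preserving random shuffle (D = 1) and a Brownian-threshold
  model (D = 0), with tail-proportion tests against both nulls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .phylo import PhyloTree, VCVMatrix, resolve_polytomies, vcv
from .simulate import _chol_of, _random_binary_matrix, _threshold_binary_matrix

__all__ = [
    "LambdaFit",
    "DResult",
    "lambda_vcv",
    "gls_profile_loglik",
    "fit_lambda",
    "d_observed",
    "fit_d",
]


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------


def lambda_vcv(V: VCVMatrix, lam: float) -> VCVMatrix:
    """Multiply the off-diagonal entries of V by ``lam``; diagonal unchanged."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    d = np.diag(V.matrix)
    M = lam * V.matrix + (1.0 - lam) * np.diag(d)
    return VCVMatrix(labels=V.labels, matrix=M)


def gls_profile_loglik(
    y: np.ndarray, X: np.ndarray, V: Union[VCVMatrix, np.ndarray]
) -> Tuple[float, np.ndarray, float]:
    """ML-profiled GLS log-likelihood.

    Returns ``(lnL, beta_hat, sigma2_hat)`` where
    ``beta_hat = (X' V^-1 X)^-1 X' V^-1 y``, ``sigma2_hat = e' V^-1 e / n``
    and ``lnL = -0.5 * (n ln(2 pi sigma2) + ln|V| + n)``, i.e. the
    multivariate-normal log-density at the profiled optimum.  Invariant to
    a global rescaling of V (absorbed by sigma2).
    """
    Vm = V.matrix if isinstance(V, VCVMatrix) else np.asarray(V)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    try:
        c = cho_factor(Vm, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("covariance matrix is not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    Vi_X = cho_solve(c, X)
    Vi_y = cho_solve(c, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    e = y - X @ beta
    quad = float(e @ cho_solve(c, e))
    sigma2 = quad / n
    if sigma2 <= 0 or sigma2 < 1e-14 * float(y @ y + 1.0) / n:
        raise ValueError("residual variance is (numerically) zero: perfect fit")
    lnL = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return float(lnL), beta, float(sigma2)


def _profile_lambda(
    y: np.ndarray,
    X: np.ndarray,
    V: VCVMatrix,
    grid_size: int = 101,
    tie_tol: float = 1e-8,
) -> Tuple[float, float, np.ndarray, float]:
    """Maximize the profiled GLS lnL over lambda in [0, 1].

    A 101-point grid pre-scan guards against local optima; Brent refinement
    runs between the grid neighbours of the best point.  Ties within
    ``tie_tol`` log-likelihood units are broken toward lambda = 0.
    Returns ``(lambda_hat, lnL_hat, beta_hat, sigma2_hat)``.
    """

    def nll(lam: float) -> float:
        return -gls_profile_loglik(y, X, lambda_vcv(V, lam))[0]

    grid = np.linspace(0.0, 1.0, grid_size)
    vals = np.array([nll(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    if hi > lo:
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        lam_hat, f_hat = float(res.x), float(res.fun)
        if vals[i] < f_hat:
            lam_hat, f_hat = float(grid[i]), float(vals[i])
    else:  # pragma: no cover - degenerate single-point grid
        lam_hat, f_hat = float(grid[i]), float(vals[i])
    # tie-break toward no signal
    if vals[0] <= f_hat + tie_tol:
        lam_hat, f_hat = 0.0, float(vals[0])
    lnL, beta, sigma2 = gls_profile_loglik(y, X, lambda_vcv(V, lam_hat))
    return lam_hat, lnL, beta, sigma2


@dataclass
class LambdaFit:
    """Maximum-likelihood Pagel's lambda with its test against lambda = 0.

    ``lambda_hat`` is capped at 1 (the search interval is [0, 1]); ``mu`` and
    ``sigma2`` are the profiled intercept and Brownian rate at the optimum.
    """

    lambda_hat: float
    loglik: float
    loglik_zero: float
    lr: float
    p_value: float
    mu: float
    sigma2: float
    n: int


def fit_lambda(tree_or_vcv: Union[PhyloTree, VCVMatrix], y) -> LambdaFit:
    """Fit Pagel's lambda by ML for a continuous trait.

    ``y`` may be an array aligned to the tree's tip order or a mapping /
    pandas Series keyed by tip label.  The likelihood-ratio test against
    lambda = 0 uses the upper tail of chi-square with 1 df (conservative by
    half at the boundary).
    """
    V = tree_or_vcv if isinstance(tree_or_vcv, VCVMatrix) else vcv(tree_or_vcv)
    y = _align(y, V.labels)
    if V.n < 4:
        raise ValueError("need at least 4 tips to estimate lambda")
    if np.allclose(y, y[0]):
        raise ValueError("trait is constant: lambda is unidentifiable")
    X = np.ones((V.n, 1))
    lam_hat, lnL, beta, sigma2 = _profile_lambda(y, X, V)
    lnL0 = gls_profile_loglik(y, X, lambda_vcv(V, 0.0))[0]
    lr = max(2.0 * (lnL - lnL0), 0.0)
    p = float(chi2.sf(lr, df=1))
    return LambdaFit(
        lambda_hat=lam_hat, loglik=lnL, loglik_zero=lnL0, lr=lr,
        p_value=p, mu=float(beta[0]), sigma2=sigma2, n=V.n,
    )


def _align(y, labels: Sequence[str]) -> np.ndarray:
    """Align a trait vector to a tip-label order (mapping, Series or array)."""
    if hasattr(y, "reindex"):  # pandas Series
        arr = y.reindex(list(labels)).to_numpy(dtype=float)
        if np.isnan(arr).any():
            missing = [l for l, v in zip(labels, arr) if np.isnan(v)]
            raise KeyError(f"trait values missing for tips: {missing[:5]}")
        return arr
    if isinstance(y, Mapping):
        try:
            return np.array([float(y[l]) for l in labels])
        except KeyError as exc:
            raise KeyError(f"trait value missing for tip {exc}") from exc
    arr = np.asarray(y, dtype=float).ravel()
    if arr.size != len(labels):
        raise ValueError(f"trait vector length {arr.size} != number of tips {len(labels)}")
    return arr


# ---------------------------------------------------------------------------
# Fritz-Purvis D
# ---------------------------------------------------------------------------


class _SisterIndex:
    """Postorder (left, right) indexing of a binary tree for vectorized
    sister-clade difference sums across many replicate state columns."""

    def __init__(self, tree: PhyloTree):
        work = tree if tree.is_binary else resolve_polytomies(tree)
        self.labels = work.tip_labels
        nodes = list(work.postorder())
        index = {id(n): i for i, n in enumerate(nodes)}
        self.n_tips = len(self.labels)
        self.tip_slots = []
        pairs = []
        slot_of = {}
        next_tip = 0
        for i, node in enumerate(nodes):
            if node.is_tip:
                slot_of[i] = next_tip
                next_tip += 1
            else:
                l, r = node.children
                pairs.append((index[id(l)], index[id(r)], i))
        # map node index -> row in the values array: tips first (in tip order
        # of `work`), then internals in postorder
        row_of = {}
        tip_order = {id(t): j for j, t in enumerate(work.tips())}
        internal_row = self.n_tips
        for i, node in enumerate(nodes):
            if node.is_tip:
                row_of[i] = tip_order[id(node)]
            else:
                row_of[i] = internal_row
                internal_row += 1
        self.n_nodes = internal_row
        self.pairs = [(row_of[l], row_of[r], row_of[i]) for l, r, i in pairs]

    def d_sum(self, states: np.ndarray) -> np.ndarray:
        """Sum of |left - right| nodal contrasts; nodal values are unweighted
        daughter means (branch lengths are ignored, per the D definition).

        ``states`` has shape (n_tips,) or (n_tips, n_reps); returns a scalar
        array of shape () or (n_reps,).
        """
        S = np.asarray(states, dtype=float)
        single = S.ndim == 1
        if single:
            S = S[:, None]
        vals = np.empty((self.n_nodes, S.shape[1]))
        vals[: self.n_tips] = S
        d = np.zeros(S.shape[1])
        for l, r, i in self.pairs:
            d += np.abs(vals[l] - vals[r])
            vals[i] = 0.5 * (vals[l] + vals[r])
        return d[0] if single else d


def d_observed(tree: PhyloTree, states) -> float:
    """Observed sum of sister-clade differences for a binary trait.

    Nodal values are estimated bottom-up as the unweighted mean of the two
    daughter values (tips carry their 0/1 states); the statistic is the sum
    over internal nodes of the absolute difference between the daughters.
    """
    idx = _SisterIndex(tree)
    s = _align(states, idx.labels)
    if set(np.unique(s)) - {0.0, 1.0}:
        raise ValueError("states must be binary 0/1")
    if s.min() == s.max():
        raise ValueError("trait is constant: D is undefined")
    return float(idx.d_sum(s))


@dataclass
class DResult:
    """Fritz-Purvis D for a binary trait with both simulated nulls.

    ``D = (d_obs - mean_brownian) / (mean_random - mean_brownian)``;
    values below 0 indicate stronger-than-Brownian phylogenetic clumping.
    ``p_random`` is the lower-tail proportion of random-shuffle d values at
    or below ``d_obs`` (departure from D = 1); ``p_brownian`` the upper-tail
    proportion of Brownian-threshold d values at or above it (departure
    from D = 0).
    """

    d_obs: float
    mean_random: float
    mean_brownian: float
    D: float
    p_random: float
    p_brownian: float
    n_sim: int
    seed: int


def fit_d(tree: PhyloTree, states, n_sim: int = 1000, seed: int = 0) -> DResult:
    """Estimate the D statistic of a binary trait with simulated nulls.

    Both nulls preserve the observed number of tips in state 1: the random
    null shuffles states across tips; the Brownian null thresholds a
    simulated Brownian liability.  ``n_sim`` replicates are drawn per null.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    idx = _SisterIndex(tree)
    s = _align(states, idx.labels)
    if set(np.unique(s)) - {0.0, 1.0}:
        raise ValueError("states must be binary 0/1")
    n_ones = int(s.sum())
    n = idx.n_tips
    if not 0 < n_ones < n:
        raise ValueError("trait is constant: D is undefined")

    d_obs = float(idx.d_sum(s))
    rng = np.random.default_rng(seed)
    rand_states = _random_binary_matrix(n, n_ones, n_sim, rng)
    d_rand = idx.d_sum(rand_states)
    L = _chol_of(vcv(tree).matrix)
    brown_states = _threshold_binary_matrix(L, n_ones, n_sim, rng)
    d_brown = idx.d_sum(brown_states)

    mean_random = float(d_rand.mean())
    mean_brownian = float(d_brown.mean())
    if np.isclose(mean_random, mean_brownian):
        raise ValueError(
            "degenerate D scaling: random and Brownian null means coincide"
        )
    D = (d_obs - mean_brownian) / (mean_random - mean_brownian)
    return DResult(
        d_obs=d_obs,
        mean_random=mean_random,
        mean_brownian=mean_brownian,
        D=float(D),
        p_random=float(np.mean(d_rand <= d_obs)),
        p_brownian=float(np.mean(d_brown >= d_obs)),
        n_sim=n_sim,
        seed=seed,
    )
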