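"""Phylogenetic generalized least squares with ML-estimated lambda,
AIC model selection and evidence ratios.

The regression model is y = X beta + e with e ~ N(0, sigma2 * V(lambda)),
V the Brownian tree covariance and lambda the off-diagonal multiplier
jointly ML-estimated with the coefficients (grid pre-scan plus Brent, the
same procedure as the signal module, for determinism).

Parameter-count convention: k = (number of coefficients) + 1 for sigma2
+ 1 if lambda is ML-estimated.  Only AIC *differences* within a battery
matter for evidence ratios, and both the model and its null estimate
lambda, so the convention cancels there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .phylo import PhyloTree, VCVMatrix, vcv
from .signal import _align, _profile_lambda, gls_profile_loglik, lambda_vcv

__all__ = [
    "PGLSFit",
    "ModelComparison",
    "fit_pgls",
    "aic_of",
    "evidence_ratio",
    "residuals_of",
    "compare_to_null",
]


@dataclass
class PGLSFit:
    """A fitted PGLS regression.

    ``params``/``se`` are aligned with ``names`` (intercept first).
    Standard errors use the unbiased residual-variance scaling
    ``sigma2 * n / (n - p)``; ``sigma2``, ``loglik`` and ``aic`` use the ML
    profile.  ``r2`` compares the model's whitened residual sum of squares
    with that of an intercept-only GLS fit under the same lambda.
    Residuals are on the response scale (y - X beta).
    """

    params: np.ndarray
    se: np.ndarray
    names: Tuple[str, ...]
    lambda_: float
    lambda_mode: str
    sigma2: float
    loglik: float
    k: int
    aic: float
    r2: float
    residuals: np.ndarray
    species: Tuple[str, ...]
    n: int

    @property
    def slope(self) -> float:
        """Coefficient of the first non-intercept predictor."""
        return float(self.params[1])


def aic_of(loglik: float, k: int) -> float:
    """Akaike's information criterion, 2k - 2 lnL."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * loglik


def evidence_ratio(aic_null: float, aic_model: float) -> float:
    """Relative likelihood of the model versus the null:
    exp((AIC_null - AIC_model) / 2)."""
    return math.exp((aic_null - aic_model) / 2.0)


@dataclass
class ModelComparison:
    """AIC comparison of a model against its null."""

    aic_model: float
    aic_null: float
    delta_aic: float   # AIC_null - AIC_model; positive favours the model
    er: float          # evidence ratio, exp(delta/2)
    better_than_null: bool


def compare_to_null(aic_null: float, aic_model: float) -> ModelComparison:
    delta = aic_null - aic_model
    return ModelComparison(
        aic_model=aic_model,
        aic_null=aic_null,
        delta_aic=delta,
        er=evidence_ratio(aic_null, aic_model),
        better_than_null=aic_model < aic_null,
    )


def fit_pgls(
    tree_or_vcv: Union[PhyloTree, VCVMatrix],
    y,
    X: Optional[np.ndarray] = None,
    lambda_mode: Union[str, float] = "ML",
    names: Optional[Sequence[str]] = None,
) -> PGLSFit:
    """Fit a PGLS regression.

    ``X`` is the design matrix including an intercept column first (``None``
    fits the intercept-only model).  ``lambda_mode`` is ``"ML"`` or a fixed
    value in [0, 1].  ``y`` may be an array in tip order or a Series/mapping
    keyed by tip label.
    """
    V = tree_or_vcv if isinstance(tree_or_vcv, VCVMatrix) else vcv(tree_or_vcv)
    yv = _align(y, V.labels)
    n = V.n
    if X is None:
        X = np.ones((n, 1))
        if names is None:
            names = ("intercept",)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    p = X.shape[1]
    if names is None:
        names = ("intercept",) + tuple(f"x{i}" for i in range(1, p))
    if len(names) != p:
        raise ValueError("names must match the number of design columns")
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("design matrix must include an intercept as its first column")

    if lambda_mode == "ML":
        lam, lnL, beta, sigma2 = _profile_lambda(yv, X, V)
        k = p + 2
        mode = "ML"
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("fixed lambda must be in [0, 1]")
        lnL, beta, sigma2 = gls_profile_loglik(yv, X, lambda_vcv(V, lam))
        k = p + 1
        mode = "fixed"
    if n <= k:
        raise ValueError(f"too few observations (n={n}) for k={k} parameters")

    Vl = lambda_vcv(V, lam).matrix
    Vi = np.linalg.inv(Vl)
    XtViX = X.T @ Vi @ X
    cov_beta = sigma2 * n / (n - p) * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))

    e = yv - X @ beta
    quad = float(e @ Vi @ e)
    if p == 1:
        r2 = 0.0
    else:
        _, beta0, sigma2_0 = gls_profile_loglik(yv, np.ones((n, 1)), Vl)
        quad0 = sigma2_0 * n
        r2 = 1.0 - quad / quad0

    return PGLSFit(
        params=beta,
        se=se,
        names=tuple(names),
        lambda_=lam,
        lambda_mode=mode,
        sigma2=sigma2,
        loglik=lnL,
        k=k,
        aic=aic_of(lnL, k),
        r2=r2,
        residuals=e,
        species=tuple(V.labels),
        n=n,
    )


def residuals_of(fit: PGLSFit) -> np.ndarray:
    """Response-scale residuals y - X beta, in ``fit.species`` order.

    Feeding these into ``fit_lambda`` gives the phylogenetic signal of the
    trait after removing the fitted allometric (or other) regression —
    e.g. residual antennal size after controlling for body size.
    """
    return fit.residuals
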