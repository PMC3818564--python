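"""Simulation-based recovery experiments.

Each experiment simulates data under a known generating process and
measures how well the corresponding estimator recovers the generating
value: Pagel's lambda under Brownian motion (truth 1) and under tip
shuffling (truth 0), Fritz-Purvis D under random assignment (truth 1) and
Brownian thresholding (truth 0), and the PGLS slope under a known
allometry.  Used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .pgls import fit_pgls
from .signal import fit_d, fit_lambda
from .simulate import brownian_trait, random_binary, threshold_binary, yule_tree

__all__ = ["lambda_recovery", "d_recovery", "slope_recovery"]


def _child_seeds(seed: int, n: int, k: int = 3) -> np.ndarray:
    """Derive n x k independent sub-seeds (< 2^31) from a master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=(n, k))


def lambda_recovery(
    n_reps: int = 200, n_tips: int = 128, seed: int = 0, shuffle: bool = False
) -> np.ndarray:
    """ML lambda estimates for Brownian traits on fresh Yule trees.

    With ``shuffle=True`` the trait values are randomly permuted across the
    tips before fitting, destroying the phylogenetic structure (the
    generating lambda is then effectively 0; otherwise it is 1).
    """
    seeds = _child_seeds(seed, n_reps)
    out = np.empty(n_reps)
    for i, (s_tree, s_trait, s_perm) in enumerate(seeds):
        tree = yule_tree(n_tips, int(s_tree))
        y = brownian_trait(tree, sigma2=1.0, root_state=0.0, seed=int(s_trait))
        if shuffle:
            y = np.random.default_rng(int(s_perm)).permutation(y)
        out[i] = fit_lambda(tree, y).lambda_hat
    return out


def d_recovery(
    n_reps: int = 200,
    n_tips: int = 128,
    n_ones: int = 32,
    n_sim: int = 1000,
    mode: str = "random",
    seed: int = 0,
) -> np.ndarray:
    """D estimates for binary traits of known generating process.

    ``mode="random"`` assigns state 1 uniformly at random (generating D of
    1); ``mode="threshold"`` thresholds a Brownian liability (generating D
    of 0).  Each fit uses ``n_sim`` simulations per null.
    """
    if mode not in ("random", "threshold"):
        raise ValueError("mode must be 'random' or 'threshold'")
    seeds = _child_seeds(seed, n_reps)
    out = np.empty(n_reps)
    for i, (s_tree, s_trait, s_fit) in enumerate(seeds):
        tree = yule_tree(n_tips, int(s_tree))
        if mode == "random":
            states = random_binary(tree.tip_labels, n_ones, int(s_trait))
        else:
            states = threshold_binary(tree, n_ones, int(s_trait))
        out[i] = fit_d(tree, states, n_sim=n_sim, seed=int(s_fit)).D
    return out


def slope_recovery(
    n_reps: int = 200,
    n_tips: int = 126,
    slope: float = 2.0,
    intercept: float = -2.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """PGLS slope estimates under a known log-log scaling relationship.

    Log "length" evolves by Brownian motion (sigma2 = 1); log "area" is
    ``intercept + slope * length`` plus independent normal noise.  The
    default slope of 2 is the isometric expectation for an areal measure
    regressed on a linear one.
    """
    seeds = _child_seeds(seed, n_reps)
    out = np.empty(n_reps)
    for i, (s_tree, s_trait, s_noise) in enumerate(seeds):
        tree = yule_tree(n_tips, int(s_tree))
        x = brownian_trait(tree, sigma2=1.0, root_state=0.0, seed=int(s_trait))
        noise = np.random.default_rng(int(s_noise)).normal(0.0, noise_sd, size=n_tips)
        y = intercept + slope * x + noise
        X = np.column_stack([np.ones(n_tips), x])
        fit = fit_pgls(tree, y, X, lambda_mode="ML", names=("intercept", "log_length"))
        out[i] = fit.slope
    return out
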