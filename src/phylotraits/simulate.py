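"""Synthetic data generation: pure-birth trees, continuous traits under
Brownian and lambda-transformed models, binary traits under random and
Brownian-threshold models, and a full synthetic comparative study.

The study emulator produces a species-by-trait table with the structure of
a parasitoid-wasp morphology/ecology dataset: log body length evolving by
Brownian motion, log antennal area tied allometrically to body length,
right-skewed host-species counts, derived host-order and plant-genus
counts, and phylogenetically clumped binary host-use flags.  It emulates
structure only; its parameter values are configuration, not estimates of
any real clade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .phylo import Node, PhyloTree, VCVMatrix, vcv

__all__ = [
    "SimConfig",
    "yule_tree",
    "brownian_trait",
    "lambda_trait",
    "threshold_binary",
    "random_binary",
    "synthetic_study",
]

SeedLike = Union[int, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def yule_tree(n_tips: int, seed: SeedLike, birth_rate: float = 1.0) -> PhyloTree:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` tips.

    The root is the first split (two lineages at time zero).  While ``k``
    lineages are extant the waiting time to the next split is
    ``Exponential(k * birth_rate)``; after the tree reaches ``n_tips`` tips
    all pendant edges are extended by one final ``Exponential(n * birth_rate)``
    draw, so the expected root-to-tip depth is ``sum_{k=2..n} 1/(k*birth_rate)``.
    The result is exactly ultrametric.  Tips are labelled ``s1..sN`` in tree
    order.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _rng(seed)

    root = Node()
    active: List[Tuple[Node, float]] = []  # (node, time its edge started)
    for _ in range(2):
        child = Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, start = active.pop(i)
        node.length = t - start
        for _ in range(2):
            child = Node()
            node.add_child(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / (n_tips * birth_rate))
    for node, start in active:
        node.length = t_end - start
    # label tips s1..sN in tree (left-to-right preorder) order
    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.children:
            counter += 1
            node.label = f"s{counter}"
        stack.extend(reversed(node.children))
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Continuous traits
# ---------------------------------------------------------------------------


def _chol_of(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor with a tiny diagonal jitter on failure (near-singular
    covariances arise for lambda -> 1 on trees with very short pendant edges)."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(cov) / cov.shape[0]
        return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))


def _lambda_cov(V: VCVMatrix, lam: float, sigma2: float) -> np.ndarray:
    cov = lam * V.matrix + (1.0 - lam) * np.diag(np.diag(V.matrix))
    return sigma2 * cov


def lambda_trait(
    tree: PhyloTree,
    lam: float,
    sigma2: float,
    seed: SeedLike,
    root_state: float = 0.0,
    n_reps: int = 1,
) -> np.ndarray:
    """Draw tip values from MVN(root_state, sigma2 * V(lambda)) where
    V(lambda) has its off-diagonal entries multiplied by ``lam``.

    Returns a vector aligned to ``tree.tip_labels`` (or an ``(n, n_reps)``
    matrix when ``n_reps > 1``).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = _rng(seed)
    V = vcv(tree)
    L = _chol_of(_lambda_cov(V, lam, sigma2))
    z = rng.standard_normal((V.n, n_reps))
    out = root_state + L @ z
    return out[:, 0] if n_reps == 1 else out


def brownian_trait(
    tree: PhyloTree,
    sigma2: float,
    root_state: float,
    seed: SeedLike,
    n_reps: int = 1,
) -> np.ndarray:
    """Brownian-motion tip values: MVN(root_state, sigma2 * V).  Identical to
    :func:`lambda_trait` with ``lam=1`` (same seed gives the same draw)."""
    return lambda_trait(tree, 1.0, sigma2, seed, root_state=root_state, n_reps=n_reps)


# ---------------------------------------------------------------------------
# Binary traits
# ---------------------------------------------------------------------------


def _random_binary_matrix(n: int, n_ones: int, n_reps: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.random((n_reps, n))
    ranks = u.argsort(axis=1).argsort(axis=1)
    return (ranks < n_ones).astype(np.int8).T  # shape (n, n_reps)


def _threshold_binary_matrix(
    chol: np.ndarray, n_ones: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    n = chol.shape[0]
    liab = chol @ rng.standard_normal((n, n_reps))
    # rank within each replicate column; top n_ones get state 1
    order = np.argsort(-liab, axis=0)
    out = np.zeros((n, n_reps), dtype=np.int8)
    cols = np.arange(n_reps)
    for k in range(n_ones):
        out[order[k, :], cols] = 1
    return out


def random_binary(labels: Sequence[str], n_ones: int, seed: SeedLike) -> np.ndarray:
    """Uniformly random assignment of exactly ``n_ones`` ones over the tips
    (the no-signal null: a prevalence-preserving tip shuffle)."""
    n = len(labels)
    if not 0 < n_ones < n:
        raise ValueError(f"n_ones must be strictly between 0 and {n}")
    return _random_binary_matrix(n, n_ones, 1, _rng(seed))[:, 0]


def threshold_binary(tree: PhyloTree, n_ones: int, seed: SeedLike) -> np.ndarray:
    """Binary trait from a thresholded Brownian liability: simulate a
    Brownian trait and assign state 1 to the ``n_ones`` tips with the
    largest values, so the tip-state counts match a target prevalence."""
    n = tree.n_tips
    if not 0 < n_ones < n:
        raise ValueError(f"n_ones must be strictly between 0 and {n}")
    V = vcv(tree)
    L = _chol_of(V.matrix)
    return _threshold_binary_matrix(L, n_ones, 1, _rng(seed))[:, 0]


# ---------------------------------------------------------------------------
# Full study emulation
# ---------------------------------------------------------------------------

#: on-disk column names of the trait table (first column is the join key)
SPECIES_COL = "species"
RAW_CONTINUOUS_COLS = ("body_length_mm", "antennal_area_mm2")
COUNT_COLS = ("n_host_species", "n_host_orders", "n_plant_genera")
BINARY_COLS = (
    "parasitoid",
    "egg_parasitoid",
    "specialist",
    "para_hemiptera",
    "para_sternorrhyncha",
    "para_other_hemiptera",
    "para_diptera",
    "para_lepidoptera",
    "para_coleoptera",
    "para_hymenoptera",
)


@dataclass
class SimConfig:
    """Configuration of the synthetic comparative study.

    Defaults give a 126-species study: Brownian log body length, antennal
    area scaling with slope 1.7 on the log-log scale with a moderately
    phylogenetic residual, lognormal (right-skewed) host-species counts,
    and phylogenetically clumped host-use flags with a randomly scattered
    specialist/generalist axis (prevalences in ``binary_traits`` with
    clumping mode "brownian" or "random" per flag).
    """

    n_species: int = 126
    birth_rate: float = 1.0
    sigma2: float = 0.25                    # Brownian rate of log body length
    root_log_body: float = 0.4              # log(mm); about a 1.5 mm wasp
    allometry_intercept: float = -2.0       # log(mm^2) at log body length 0
    allometry_slope: float = 1.7
    lambda_resid: float = 0.5               # phylogenetic signal of the antennal residual
    resid_var: float = 0.02                 # variance of the antennal residual
    host_log_mean: float = 1.0              # lognormal latent for host-species counts
    host_log_sd: float = 1.2
    binary_traits: Dict[str, Tuple[float, str]] = field(
        default_factory=lambda: {
            "parasitoid": (0.90, "brownian"),
            "egg_parasitoid": (0.16, "brownian"),
            "para_sternorrhyncha": (0.25, "brownian"),
            "para_other_hemiptera": (0.07, "brownian"),
            "para_diptera": (0.15, "brownian"),
            "para_lepidoptera": (0.20, "brownian"),
            "para_coleoptera": (0.15, "brownian"),
            "para_hymenoptera": (0.12, "brownian"),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.sigma2 <= 0 or self.resid_var < 0:
            raise ValueError("variances must be positive")
        if not 0.0 <= self.lambda_resid <= 1.0:
            raise ValueError("lambda_resid must be in [0, 1]")
        for name, (prev, mode) in self.binary_traits.items():
            if not 0.0 < prev < 1.0:
                raise ValueError(f"prevalence of {name} must be in (0, 1)")
            if mode not in ("brownian", "random"):
                raise ValueError(f"unknown clumping mode {mode!r} for {name}")


def synthetic_study(config: Optional[SimConfig] = None) -> Tuple[PhyloTree, pd.DataFrame]:
    """Generate a full synthetic study: a Yule tree plus a raw trait table.

    The returned table holds untransformed values (mm, mm^2, counts, 0/1
    flags); the pipeline loader applies the log transforms.  Bit-identical
    under a fixed ``config.seed``.
    """
    config = config or SimConfig()
    config.validate()
    master = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in master.spawn(8)]
    (rng_tree, rng_body, rng_resid, rng_host, rng_orders,
     rng_plants, rng_flags, rng_extra) = streams

    n = config.n_species
    tree = yule_tree(n, rng_tree, birth_rate=config.birth_rate)
    labels = tree.tip_labels

    log_body = brownian_trait(tree, config.sigma2, config.root_log_body, rng_body)
    resid = (
        lambda_trait(tree, config.lambda_resid, config.resid_var, rng_resid)
        if config.resid_var > 0
        else np.zeros(n)
    )
    log_area = config.allometry_intercept + config.allometry_slope * log_body + resid

    # right-skewed host-species counts: lognormal latent, rounded up to >= 1
    latent = rng_host.lognormal(config.host_log_mean, config.host_log_sd, size=n)
    n_hosts = np.maximum(np.ceil(latent), 1.0).astype(int)

    # host-order breadth grows (noisily) with host-species breadth
    order_rate = 0.35 * np.log1p(n_hosts)
    n_orders = 1 + np.minimum(rng_orders.poisson(order_rate), 5)

    # plant associates: independent right-skewed counts, may be zero
    n_plants = np.floor(rng_plants.lognormal(0.5, 1.0, size=n)).astype(int)

    table = pd.DataFrame({SPECIES_COL: labels})
    table["body_length_mm"] = np.exp(log_body)
    table["antennal_area_mm2"] = np.exp(log_area)
    table["n_host_species"] = n_hosts
    table["n_host_orders"] = n_orders
    table["n_plant_genera"] = n_plants

    flag_seeds = rng_flags.integers(0, 2**31 - 1, size=len(config.binary_traits))
    V = vcv(tree)
    L = _chol_of(V.matrix)
    flags: Dict[str, np.ndarray] = {}
    for (name, (prev, mode)), s in zip(config.binary_traits.items(), flag_seeds):
        n_ones = min(max(int(round(prev * n)), 1), n - 1)
        r = np.random.default_rng(int(s))
        if mode == "brownian":
            flags[name] = _threshold_binary_matrix(L, n_ones, 1, r)[:, 0]
        else:
            flags[name] = _random_binary_matrix(n, n_ones, 1, r)[:, 0]

    table["parasitoid"] = flags["parasitoid"]
    table["egg_parasitoid"] = flags["egg_parasitoid"]
    # specialist rule: fewer than 10 host species, all in a single order
    table["specialist"] = (
        (table["n_host_species"] < 10) & (table["n_host_orders"] == 1)
    ).astype(np.int8) * table["parasitoid"].astype(np.int8)
    table["para_sternorrhyncha"] = flags["para_sternorrhyncha"]
    table["para_other_hemiptera"] = flags["para_other_hemiptera"]
    table["para_hemiptera"] = (
        (flags["para_sternorrhyncha"] | flags["para_other_hemiptera"]).astype(np.int8)
    )
    for name in ("para_diptera", "para_lepidoptera", "para_coleoptera", "para_hymenoptera"):
        table[name] = flags[name]
    table = table[[SPECIES_COL, *RAW_CONTINUOUS_COLS, *COUNT_COLS, *BINARY_COLS]]
    return tree, table
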