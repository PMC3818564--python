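"""Rooted-tree data model, Newick I/O, tree surgery, phylogenetic covariance,
penalized-likelihood rate smoothing, and Fitch parsimony.

The tree-surgery operations implement the composite-phylogeny assembly rules
used when a backbone phylogeny lacks species-level resolution: a missing
congener can be attached as a sibling branching halfway along an existing
pendant edge, and a published intrageneric phylogeny can be grafted onto the
backbone after rescaling its branch lengths so that a shared reference
species keeps its backbone root-to-tip distance.

All surgery functions are pure: they return modified copies and never mutate
their inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterator, List, Mapping, Optional, Sequence, Set

import dendropy
import numpy as np
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "NewickError",
    "PLOptimizationError",
    "Node",
    "PhyloTree",
    "VCVMatrix",
    "Chronogram",
    "parse_newick",
    "write_newick",
    "prune_to",
    "attach_sibling_halfway",
    "graft_rescaled",
    "set_equal_branch_lengths",
    "vcv",
    "is_ultrametric",
    "resolve_polytomies",
    "ultrametricize_pl",
    "count_origins_fitch",
]


class NewickError(ValueError):
    """Raised for malformed or inconsistent Newick input."""


class PLOptimizationError(RuntimeError):
    """Raised when penalized-likelihood rate smoothing fails to converge.

    Carries the best objective value found in ``best_objective``.
    """

    def __init__(self, message: str, best_objective: float):
        super().__init__(message)
        self.best_objective = best_objective


class Node:
    """A node of a rooted tree.

    ``length`` is the length of the edge subtending this node (``None`` for
    the root, or when the source tree carried no branch lengths).
    """

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.parent: Optional["Node"] = None
        self.children: List["Node"] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} len={self.length}>"


class PhyloTree:
    """A rooted phylogeny with optional branch lengths and unique tip labels."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            # reversed keeps left-to-right child order in the yielded sequence
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: List[Node] = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> List[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def find_tip(self, label: str) -> Node:
        for n in self.tips():
            if n.label == label:
                return n
        raise KeyError(f"tip {label!r} not found")

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder() if not n.is_tip)

    @property
    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.preorder() if n.parent is not None)

    # -- metrics -----------------------------------------------------------

    def node_depths(self) -> Dict[int, float]:
        """Root-to-node path length keyed by ``id(node)``; requires lengths."""
        depths: Dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node.parent is None:
                continue
            if node.length is None:
                raise ValueError("tree has missing branch lengths")
            depths[id(node)] = depths[id(node.parent)] + node.length
        return depths

    def depths(self) -> Dict[str, float]:
        """Root-to-tip path length keyed by tip label."""
        nd = self.node_depths()
        return {n.label: nd[id(n)] for n in self.tips()}

    def max_depth(self) -> float:
        return max(self.depths().values())

    def total_length(self) -> float:
        return sum(n.length for n in self.preorder() if n.parent is not None)

    # -- copying -----------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        seen: Set[str] = set()
        for node in self.preorder():
            if node.is_tip:
                if not node.label:
                    raise NewickError("tip with empty label")
                if node.label in seen:
                    raise NewickError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
            if node.parent is not None and node.length is not None:
                if not math.isfinite(node.length) or node.length < 0:
                    raise ValueError(
                        f"negative or non-finite branch length on {node.label!r}"
                    )
        if len(seen) < 1:
            raise NewickError("tree has no labelled tips")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips>"


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; accepts quoted labels, internal
# labels, and bracketed comments)
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Missing branch lengths are preserved as absent (``None``), not zero.
    Raises :class:`NewickError` on malformed input or duplicate tip labels.
    """
    if text is None or not text.strip():
        raise NewickError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # a root edge length has no meaning here
    return PhyloTree(root)


_UNSAFE = set(" \t(),:;[]'\"")


def _format_label(label: str) -> str:
    if any(c in _UNSAFE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(x: float) -> str:
    return format(x, ".10g")


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick; omits ``:length`` tokens where absent."""

    def rec(node: Node) -> str:
        if node.is_tip:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.label:
                s += _format_label(node.label)
        if node.parent is not None and node.length is not None:
            s += ":" + _format_length(node.length)
        return s

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Tree surgery
# ---------------------------------------------------------------------------


def prune_to(tree: PhyloTree, keep: Set[str]) -> PhyloTree:
    """Restrict a tree to the tips in ``keep``.

    Unbranched internal nodes created by the pruning are suppressed with
    their branch lengths summed, so every retained tip keeps its original
    root-to-tip depth.  The root is never suppressed (a root left with a
    single child is retained, again preserving depths).
    """
    keep = set(keep)
    labels = set(tree.tip_labels)
    missing = sorted(keep - labels)
    if missing:
        raise KeyError(f"labels not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("need at least 2 tips to keep")

    out = tree.copy()
    # drop unwanted tips bottom-up
    for node in list(out.postorder()):
        if node.is_tip and node.label not in keep and node.parent is not None:
            node.parent.children.remove(node)
    # repeatedly remove childless internal nodes left behind
    changed = True
    while changed:
        changed = False
        for node in list(out.postorder()):
            if node.parent is None:
                continue
            if not node.children and node.label not in keep:
                node.parent.children.remove(node)
                changed = True
    # suppress unary internal nodes (never the root)
    for node in list(out.postorder()):
        if node.parent is not None and len(node.children) == 1:
            (child,) = node.children
            if child.length is not None and node.length is not None:
                child.length += node.length
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
    return PhyloTree(out.root)


def attach_sibling_halfway(tree: PhyloTree, existing_tip: str, new_tip: str) -> PhyloTree:
    """Attach ``new_tip`` as the sibling of ``existing_tip``, branching
    halfway along the existing pendant edge.

    Both sibling tips end up with pendant length ``b/2`` where ``b`` is the
    original pendant length, so an ultrametric tree stays ultrametric.
    """
    if new_tip in tree.tip_labels:
        raise ValueError(f"new tip {new_tip!r} already present")
    out = tree.copy()
    tip = out.find_tip(existing_tip)
    b = tip.length
    if b is None or b <= 0:
        raise ValueError(
            f"cannot bisect pendant edge of {existing_tip!r}: branch length absent or zero"
        )
    parent = tip.parent
    if parent is None:
        raise ValueError("cannot attach a sibling to the root")
    fork = Node(length=b / 2.0)
    idx = parent.children.index(tip)
    parent.children[idx] = fork
    fork.parent = parent
    tip.length = b / 2.0
    fork.add_child(tip)
    fork.add_child(Node(label=new_tip, length=b / 2.0))
    return PhyloTree(out.root)


def graft_rescaled(backbone: PhyloTree, subtree: PhyloTree, ref: str) -> PhyloTree:
    """Graft an intrageneric ``subtree`` onto ``backbone`` at the pendant
    edge of the shared reference species ``ref``.

    Every subtree branch length is multiplied by
    ``s = d_back / d_sub`` where ``d_back`` is the pendant edge length of
    ``ref`` in the backbone and ``d_sub`` its root-to-tip distance in the
    subtree; the rescaled subtree then replaces the pendant edge, rooted at
    the attachment node.  ``ref`` keeps its backbone depth exactly.
    """
    if ref not in backbone.tip_labels:
        raise KeyError(f"reference tip {ref!r} not in backbone")
    if ref not in subtree.tip_labels:
        raise KeyError(f"reference tip {ref!r} not in subtree")
    if subtree.n_tips == 1:
        return backbone.copy()
    if not subtree.has_branch_lengths:
        raise ValueError(
            "subtree lacks branch lengths; apply set_equal_branch_lengths first"
        )
    collisions = (set(subtree.tip_labels) - {ref}) & set(backbone.tip_labels)
    if collisions:
        raise ValueError(f"label collision between subtree and backbone: {sorted(collisions)}")

    d_sub = subtree.depths()[ref]
    if d_sub <= 0:
        raise ValueError("subtree root-to-reference distance is zero")

    out = backbone.copy()
    ref_node = out.find_tip(ref)
    d_back = ref_node.length
    if d_back is None or d_back <= 0:
        raise ValueError(f"backbone pendant edge of {ref!r} absent or zero")
    scale = d_back / d_sub

    scaled = subtree.copy()
    for node in scaled.preorder():
        if node.parent is not None:
            node.length = node.length * scale

    attach = ref_node.parent
    if attach is None:
        raise ValueError("reference tip is the backbone root")
    idx = attach.children.index(ref_node)
    attach.children.pop(idx)
    for i, child in enumerate(scaled.root.children):
        child.parent = attach
        attach.children.insert(idx + i, child)
    return PhyloTree(out.root)


def set_equal_branch_lengths(tree: PhyloTree, value: float) -> PhyloTree:
    """Set every non-root edge to ``value`` (used when a source phylogeny
    carries no branch length information)."""
    if value <= 0:
        raise ValueError("branch length value must be positive")
    out = tree.copy()
    for node in out.preorder():
        if node.parent is not None:
            node.length = float(value)
    return out


# ---------------------------------------------------------------------------
# Phylogenetic covariance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VCVMatrix:
    """Expected trait covariance among tips under Brownian motion.

    ``matrix[i, j]`` is the root-to-MRCA shared path length of tips
    ``labels[i]`` and ``labels[j]``; the diagonal holds root-to-tip depths.
    """

    labels: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("label/matrix size mismatch")

    @property
    def n(self) -> int:
        return len(self.labels)


def vcv(tree: PhyloTree, zero_length_eps_frac: float = 1e-8) -> VCVMatrix:
    """Compute the phylogenetic variance-covariance matrix of a tree.

    Zero-length edges are replaced by ``zero_length_eps_frac`` times the tree
    height so the matrix stays positive definite (identical tips would
    otherwise produce duplicated rows).
    """
    if not tree.has_branch_lengths:
        raise ValueError("tree has missing branch lengths")
    tips = tree.tips()
    n = len(tips)
    tip_index = {id(t): i for i, t in enumerate(tips)}

    height = tree.max_depth()
    eps = zero_length_eps_frac * height if height > 0 else zero_length_eps_frac

    def eff_len(node: Node) -> float:
        return node.length if node.length > 0 else eps

    # effective depths with the epsilon substitution
    depth: Dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + eff_len(node)

    M = np.zeros((n, n))
    # tip sets per node, assembled bottom-up
    tipsets: Dict[int, List[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            tipsets[id(node)] = [tip_index[id(node)]]
            continue
        child_sets = [tipsets[id(c)] for c in node.children]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia = np.asarray(child_sets[a])
                ib = np.asarray(child_sets[b])
                M[np.ix_(ia, ib)] = d
                M[np.ix_(ib, ia)] = d
        tipsets[id(node)] = [i for s in child_sets for i in s]
    for tip in tips:
        i = tip_index[id(tip)]
        M[i, i] = depth[id(tip)]
    return VCVMatrix(labels=tuple(t.label for t in tips), matrix=M)


def is_ultrametric(tree: PhyloTree, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip depths agree to relative tolerance."""
    d = list(tree.depths().values())
    mx = max(d)
    if mx <= 0:
        return True
    return (mx - min(d)) / mx <= rel_tol


# ---------------------------------------------------------------------------
# Polytomy resolution
# ---------------------------------------------------------------------------


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Resolve multifurcations into binary splits by left-grouping with
    zero-length edges.  Path lengths between tips are unchanged, so the
    resolution is neutral for parsimony counts and Brownian covariances."""
    out = tree.copy()
    warned = False
    for node in list(out.preorder()):
        while len(node.children) > 2:
            if not warned:
                logger.warning("resolving polytomies with zero-length left-grouping")
                warned = True
            c1 = node.children.pop(0)
            c2 = node.children.pop(0)
            group = Node(length=0.0)
            group.add_child(c1)
            group.add_child(c2)
            group.parent = node
            node.children.insert(0, group)
    return PhyloTree(out.root)


# ---------------------------------------------------------------------------
# Penalized-likelihood rate smoothing (ultrametricization)
# ---------------------------------------------------------------------------


@dataclass
class Chronogram:
    """An ultrametric tree with estimated per-edge substitution rates.

    ``ages`` and ``rates`` are aligned to ``tree.preorder()`` order; the
    root age is fixed at 1 (relative time), tips at 0, and ``rates`` is NaN
    at the root position.
    """

    tree: PhyloTree
    ages: np.ndarray
    rates: np.ndarray
    objective: float


def _pl_pack(tree: PhyloTree):
    """Index a binary tree for the PL optimizer: preorder arrays."""
    nodes = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    is_tip = np.zeros(n, dtype=bool)
    x = np.full(n, np.nan)
    for i, node in enumerate(nodes):
        if node.parent is not None:
            parent[i] = index[id(node.parent)]
            x[i] = node.length
        is_tip[i] = node.is_tip
    return nodes, parent, is_tip, x


def ultrametricize_pl(
    tree: PhyloTree,
    smoothing: float = 10.0,
    *,
    n_restarts: int = 3,
    seed: int = 0,
    maxiter: int = 2000,
) -> Chronogram:
    """Make a tree ultrametric by penalized-likelihood rate smoothing.

    Branch lengths are treated as expected substitution counts ``x_k``.
    Node ages ``a`` (root fixed at 1, tips at 0) and per-edge rates ``r_k``
    jointly maximize::

        sum_k [ x_k * ln(r_k * t_k) - r_k * t_k ]  -  smoothing * Phi(r)

    where ``t_k`` is the edge duration implied by the ages and ``Phi``
    penalizes rate changes between parent and child edges plus the variance
    of the root's daughter-edge rates.  Ages are parameterized as logistic
    fractions of the parent's age (so the age ordering constraint holds by
    construction) and rates on the log scale; the optimizer is multi-start
    L-BFGS with an analytic gradient.

    Zero-length input edges are replaced by ``1e-8`` times tree height.
    Non-binary trees are first resolved by zero-length left-grouping.
    """
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    work = tree.copy() if tree.is_binary else resolve_polytomies(tree)
    if not work.has_branch_lengths:
        raise ValueError("tree has missing branch lengths")

    nodes, parent, is_tip, x = _pl_pack(work)
    n = len(nodes)
    height = work.max_depth()
    eps = 1e-8 * height if height > 0 else 1e-8
    x = np.where(np.nan_to_num(x) <= 0, np.where(np.isnan(x), np.nan, eps), x)

    edge_idx = np.where(parent >= 0)[0]  # nodes that subtend an edge
    free_idx = np.where((parent >= 0) & (~is_tip))[0]  # internal non-root
    root_children = np.where(parent == 0)[0]
    # edges whose parent edge exists (parent node is not the root)
    smooth_idx = edge_idx[parent[edge_idx] != 0]

    n_free = len(free_idx)
    n_edge = len(edge_idx)
    edge_pos = {j: p for p, j in enumerate(edge_idx)}
    # for each smoothing edge: its own position and its parent edge's position
    sm_self = np.array([edge_pos[j] for j in smooth_idx], dtype=int)
    sm_par = np.array([edge_pos[parent[j]] for j in smooth_idx], dtype=int)
    rc_pos = np.array([edge_pos[j] for j in root_children], dtype=int)
    xe = x[edge_idx]

    preorder_free = [i for i in range(n) if (parent[i] >= 0 and not is_tip[i])]

    def ages_from_theta(theta: np.ndarray) -> np.ndarray:
        ages = np.zeros(n)
        ages[0] = 1.0
        s = 1.0 / (1.0 + np.exp(-theta))
        for p, i in enumerate(preorder_free):
            ages[i] = ages[parent[i]] * s[p]
        return ages

    def objective_and_grad(params: np.ndarray):
        theta = params[:n_free]
        logr = params[n_free:]
        s = 1.0 / (1.0 + np.exp(-theta))
        ages = ages_from_theta(theta)
        r = np.exp(logr)
        t = ages[parent[edge_idx]] - ages[edge_idx]
        t = np.maximum(t, 1e-300)
        # Poisson-type branch log-likelihood
        ll = np.sum(xe * np.log(r * t) - r * t)
        # smoothing penalty
        diff = r[sm_self] - r[sm_par]
        rc = r[rc_pos]
        rc_mean = rc.mean()
        phi = np.sum(diff ** 2) + np.mean((rc - rc_mean) ** 2)
        f = ll - smoothing * phi

        # gradient wrt rates
        g_r = xe / r - t
        np.add.at(g_r, sm_self, -2.0 * smoothing * diff)
        np.add.at(g_r, sm_par, 2.0 * smoothing * diff)
        g_r[rc_pos] -= smoothing * (2.0 / len(rc)) * (rc - rc_mean)
        g_logr = g_r * r

        # gradient wrt ages, then backprop through the logistic chain
        dl_dt = xe / t - r
        g_age = np.zeros(n)
        np.add.at(g_age, parent[edge_idx], dl_dt)
        np.add.at(g_age, edge_idx, -dl_dt)
        g_theta = np.zeros(n_free)
        pos_of = {i: p for p, i in enumerate(preorder_free)}
        for p in range(n_free - 1, -1, -1):
            i = preorder_free[p]
            pi = parent[i]
            # propagate to the parent's age before converting to theta
            g_age[pi] += g_age[i] * s[p]
            g_theta[p] = g_age[i] * ages[pi] * s[p] * (1.0 - s[p])
        _ = pos_of
        grad = np.concatenate([g_theta, g_logr])
        return -f, -grad

    # clock-like initialization: ages proportional to remaining path length
    depth = np.zeros(n)
    for i in range(1, n):
        depth[i] = depth[parent[i]] + x[i]
    max_tip = depth[is_tip].max()
    theta0 = np.zeros(n_free)
    ages0 = np.clip(1.0 - depth / max_tip, 1e-6, 1.0)
    for p, i in enumerate(preorder_free):
        frac = min(ages0[i] / ages0[parent[i]], 1.0 - 1e-9) if ages0[parent[i]] > 0 else 0.5
        frac = min(max(frac, 1e-9), 1.0 - 1e-9)
        theta0[p] = math.log(frac / (1.0 - frac))
    # initial durations under the clock ages, to set a global rate
    ages_init = ages_from_theta(theta0)
    t0 = np.maximum(ages_init[parent[edge_idx]] - ages_init[edge_idx], 1e-9)
    r_global = max(xe.sum() / t0.sum(), 1e-9)
    logr0 = np.full(n_edge, math.log(r_global))

    x0 = np.concatenate([theta0, logr0])
    f_init = -objective_and_grad(x0)[0]
    bounds = [(-15.0, 15.0)] * n_free + [(-25.0, 25.0)] * n_edge

    rng = np.random.default_rng(seed)
    best = None
    best_f = -np.inf
    for attempt in range(max(1, n_restarts)):
        start = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.5, size=x0.size)
        try:
            res = minimize(
                objective_and_grad,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter},
            )
        except (FloatingPointError, np.linalg.LinAlgError):  # pragma: no cover
            continue
        f = -res.fun
        if np.isfinite(f) and f > best_f:
            best_f = f
            best = res.x
    if best is None or not np.isfinite(best_f):
        raise PLOptimizationError("penalized-likelihood optimization failed", best_f)
    if best_f < f_init:
        # never return a solution worse than the initialization
        best, best_f = x0, f_init

    theta = best[:n_free]
    ages = ages_from_theta(theta)
    rates = np.full(n, np.nan)
    rates[edge_idx] = np.exp(best[n_free:])
    for i, node in enumerate(nodes):
        if node.parent is not None:
            node.length = float(ages[parent[i]] - ages[i])
    chron_tree = PhyloTree(work.root)
    assert is_ultrametric(chron_tree, 1e-6)
    return Chronogram(tree=chron_tree, ages=ages, rates=rates, objective=best_f)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


def count_origins_fitch(tree: PhyloTree, states: Mapping[str, int]) -> int:
    """Minimum number of state changes of a binary character over the tree
    (Fitch parsimony length).

    Polytomies are resolved with zero-length left-grouping first, which
    cannot decrease the count.  Returns 0 iff the character is constant.
    """
    missing = [lbl for lbl in tree.tip_labels if lbl not in states]
    if missing:
        raise KeyError(f"tips without states: {missing}")
    work = tree if tree.is_binary else resolve_polytomies(tree)
    changes = 0
    sets: Dict[int, int] = {}  # bitmask: 1 -> {0}, 2 -> {1}
    for node in work.postorder():
        if node.is_tip:
            state = int(states[node.label])
            if state not in (0, 1):
                raise ValueError(f"non-binary state {state!r} for tip {node.label!r}")
            sets[id(node)] = 1 << state
            continue
        acc = None
        for child in node.children:
            cs = sets[id(child)]
            if acc is None:
                acc = cs
            else:
                inter = acc & cs
                if inter:
                    acc = inter
                else:
                    acc |= cs
                    changes += 1
        sets[id(node)] = acc
    return changes
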