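"""Independent reference implementations used as test oracles.

Deliberately naive: each recomputes a quantity by brute force or from its
textbook definition, independently of the library code paths it checks.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Set, Tuple

import numpy as np

from phylotraits.phylo import Node, PhyloTree


def bipartitions(tree: PhyloTree) -> Set[frozenset]:
    """Non-trivial tip bipartitions (as tip-label frozensets of one side)."""
    all_tips = frozenset(tree.tip_labels)
    parts = set()
    for node in tree.preorder():
        if node.parent is None or node.is_tip:
            continue
        side = frozenset(l for l in _tips_below(node))
        if 1 < len(side) < len(all_tips):
            parts.add(min(side, all_tips - side, key=sorted))
    return parts


def _tips_below(node: Node) -> List[str]:
    if node.is_tip:
        return [node.label]
    out = []
    for c in node.children:
        out.extend(_tips_below(c))
    return out


def brute_force_vcv(tree: PhyloTree) -> Tuple[List[str], np.ndarray]:
    """Shared root-to-MRCA path length for every tip pair, via explicit
    root-to-tip paths and their common prefix."""

    def path(node: Node) -> List[Node]:
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return list(reversed(out))

    tips = tree.tips()
    labels = [t.label for t in tips]
    n = len(tips)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            pi, pj = path(tips[i]), path(tips[j])
            shared = 0.0
            for a, b in zip(pi[1:], pj[1:]):  # skip root, walk common prefix
                if a is b:
                    shared += a.length
                else:
                    break
            M[i, j] = shared
    return labels, M


def exhaustive_fitch(tree: PhyloTree, states: Dict[str, int]) -> int:
    """Minimum change count by enumerating all internal 0/1 assignments."""
    internals = [n for n in tree.preorder() if not n.is_tip]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internals)):
        lab = {id(n): s for n, s in zip(internals, assign)}
        for t in tree.tips():
            lab[id(t)] = states[t.label]
        changes = sum(
            1
            for n in tree.preorder()
            if n.parent is not None and lab[id(n)] != lab[id(n.parent)]
        )
        if best is None or changes < best:
            best = changes
    return best


def recursive_d_sum(tree: PhyloTree, states: Dict[str, float]) -> float:
    """Sister-clade difference sum from its recursive definition."""

    def value(node: Node) -> float:
        if node.is_tip:
            return float(states[node.label])
        l, r = node.children
        return 0.5 * (value(l) + value(r))

    total = 0.0
    for node in tree.preorder():
        if not node.is_tip:
            l, r = node.children
            total += abs(value(l) - value(r))
    return total


def ols_fit(y: np.ndarray, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Textbook OLS coefficients and standard errors."""
    n, p = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    e = y - X @ beta
    s2 = float(e @ e) / (n - p)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
    return beta, se


def pic_slope(tree: PhyloTree, x_map: Dict[str, float], y_map: Dict[str, float]) -> float:
    """Phylogenetically independent contrasts, through-origin regression
    slope of y-contrasts on x-contrasts (Felsenstein's algorithm)."""

    contrasts_x: List[float] = []
    contrasts_y: List[float] = []

    def visit(node: Node) -> Tuple[float, float, float]:
        """Returns (x value, y value, additional edge length) at node."""
        if node.is_tip:
            return x_map[node.label], y_map[node.label], node.length or 0.0
        (xl, yl, vl), (xr, yr, vr) = (visit(c) for c in node.children)
        sd = np.sqrt(vl + vr)
        contrasts_x.append((xl - xr) / sd)
        contrasts_y.append((yl - yr) / sd)
        x = (xl / vl + xr / vr) / (1 / vl + 1 / vr)
        y = (yl / vl + yr / vr) / (1 / vl + 1 / vr)
        extra = (node.length or 0.0) + vl * vr / (vl + vr)
        return x, y, extra

    visit(tree.root)
    cx = np.array(contrasts_x)
    cy = np.array(contrasts_y)
    return float((cx @ cy) / (cx @ cx))
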