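"""Monothetic divisive clustering of binary vectors (DIVCLUS-T).

The algorithm grows a binary tree top-down. Every split is monothetic: a
cluster is divided by the value of a single coordinate d into its v_d = 0 and
v_d = 1 sides, so each cluster is described by human-readable inclusion
criteria (blocks every member has) and exclusion criteria (blocks no member
has) -- the conjunction of the split decisions on its root path. At each step
the (cluster, coordinate) pair with the largest reduction of within-cluster
inertia (sum of squared Euclidean distances to the centroid) is split,
greedily, until ``max_leaves`` is reached or nothing is splittable.

For binary data the inertia of n vectors with coordinate means p_d is
n * sum_d p_d (1 - p_d), and all sufficient statistics of every candidate
split of a cluster are contained in its co-occurrence matrix S = X^T X, so the
best split is found with one matrix product per cluster. Reductions are
rational numbers with small integer numerators; candidates that are tied
within floating-point tolerance are re-compared exactly (integer arithmetic
via fractions), and ties are broken by lowest coordinate index, then lowest
cluster id. This makes the tree fully deterministic, including on
symmetric data.

Leaf ids are assigned by depth-first order visiting each split's 0-side
(exclusion) child before its 1-side (inclusion) child. Under this order, for
any two leaves the one with value 0 at their divergence coordinate precedes
the other; since health-state vectors only gain coordinates over time, every
observed transition goes to an equal-or-higher leaf id, and the transition
count matrix is upper triangular by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

logger = logging.getLogger(__name__)

_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class Criteria:
    """Inclusion/exclusion block sets describing one cluster."""

    inclusion: frozenset[int]
    exclusion: frozenset[int]

    def satisfied_by(self, v) -> bool:
        v = np.asarray(v)
        return all(v[d] for d in self.inclusion) and not any(v[d] for d in self.exclusion)


@dataclass
class Node:
    id: int
    depth: int
    n: int
    inertia: float
    inertia_exact: Fraction
    split_var: int | None = None
    reduction: float = 0.0
    child0: int | None = None
    child1: int | None = None
    parent: int | None = None
    leaf_id: int | None = None
    members: np.ndarray | None = None  # build-data row indices (leaves only)

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None


@dataclass
class ClusterTree:
    """Result of a DIVCLUS-T fit: nodes, recorded split order, inertia curve."""

    M: int
    nodes: list[Node]
    split_sequence: list[int] = field(default_factory=list)  # node ids, in order split
    inertia_curve: list[float] = field(default_factory=list)  # I(1) ... I(n_leaves)

    @property
    def root(self) -> Node:
        return self.nodes[0]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_nodes())

    def leaf_nodes(self) -> list[Node]:
        order = order_leaves(self)
        return [self.nodes[i] for i in order]

    def path(self, node_id: int) -> list[tuple[int, int]]:
        """(split variable, side) decisions from the root to ``node_id``."""
        out = []
        node = self.nodes[node_id]
        while node.parent is not None:
            par = self.nodes[node.parent]
            out.append((par.split_var, 1 if par.child1 == node.id else 0))
            node = par
        return out[::-1]

    def criteria(self, leaf_id: int) -> Criteria:
        return leaf_criteria(self, leaf_id)

    def leaf_node_id(self, leaf_id: int) -> int:
        order = order_leaves(self)
        if not 0 <= leaf_id < len(order):
            raise ValueError(f"unknown leaf id {leaf_id}")
        return order[leaf_id]

    # ---- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "split_sequence": list(self.split_sequence),
            "inertia_curve": [float(x) for x in self.inertia_curve],
            "nodes": [
                {
                    "id": nd.id,
                    "depth": nd.depth,
                    "n": int(nd.n),
                    "inertia": float(nd.inertia),
                    "split_var": nd.split_var,
                    "reduction": float(nd.reduction),
                    "child0": nd.child0,
                    "child1": nd.child1,
                    "parent": nd.parent,
                    "leaf_id": nd.leaf_id,
                }
                for nd in self.nodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterTree":
        nodes = [
            Node(
                id=nd["id"],
                depth=nd["depth"],
                n=nd["n"],
                inertia=nd["inertia"],
                inertia_exact=Fraction(nd["inertia"]).limit_denominator(10**12),
                split_var=nd["split_var"],
                reduction=nd["reduction"],
                child0=nd["child0"],
                child1=nd["child1"],
                parent=nd["parent"],
                leaf_id=nd["leaf_id"],
            )
            for nd in d["nodes"]
        ]
        return cls(
            M=d["M"],
            nodes=nodes,
            split_sequence=list(d["split_sequence"]),
            inertia_curve=list(d["inertia_curve"]),
        )


# ---------------------------------------------------------------------------
# Inertia and split search


def _as_matrix(vectors) -> np.ndarray:
    X = np.asarray(vectors)
    if X.ndim != 2:
        X = X.reshape(len(X), -1) if len(X) else X.reshape(0, 0)
    return X.astype(np.float64, copy=False)


def inertia(vectors) -> float:
    """Sum of squared Euclidean distances to the centroid; 0 for empty input.

    For binary data this equals n * sum_d p_d (1 - p_d) with p the coordinate
    means.
    """
    X = _as_matrix(vectors)
    n = X.shape[0]
    if n == 0:
        return 0.0
    s = X.sum(axis=0)
    return float(s.sum() - np.dot(s, s) / n)


def _exact_inertia(n: int, s: np.ndarray) -> Fraction:
    si = [int(round(x)) for x in s]
    return Fraction(n * sum(si) - sum(x * x for x in si), n) if n else Fraction(0)


@dataclass
class _LeafStats:
    n: int
    s: np.ndarray  # column sums (ints in float64)
    S: np.ndarray  # co-occurrence X^T X


def _leaf_stats(X: np.ndarray) -> _LeafStats:
    Xf = X.astype(np.float64, copy=False)
    return _LeafStats(n=X.shape[0], s=Xf.sum(axis=0), S=Xf.T @ Xf)


def _candidate_reductions(st: _LeafStats, min_leaf_size: int) -> np.ndarray:
    """Inertia reduction of splitting on each coordinate; -inf where invalid."""
    n, s, S = st.n, st.s, st.S
    c = np.diag(S)  # count of v_d = 1 per coordinate
    with np.errstate(divide="ignore", invalid="ignore"):
        sum_s1 = S.sum(axis=0)  # per d: sum_j s1_j
        sumsq_s1 = (S * S).sum(axis=0)  # per d: sum_j s1_j^2
        sum_s0 = s.sum() - sum_s1
        sumsq_s0 = np.dot(s, s) - 2.0 * (s @ S) + sumsq_s1
        i_parent = s.sum() - np.dot(s, s) / n
        i1 = sum_s1 - sumsq_s1 / c
        i0 = sum_s0 - sumsq_s0 / (n - c)
        red = i_parent - i0 - i1
    valid = (c >= min_leaf_size) & ((n - c) >= min_leaf_size) & (c > 0) & (c < n)
    red[~valid] = -np.inf
    return red


def _exact_reduction(st: _LeafStats, d: int) -> Fraction:
    n = st.n
    c = int(round(st.S[d, d]))
    s1 = st.S[:, d]
    s0 = st.s - s1
    return (
        _exact_inertia(n, st.s)
        - _exact_inertia(c, s1)
        - _exact_inertia(n - c, s0)
    )


def _best_split_from_stats(
    st: _LeafStats, min_leaf_size: int
) -> tuple[int, float, Fraction] | None:
    red = _candidate_reductions(st, min_leaf_size)
    best = red.max() if len(red) else -np.inf
    if not np.isfinite(best) or best < -_TIE_RTOL:
        return None
    tol = _TIE_RTOL * max(1.0, abs(best))
    tied = np.flatnonzero(red >= best - tol)
    exact = [(_exact_reduction(st, int(d)), int(d)) for d in tied]
    best_frac = max(f for f, _ in exact)
    if best_frac < 0:
        return None
    d_star = min(d for f, d in exact if f == best_frac)
    return d_star, float(best_frac), best_frac


def best_monothetic_split(vectors, min_leaf_size: int = 1) -> tuple[int | None, float]:
    """Coordinate maximizing the inertia reduction, with the reduction.

    Returns (None, 0.0) when no split with two non-empty sides exists. Ties are
    broken by the lowest coordinate index.
    """
    X = _as_matrix(vectors)
    if X.shape[0] == 0:
        raise ValueError("cannot split an empty cluster")
    res = _best_split_from_stats(_leaf_stats(X), min_leaf_size)
    if res is None:
        return None, 0.0
    d, red, _ = res
    return d, red


# ---------------------------------------------------------------------------
# Tree growth


def fit_divclus(
    data, max_leaves: int, min_leaf_size: int = 1
) -> ClusterTree:
    """Grow the divisive tree greedily to at most ``max_leaves`` leaves.

    ``data`` is the pooled set of binary state vectors (rows). The recorded
    ``split_sequence`` and ``inertia_curve`` allow any coarser partition
    (including the macro-cluster cut) to be replayed from the same tree.
    """
    if max_leaves < 1:
        raise ValueError("max_leaves must be >= 1")
    X = np.ascontiguousarray(np.asarray(data), dtype=bool)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("data must be a non-empty 2-D array of binary vectors")
    M = X.shape[1]

    root_stats = _leaf_stats(X)
    root = Node(
        id=0,
        depth=0,
        n=root_stats.n,
        inertia=float(_exact_inertia(root_stats.n, root_stats.s)),
        inertia_exact=_exact_inertia(root_stats.n, root_stats.s),
        members=np.arange(X.shape[0]),
    )
    tree = ClusterTree(M=M, nodes=[root])
    tree.inertia_curve = [root.inertia]

    # candidate best split per current leaf: node id -> (Fraction, var) or None
    candidates: dict[int, tuple[Fraction, int] | None] = {}
    stats: dict[int, _LeafStats] = {0: root_stats}

    def compute_candidate(nid: int) -> None:
        res = _best_split_from_stats(stats[nid], min_leaf_size)
        candidates[nid] = None if res is None else (res[2], res[0])

    compute_candidate(0)

    while len(candidates) < max_leaves:
        # global selection: max reduction, ties by lowest var then lowest leaf id
        best_key = None
        best_nid = None
        for nid in sorted(candidates):
            cand = candidates[nid]
            if cand is None:
                continue
            frac, var = cand
            key = (frac, -var, -nid)
            if frac > 0 and (best_key is None or key > best_key):
                best_key = key
                best_nid = nid
        if best_nid is None:
            break
        frac, var = candidates[best_nid]
        node = tree.nodes[best_nid]
        rows = node.members
        side1 = X[rows, var]
        r0, r1 = rows[~side1], rows[side1]
        kids = []
        for rws in (r0, r1):
            st = _leaf_stats(X[rws])
            kid = Node(
                id=len(tree.nodes),
                depth=node.depth + 1,
                n=len(rws),
                inertia=float(_exact_inertia(st.n, st.s)),
                inertia_exact=_exact_inertia(st.n, st.s),
                parent=node.id,
                members=rws,
            )
            tree.nodes.append(kid)
            stats[kid.id] = st
            kids.append(kid)
        node.split_var = int(var)
        node.reduction = float(frac)
        node.child0, node.child1 = kids[0].id, kids[1].id
        node.members = None
        tree.split_sequence.append(node.id)
        tree.inertia_curve.append(tree.inertia_curve[-1] - float(frac))
        del candidates[best_nid], stats[best_nid]
        compute_candidate(kids[0].id)
        compute_candidate(kids[1].id)

    for leaf_id, nid in enumerate(order_leaves(tree)):
        tree.nodes[nid].leaf_id = leaf_id
    return tree


def order_leaves(tree: ClusterTree) -> list[int]:
    """Node ids of the leaves in DFS order, 0-side child before 1-side child."""
    order: list[int] = []
    stack = [0]
    while stack:
        nid = stack.pop()
        node = tree.nodes[nid]
        if node.is_leaf:
            order.append(nid)
        else:
            stack.append(node.child1)
            stack.append(node.child0)
    return order


def leaf_criteria(tree: ClusterTree, leaf_id: int) -> Criteria:
    """Conjunction of root-to-leaf path constraints for a (DFS-ordered) leaf."""
    nid = tree.leaf_node_id(leaf_id)
    inc, exc = set(), set()
    for var, side in tree.path(nid):
        (inc if side == 1 else exc).add(var)
    return Criteria(inclusion=frozenset(inc), exclusion=frozenset(exc))


def assign_vector(tree: ClusterTree, v) -> int:
    """Leaf id reached by root-to-leaf traversal of one vector."""
    v = np.asarray(v).ravel()
    if v.shape[0] != tree.M:
        raise ValueError(f"vector has dimension {v.shape[0]}, tree expects {tree.M}")
    node = tree.root
    while not node.is_leaf:
        node = tree.nodes[node.child1 if v[node.split_var] else node.child0]
    return node.leaf_id


def assign_matrix(tree: ClusterTree, X) -> np.ndarray:
    """Vectorized :func:`assign_vector` over the rows of ``X``."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != tree.M:
        raise ValueError(f"expected (n, {tree.M}) array, got {X.shape}")
    out = np.empty(X.shape[0], dtype=np.int64)
    stack = [(0, np.arange(X.shape[0]))]
    while stack:
        nid, rows = stack.pop()
        node = tree.nodes[nid]
        if node.is_leaf:
            out[rows] = node.leaf_id
        else:
            side = X[rows, node.split_var].astype(bool)
            stack.append((node.child1, rows[side]))
            stack.append((node.child0, rows[~side]))
    return out


def select_k_elbow(inertia_curve, override: int | None = None) -> int:
    """Elbow choice of the number of clusters from I(1..K_max).

    Picks the interior K maximizing the second difference
    (I(K-1) - I(K)) - (I(K) - I(K+1)); ties go to the smallest K. A flat
    (linear) curve has no distinct elbow and is reported via a warning.
    ``override`` bypasses the heuristic.
    """
    c = [float(x) for x in inertia_curve]
    if override is not None:
        if not 1 <= override <= len(c):
            raise ValueError(f"override {override} outside 1..{len(c)}")
        return int(override)
    if len(c) < 3:
        raise ValueError("inertia curve must have length >= 3 for the elbow rule")
    if any(b > a + 1e-9 for a, b in zip(c, c[1:])):
        raise ValueError("inertia curve must be non-increasing")
    second = [(c[k - 1] - c[k]) - (c[k] - c[k + 1]) for k in range(1, len(c) - 1)]
    best = max(second)
    if best - min(second) <= 1e-12 * max(1.0, abs(best)):
        logger.warning("no distinct elbow: all second differences equal; choosing K=2")
    k_star = 2 + second.index(best)  # K is 1-based; interior K starts at 2
    return k_star


@dataclass
class MacroPartition:
    """A cut of the tree into macro-clusters (replay of the first splits)."""

    n_parts: int
    frontier: list[int]  # node ids in DFS order; macro id = position
    leaf_to_macro: np.ndarray  # leaf id -> macro id
    criteria: list[Criteria]


def cut_tree(tree: ClusterTree, n_parts: int) -> MacroPartition:
    """Partition after the first ``n_parts`` - 1 recorded splits."""
    n_leaves = tree.n_leaves
    if not 1 <= n_parts <= n_leaves:
        raise ValueError(f"n_parts must lie in 1..{n_leaves}")
    frontier = {0}
    for nid in tree.split_sequence[: n_parts - 1]:
        node = tree.nodes[nid]
        frontier.discard(nid)
        frontier.add(node.child0)
        frontier.add(node.child1)

    # DFS order of the frontier, and leaf membership below each frontier node
    order: list[int] = []
    leaf_to_macro = np.empty(n_leaves, dtype=np.int64)
    stack = [0]
    while stack:
        nid = stack.pop()
        node = tree.nodes[nid]
        if nid in frontier:
            macro = len(order)
            order.append(nid)
            sub = [nid]
            while sub:
                mid = sub.pop()
                mnode = tree.nodes[mid]
                if mnode.is_leaf:
                    leaf_to_macro[mnode.leaf_id] = macro
                else:
                    sub.extend([mnode.child0, mnode.child1])
        elif not node.is_leaf:
            stack.append(node.child1)
            stack.append(node.child0)
    crit = []
    for nid in order:
        inc, exc = set(), set()
        for var, side in tree.path(nid):
            (inc if side == 1 else exc).add(var)
        crit.append(Criteria(inclusion=frozenset(inc), exclusion=frozenset(exc)))
    return MacroPartition(
        n_parts=n_parts, frontier=order, leaf_to_macro=leaf_to_macro, criteria=crit
    )


def cut_assignments(tree: ClusterTree, n_parts: int) -> np.ndarray:
    """Map from leaf id to cluster id under the cut at ``n_parts`` clusters.

    Cluster ids follow the DFS order of the cut frontier, so they inherit the
    upper-triangular transition property of the leaf order.
    """
    return cut_tree(tree, n_parts).leaf_to_macro
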