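"""Shared fixtures: block table, hand-built claims, brute-force oracles."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from diseasetraj.blocks import load_default_blocks
from diseasetraj.simulate import CLAIMS_COLUMNS


@pytest.fixture(scope="session")
def table():
    return load_default_blocks()


def make_claims(rows) -> pd.DataFrame:
    """Rows: (patient_id, sex, age_group, region, half_year, codes, discharge)."""
    return pd.DataFrame(list(rows), columns=CLAIMS_COLUMNS)


@pytest.fixture
def claims_factory():
    return make_claims


# ---------------------------------------------------------------------------
# Exact brute-force oracles for the divisive clustering, independent of the
# implementation: plain loops over python lists with Fraction arithmetic.


def oracle_inertia(X) -> Fraction:
    n = len(X)
    if n == 0:
        return Fraction(0)
    M = len(X[0])
    s = [sum(int(row[d]) for row in X) for d in range(M)]
    return Fraction(n * sum(s) - sum(v * v for v in s), n)


def oracle_best_split(X, min_leaf: int = 1):
    """(variable, reduction) maximizing inertia reduction; ties -> lowest var."""
    if not X:
        return None
    total = oracle_inertia(X)
    best = None
    for d in range(len(X[0])):
        side1 = [row for row in X if row[d]]
        side0 = [row for row in X if not row[d]]
        if len(side1) < min_leaf or len(side0) < min_leaf:
            continue
        red = total - oracle_inertia(side0) - oracle_inertia(side1)
        if best is None or red > best[1]:
            best = (d, red)
    return best


def oracle_greedy_sequence(X, max_leaves: int):
    """Greedy divisive splits by exhaustive enumeration.

    Returns [(frozenset of row indices split, variable), ...] in order, using
    the same tie rule as the implementation contract: maximal reduction, then
    lowest variable index, then lowest (creation-order) cluster id. Creation
    ids mirror the implementation: root is 0, each split appends the 0-side
    child then the 1-side child.
    """
    leaves = [(0, list(range(len(X))))]
    next_id = 1
    seq = []
    while len(leaves) < max_leaves:
        best = None
        for cid, rows in leaves:
            cand = oracle_best_split([X[i] for i in rows])
            if cand is None or cand[1] <= 0:
                continue
            d, red = cand
            key = (red, -d, -cid)
            if best is None or key > best[0]:
                best = (key, cid, rows, d)
        if best is None:
            break
        _, cid, rows, d = best
        seq.append((frozenset(rows), d))
        r0 = [i for i in rows if not X[i][d]]
        r1 = [i for i in rows if X[i][d]]
        leaves = [lv for lv in leaves if lv[0] != cid]
        leaves.append((next_id, r0))
        leaves.append((next_id + 1, r1))
        next_id += 2
    return seq


def replay_split_sequence(tree, X):
    """[(frozenset of rows, variable), ...] actually applied by a fitted tree."""
    members = {0: frozenset(range(len(X)))}
    out = []
    for nid in tree.split_sequence:
        node = tree.nodes[nid]
        rows = members[nid]
        out.append((rows, node.split_var))
        r1 = frozenset(i for i in rows if X[i][node.split_var])
        members[node.child0] = rows - r1
        members[node.child1] = r1
    return out


def planted_onehot_groups(k: int, per_group: int, n_noise: int = 4,
                          eps: float = 0.03, seed: int = 0):
    """K pure monothetic groups (one-hot signatures) + noisy extra coordinates.

    Group g is defined by signature coordinate g; within-group noise is
    confined to the extra coordinates so group membership stays monothetic.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), per_group)
    X = np.zeros((k * per_group, k + n_noise), dtype=bool)
    X[np.arange(k * per_group), labels] = True
    X[:, k:] = rng.random((k * per_group, n_noise)) < eps
    return X, labels
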