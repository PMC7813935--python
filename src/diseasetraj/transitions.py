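"""Cluster-transition tensors, matched risk differences, mortality, networks.

A patient of sex s and age group a assigned to cluster k at half-year t and to
cluster j at t+1 contributes one step to N[s, a, k, j] and one occasion of
exposure to E[s, a, k]. The transition rate q[s, a, k, j] = N / E is the
per-half-year probability of stepping from k to j; rows sum to one over all
destinations including j = k wherever exposure is positive. The final observed
half-year of a patient (the death half-year, or the window end) contributes no
exposure, so death is absorbing.

Arm comparisons are elementwise: the risk difference RD = q^case - q^control
(positive where the case cohort progresses faster) and the sex risk difference
SRD = q^male - q^female within the case cohort. Averages over age and/or sex
strata are unweighted means over the strata where the cell is defined in every
constituent arm; exposure-weighted pooling is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .states import StateMatrix
from .util import AGE_GROUPS

SEXES = ("F", "M")

AXES = ("s", "a", "k", "j")


class DataIntegrityError(ValueError):
    pass


@dataclass
class TransitionTensor:
    """Counts N[s, a, k, j], exposures E[s, a, k] and rates q = N / E."""

    n_clusters: int
    N: np.ndarray  # (2, A, K, K) int64
    E: np.ndarray  # (2, A, K) int64
    sexes: tuple[str, ...] = SEXES
    age_groups: tuple[str, ...] = AGE_GROUPS

    def rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(q, defined): q is nan where exposure is zero."""
        E = self.E.astype(np.float64)[..., None]
        with np.errstate(divide="ignore", invalid="ignore"):
            q = self.N / E
        defined = np.broadcast_to(self.E[..., None] > 0, self.N.shape)
        return q, defined

    def pooled(self, over: tuple[str, ...] = ("s", "a")) -> "TransitionTensor":
        """Sum counts and exposures over strata (exposure-weighted pooling)."""
        axes = tuple(i for i, name in enumerate(("s", "a")) if name in over)
        if not axes:
            return self
        N = self.N.sum(axis=axes, keepdims=True)
        E = self.E.sum(axis=axes, keepdims=True)
        return TransitionTensor(
            n_clusters=self.n_clusters, N=N, E=E,
            sexes=self.sexes if "s" not in over else ("all",),
            age_groups=self.age_groups if "a" not in over else ("all",),
        )

    def to_frame(self) -> pd.DataFrame:
        """Sparse long format: one row per cell with at least one step."""
        q, _ = self.rates()
        s, a, k, j = np.nonzero(self.N)
        return pd.DataFrame(
            {
                "sex": [self.sexes[i] for i in s],
                "age_group": [self.age_groups[i] for i in a],
                "source": k,
                "target": j,
                "steps": self.N[s, a, k, j],
                "exposure": self.E[s, a, k],
                "rate": q[s, a, k, j],
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        n_clusters: int,
        sexes: tuple[str, ...] = SEXES,
        age_groups: tuple[str, ...] = AGE_GROUPS,
    ) -> "TransitionTensor":
        sx = {x: i for i, x in enumerate(sexes)}
        ag = {x: i for i, x in enumerate(age_groups)}
        N = np.zeros((len(sexes), len(age_groups), n_clusters, n_clusters), dtype=np.int64)
        E = np.zeros((len(sexes), len(age_groups), n_clusters), dtype=np.int64)
        for row in frame.itertuples(index=False):
            i, a = sx[row.sex], ag[row.age_group]
            N[i, a, row.source, row.target] = row.steps
            E[i, a, row.source] = row.exposure
        return cls(n_clusters=n_clusters, N=N, E=E, sexes=sexes, age_groups=age_groups)


def count_transitions(
    states: StateMatrix, assignments: np.ndarray, n_clusters: int
) -> TransitionTensor:
    """Count half-year cluster steps, stratified by sex and source-time age.

    ``assignments`` gives the cluster of each snapshot of ``states`` (same
    order). Gaps in a patient's snapshot sequence (non-consecutive half-years
    while alive) raise :class:`DataIntegrityError`.
    """
    if len(assignments) != states.n_snapshots:
        raise ValueError("one assignment per snapshot required")
    S, A = len(SEXES), len(AGE_GROUPS)
    N = np.zeros((S, A, n_clusters, n_clusters), dtype=np.int64)
    E = np.zeros((S, A, n_clusters), dtype=np.int64)

    pat = states.snap_patient
    t = states.snap_t
    same = pat[1:] == pat[:-1]
    if np.any(same & (np.diff(t) != 1)):
        bad = int(pat[1:][same & (np.diff(t) != 1)][0])
        raise DataIntegrityError(
            f"patient {states.patient_ids[bad]} has a gap in its half-year sequence"
        )
    src = assignments[:-1][same]
    dst = assignments[1:][same]
    a_idx = states.snap_age[:-1][same]
    sex_per_patient = np.array([SEXES.index(x) for x in states.sex])
    s_idx = sex_per_patient[pat[:-1][same]]
    np.add.at(N, (s_idx, a_idx, src, dst), 1)
    np.add.at(E, (s_idx, a_idx, src), 1)
    return TransitionTensor(n_clusters=n_clusters, N=N, E=E)


@dataclass
class ComparisonResult:
    """Elementwise arm difference with explicit definedness and support."""

    kind: str  # "RD" or "SRD"
    axes: tuple[str, ...]  # e.g. ("s", "a", "k", "j")
    values: np.ndarray  # nan where undefined
    defined: np.ndarray  # bool
    support: np.ndarray  # strata (or arms) contributing to each cell
    sexes: tuple[str, ...] = SEXES
    age_groups: tuple[str, ...] = AGE_GROUPS
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        idx = np.nonzero(self.defined)
        cols = {}
        for name, ix in zip(self.axes, idx):
            if name == "s":
                cols["sex"] = [self.sexes[i] for i in ix]
            elif name == "a":
                cols["age_group"] = [self.age_groups[i] for i in ix]
            elif name == "k":
                cols["source"] = ix
            else:
                cols["target"] = ix
        cols["value"] = self.values[idx]
        cols["support"] = self.support[idx]
        return pd.DataFrame(cols)


def risk_difference(
    q_cohort: TransitionTensor, q_control: TransitionTensor
) -> ComparisonResult:
    """RD = q^case - q^control, defined where both cells are defined."""
    if q_cohort.n_clusters != q_control.n_clusters or q_cohort.N.shape != q_control.N.shape:
        raise ValueError("tensors must share cluster set and strata")
    qa, da = q_cohort.rates()
    qb, db = q_control.rates()
    defined = da & db
    values = np.where(defined, qa - qb, np.nan)
    return ComparisonResult(
        kind="RD",
        axes=AXES,
        values=values,
        defined=defined,
        support=defined.astype(np.int64) * 2,
        sexes=q_cohort.sexes,
        age_groups=q_cohort.age_groups,
    )


def sex_risk_difference(q_cohort: TransitionTensor) -> ComparisonResult:
    """SRD = q^male - q^female within the cohort, per age group."""
    try:
        im, if_ = q_cohort.sexes.index("M"), q_cohort.sexes.index("F")
    except ValueError:
        raise ValueError("both sexes must be present in the cohort tensor") from None
    if q_cohort.E[im].sum() == 0 or q_cohort.E[if_].sum() == 0:
        raise ValueError("a sex is absent from the cohort (zero exposure)")
    q, d = q_cohort.rates()
    defined = d[im] & d[if_]
    values = np.where(defined, q[im] - q[if_], np.nan)
    return ComparisonResult(
        kind="SRD",
        axes=("a", "k", "j"),
        values=values,
        defined=defined,
        support=defined.astype(np.int64) * 2,
        age_groups=q_cohort.age_groups,
    )


def average_strata(obj, over: tuple[str, ...] = ("a",), weights: str = "equal"):
    """Average a tensor's rates or a comparison over sex and/or age strata.

    Unweighted (``weights='equal'``): the mean over strata where the cell is
    defined; cells defined in no stratum stay undefined, the per-cell support
    count records how many strata contributed. Exposure-weighted pooling
    (``weights='exposure'``) is available for :class:`TransitionTensor` only,
    where it amounts to summing counts and exposures.
    """
    if not over:
        raise ValueError("specify at least one stratum axis to average over")
    if isinstance(obj, TransitionTensor):
        if any(o not in ("s", "a") for o in over):
            raise ValueError("tensor strata are 's' and 'a'")
        if weights == "exposure":
            q, d = obj.pooled(over).rates()
            axes = tuple(i for i, n in enumerate(("s", "a")) if n in over)
            return np.squeeze(q, axis=axes), np.squeeze(d, axis=axes)
        q, d = obj.rates()
        axes = tuple(i for i, n in enumerate(("s", "a")) if n in over)
        return _nanmean_over(q, d, axes)
    if isinstance(obj, ComparisonResult):
        if weights != "equal":
            raise ValueError("comparisons support unweighted averaging only")
        axes = tuple(i for i, n in enumerate(obj.axes) if n in over)
        missing = [o for o in over if o not in obj.axes]
        if missing:
            raise ValueError(f"axes {missing} not present in this comparison")
        values, defined = _nanmean_over(obj.values, obj.defined, axes)
        support = obj.defined.sum(axis=axes)
        return ComparisonResult(
            kind=obj.kind,
            axes=tuple(n for n in obj.axes if n not in over),
            values=values,
            defined=defined,
            support=support,
            sexes=obj.sexes,
            age_groups=obj.age_groups,
            meta={**obj.meta, "averaged_over": tuple(over)},
        )
    raise TypeError(f"cannot average object of type {type(obj)!r}")


def _nanmean_over(values, defined, axes) -> tuple[np.ndarray, np.ndarray]:
    cnt = defined.sum(axis=axes)
    with np.errstate(invalid="ignore"):
        total = np.where(defined, values, 0.0).sum(axis=axes)
        mean = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
    return mean, cnt > 0


def cluster_mortality(
    states: StateMatrix, assignments: np.ndarray, n_clusters: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster in-hospital death rate.

    Deaths occurring while assigned to cluster k divided by all
    (patient, half-year) occasions assigned to k. Returns (rates, occasions);
    the rate is nan for clusters with no occasions.
    """
    occasions = np.bincount(assignments, minlength=n_clusters).astype(np.float64)
    is_death = states.death_t[states.snap_patient] == states.snap_t
    deaths = np.bincount(assignments[is_death], minlength=n_clusters).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(occasions > 0, deaths / np.maximum(occasions, 1.0), np.nan)
    return rates, occasions.astype(np.int64)


@dataclass
class NodeStats:
    """Per-cluster display statistics for the trajectory network."""

    size: np.ndarray  # distinct patients ever assigned to the cluster
    mortality: np.ndarray
    macro: np.ndarray
    mean_age: np.ndarray  # years


def node_statistics(
    states: StateMatrix,
    assignments: np.ndarray,
    n_clusters: int,
    leaf_to_macro: np.ndarray | None = None,
) -> NodeStats:
    from .util import age_group_midpoint_years

    size = np.zeros(n_clusters, dtype=np.int64)
    pairs = np.unique(np.stack([states.snap_patient, assignments], axis=1), axis=0)
    np.add.at(size, pairs[:, 1], 1)
    mortality, occ = cluster_mortality(states, assignments, n_clusters)
    age_years = np.array([age_group_midpoint_years(i) for i in range(len(AGE_GROUPS))])
    mean_age = np.full(n_clusters, np.nan)
    tot = np.zeros(n_clusters)
    np.add.at(tot, assignments, age_years[states.snap_age])
    mean_age[occ > 0] = tot[occ > 0] / occ[occ > 0]
    macro = (
        np.arange(n_clusters) if leaf_to_macro is None else np.asarray(leaf_to_macro)
    )
    return NodeStats(size=size, mortality=mortality, macro=macro, mean_age=mean_age)


def build_network(
    weights: np.ndarray,
    defined: np.ndarray,
    node_stats: NodeStats,
    threshold: float = 0.007,
    kind: str = "rate",
) -> nx.DiGraph:
    """Directed trajectory network keeping edges with |weight| >= threshold.

    Self-loops are excluded from the rendered network (they remain in the
    tensor); every cluster is kept as a node with its display statistics.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    K = weights.shape[0]
    g = nx.DiGraph(kind=kind, threshold=float(threshold))
    for k in range(K):
        g.add_node(
            int(k),
            size=int(node_stats.size[k]),
            mortality=float(node_stats.mortality[k])
            if np.isfinite(node_stats.mortality[k])
            else None,
            macro=int(node_stats.macro[k]),
            mean_age=float(node_stats.mean_age[k])
            if np.isfinite(node_stats.mean_age[k])
            else None,
        )
    for k in range(K):
        for j in range(K):
            if k == j or not defined[k, j]:
                continue
            w = float(weights[k, j])
            if w != 0.0 and abs(w) >= threshold:
                g.add_edge(int(k), int(j), weight=w, kind=kind)
    return g


def network_to_node_link(g: nx.DiGraph) -> dict:
    """JSON-ready node-link document (nodes: id/macro/size/mortality/mean_age)."""
    return {
        "kind": g.graph.get("kind"),
        "threshold": g.graph.get("threshold"),
        "nodes": [
            {"id": n, **{k: v for k, v in d.items()}} for n, d in sorted(g.nodes(data=True))
        ],
        "links": [
            {"source": u, "target": v, "weight": d["weight"], "kind": d["kind"]}
            for u, v, d in sorted(g.edges(data=True))
        ],
    }
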