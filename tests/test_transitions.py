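"""Transition tensors, risk differences, mortality, trajectory networks."""

import numpy as np
import pytest

from diseasetraj.states import build_state_matrix
from diseasetraj.transitions import (
    ComparisonResult,
    NodeStats,
    TransitionTensor,
    average_strata,
    build_network,
    cluster_mortality,
    count_transitions,
    network_to_node_link,
    risk_difference,
    sex_risk_difference,
)
from diseasetraj.util import AGE_GROUPS, HalfYearInterval

OBS = HalfYearInterval(12, 36)


def row(pid, t, codes, sex="F", age="60-64", region="east", discharge="normal"):
    return (pid, sex, age, region, t, codes, discharge)


def small_states(claims_factory, table, rows, pids):
    return build_state_matrix(claims_factory(rows), pids, table, OBS)


def tensor_from_counts(n, cells, exposures, sexes=("F", "M"), ages=AGE_GROUPS):
    N = np.zeros((len(sexes), len(ages), n, n), dtype=np.int64)
    E = np.zeros((len(sexes), len(ages), n), dtype=np.int64)
    for (s, a, k, j), v in cells.items():
        N[s, a, k, j] = v
    for (s, a, k), v in exposures.items():
        E[s, a, k] = v
    return TransitionTensor(n_clusters=n, N=N, E=E, sexes=sexes, age_groups=ages)


class TestCounting:
    def test_three_halfyears_two_occasions(self, claims_factory, table):
        # clusters (k, k, j): stays in 0, then gains a block at t=14
        sm = small_states(
            claims_factory, table, [row("p1", 12, ""), row("p1", 14, "I21")], ["p1"]
        )
        # cluster by presence of the I20-I25 block: simple 2-state assignment
        d = table.map_code("I21")
        assignments = sm.vectors[:, d].astype(np.int64)
        tensor = count_transitions(sm, assignments, 2)
        a = AGE_GROUPS.index("60-64")
        s = 0  # F
        assert tensor.E[s, a, 0] == 2
        assert tensor.N[s, a, 0, 0] == 1
        assert tensor.N[s, a, 0, 1] == 1
        q, defined = tensor.rates()
        assert q[s, a, 0, 1] == pytest.approx(0.5)

    def test_single_transition_rate_one(self, claims_factory, table):
        sm = small_states(
            claims_factory, table,
            [row("p1", 34, ""), row("p1", 35, "I21")], ["p1"],
        )
        d = table.map_code("I21")
        sub = sm.vectors[:, d].astype(np.int64)
        # restrict to the last two observed half-years by construction of claims:
        # snapshots cover 12..35; all transitions are 0->0 except the last
        tensor = count_transitions(sm, sub, 2)
        q, defined = tensor.rates()
        a = AGE_GROUPS.index("60-64")
        assert tensor.N[0, a, 0, 1] == 1
        assert q[0, a, 0, 1] == pytest.approx(1 / 23)

    def test_death_halfyear_contributes_no_exposure(self, claims_factory, table):
        sm = small_states(
            claims_factory, table,
            [row("p1", 12, ""), row("p1", 14, "N18", discharge="death")], ["p1"],
        )
        d = table.map_code("N18")
        tensor = count_transitions(sm, sm.vectors[:, d].astype(np.int64), 2)
        # snapshots at 12, 13, 14(death): occasions 12->13 and 13->14 only
        assert tensor.E.sum() == 2
        assert tensor.N[:, :, 0, 1].sum() == 1  # the step into the death half-year

    def test_row_normalization(self, claims_factory, table):
        rows = [row("p1", 12, ""), row("p1", 15, "I21"), row("p1", 20, "N18"),
                row("p2", 13, "A02", sex="M"), row("p2", 22, "J44", sex="M")]
        sm = small_states(claims_factory, table, rows, ["p1", "p2"])
        assignments = sm.vectors.sum(axis=1).astype(np.int64)  # block count as cluster
        tensor = count_transitions(sm, assignments, 3)
        q, defined = tensor.rates()
        sums = q.sum(axis=-1)[tensor.E > 0]
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_gap_in_sequence_rejected(self, claims_factory, table):
        sm = small_states(claims_factory, table, [row("p1", 12, "")], ["p1"])
        sm.snap_t[5] += 1  # corrupt: introduce a gap
        from diseasetraj.transitions import DataIntegrityError

        with pytest.raises(DataIntegrityError, match="gap"):
            count_transitions(sm, np.zeros(sm.n_snapshots, dtype=np.int64), 1)


class TestRiskDifference:
    def test_reported_rates_example(self):
        # one cell: case rate 0.016 vs control rate 0.0084 -> RD 0.0076
        a = AGE_GROUPS.index("75-79")
        tc = tensor_from_counts(11, {(1, a, 7, 10): 16}, {(1, a, 7): 1000})
        tk = tensor_from_counts(11, {(1, a, 7, 10): 21}, {(1, a, 7): 2500})
        rd = risk_difference(tc, tk)
        assert rd.values[1, a, 7, 10] == pytest.approx(0.016 - 0.0084)

    def test_identical_tensors_zero(self):
        t = tensor_from_counts(3, {(0, 0, 0, 1): 5}, {(0, 0, 0): 50})
        rd = risk_difference(t, t)
        assert np.all(rd.values[rd.defined] == 0.0)

    def test_antisymmetry(self):
        t1 = tensor_from_counts(3, {(0, 0, 0, 1): 5}, {(0, 0, 0): 50})
        t2 = tensor_from_counts(3, {(0, 0, 0, 1): 9}, {(0, 0, 0): 60})
        rd12 = risk_difference(t1, t2)
        rd21 = risk_difference(t2, t1)
        np.testing.assert_array_equal(rd12.defined, rd21.defined)
        np.testing.assert_allclose(
            rd12.values[rd12.defined], -rd21.values[rd21.defined]
        )

    def test_undefined_cells_propagate(self):
        t1 = tensor_from_counts(2, {(0, 0, 0, 1): 5}, {(0, 0, 0): 50})
        t2 = tensor_from_counts(2, {}, {})  # no exposure anywhere
        rd = risk_difference(t1, t2)
        assert not rd.defined.any()
        assert np.isnan(rd.values).all()

    def test_mismatched_clusters_rejected(self):
        t1 = tensor_from_counts(2, {}, {})
        t2 = tensor_from_counts(3, {}, {})
        with pytest.raises(ValueError, match="share"):
            risk_difference(t1, t2)


class TestSexRiskDifference:
    def test_single_stratum_difference(self):
        t = tensor_from_counts(
            2,
            {(1, 3, 0, 1): 30, (0, 3, 0, 1): 10},
            {(1, 3, 0): 100, (0, 3, 0): 100},
        )
        srd = sex_risk_difference(t)
        assert srd.values[3, 0, 1] == pytest.approx(0.3 - 0.1)

    def test_absent_sex_rejected(self):
        t = tensor_from_counts(2, {(0, 0, 0, 1): 5}, {(0, 0, 0): 50})
        with pytest.raises(ValueError, match="absent"):
            sex_risk_difference(t)


class TestAveraging:
    def test_single_stratum_identity(self):
        t = tensor_from_counts(2, {(0, 2, 0, 1): 5}, {(0, 2, 0): 50})
        rd = risk_difference(t, t)
        avg = average_strata(rd, over=("s", "a"))
        assert avg.values[0, 1] == pytest.approx(0.0)
        assert avg.support[0, 1] == 1

    def test_arithmetic_mean_two_age_groups(self):
        cells = {(0, 0, 0, 1): 20, (0, 1, 0, 1): 40}
        t = tensor_from_counts(2, cells, {(0, 0, 0): 100, (0, 1, 0): 100})
        q_mean, defined = average_strata(t, over=("s", "a"))
        assert q_mean[0, 1] == pytest.approx(0.3)  # mean of 0.2 and 0.4

    def test_partial_definition_support_count(self):
        # defined in 3 of 5 age strata
        cells = {(0, a, 0, 1): 10 for a in range(3)}
        expo = {(0, a, 0): 100 for a in range(3)}
        t = tensor_from_counts(2, cells, expo)
        rd = risk_difference(t, t)
        avg = average_strata(rd, over=("a",))
        assert avg.support[0, 0, 1] == 3
        assert avg.values[0, 0, 1] == pytest.approx(0.0)
        assert not avg.defined[1, 0, 1]  # other sex never defined

    def test_exposure_weighted_pooling(self):
        cells = {(0, 0, 0, 1): 20, (0, 1, 0, 1): 40}
        t = tensor_from_counts(2, cells, {(0, 0, 0): 100, (0, 1, 0): 300})
        q_pool, _ = average_strata(t, over=("s", "a"), weights="exposure")
        assert q_pool[0, 1] == pytest.approx(60 / 400)

    def test_empty_axis_rejected(self):
        t = tensor_from_counts(2, {}, {})
        with pytest.raises(ValueError):
            average_strata(t, over=())


class TestMortality:
    def test_two_deaths_in_ten_occasions(self, claims_factory, table):
        rows = []
        for i in range(5):
            rows.append(row(f"p{i}", 12, "I21"))
        # two of the five die in their second observed half-year
        rows.append(row("p0", 13, "", discharge="death"))
        rows.append(row("p1", 13, "", discharge="death"))
        sm = build_state_matrix(
            claims_factory(rows), [f"p{i}" for i in range(5)], table, HalfYearInterval(12, 14)
        )
        assignments = np.zeros(sm.n_snapshots, dtype=np.int64)
        rates, occ = cluster_mortality(sm, assignments, 1)
        assert occ[0] == 10
        assert rates[0] == pytest.approx(0.2)

    def test_no_deaths_zero_rates(self, claims_factory, table):
        sm = build_state_matrix(
            claims_factory([row("p1", 12, "I21")]), ["p1"], table, OBS
        )
        rates, occ = cluster_mortality(sm, np.zeros(sm.n_snapshots, dtype=np.int64), 2)
        assert rates[0] == 0.0
        assert np.isnan(rates[1])  # empty cluster undefined


def default_stats(n):
    return NodeStats(
        size=np.ones(n, dtype=np.int64),
        mortality=np.zeros(n),
        macro=np.zeros(n, dtype=np.int64),
        mean_age=np.full(n, 60.0),
    )


class TestNetwork:
    def test_threshold_filtering_retains_0074_drops_0069(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.0074
        w[0, 2] = 0.0069
        g = build_network(w, np.ones_like(w, dtype=bool), default_stats(3), threshold=0.007)
        assert g.has_edge(0, 1)
        assert not g.has_edge(0, 2)

    def test_zero_threshold_keeps_all_nonzero(self):
        w = np.array([[0.0, 0.001], [0.0, 0.0]])
        g = build_network(w, np.ones_like(w, dtype=bool), default_stats(2), threshold=0.0)
        assert g.number_of_edges() == 1

    def test_high_threshold_empty_edges_nodes_intact(self):
        w = np.full((4, 4), 0.5)
        g = build_network(w, np.ones_like(w, dtype=bool), default_stats(4), threshold=0.9)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 4

    def test_self_loops_excluded(self):
        w = np.array([[0.9, 0.5], [0.0, 0.9]])
        g = build_network(w, np.ones_like(w, dtype=bool), default_stats(2), threshold=0.0)
        assert not g.has_edge(0, 0)
        assert g.has_edge(0, 1)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_network(np.zeros((1, 1)), np.ones((1, 1), dtype=bool), default_stats(1), threshold=-0.1)

    def test_node_link_export_schema(self):
        w = np.zeros((2, 2))
        w[0, 1] = 0.01
        g = build_network(w, np.ones_like(w, dtype=bool), default_stats(2), threshold=0.0, kind="RD")
        doc = network_to_node_link(g)
        assert {n["id"] for n in doc["nodes"]} == {0, 1}
        assert doc["links"] == [
            {"source": 0, "target": 1, "weight": 0.01, "kind": "RD"}
        ]
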