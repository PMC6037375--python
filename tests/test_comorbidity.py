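"""comorbidity network: counting oracle, RR identity, partition, comparison."""

import numpy as np
import pandas as pd
import pytest

from agedense import (
    ClusterAssignment,
    Cohort,
    build_network,
    compare_rr_distributions,
    cooccurrence_counts,
    partition_edges,
    relative_risk,
    top_edges,
)
from agedense.comorbidity import ComorbidityNetwork
from agedense.records import DataError

from conftest import cooccurrence_oracle, make_cohort, random_cohort


class TestCooccurrence:
    def test_set_semantics(self):
        c = make_cohort([("p1", 30, "male", "J06"), ("p1", 30, "male", "M54"),
                         ("p1", 30, "male", "M54")])
        assert cooccurrence_counts(c) == {("J06", "M54"): 1}

    def test_disjoint_patient_sets_give_no_pair(self):
        c = make_cohort([("p1", 1, "male", "J06"), ("p2", 2, "female", "M54")])
        assert cooccurrence_counts(c) == {}

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        codes = ["A09", "I10", "J06", "M54", "N39"]
        for _ in range(20):
            cohort = random_cohort(rng, int(rng.integers(2, 30)), codes)
            assert cooccurrence_counts(cohort) == cooccurrence_oracle(cohort)

    def test_eligible_filter(self):
        c = make_cohort([("p1", 1, "male", "J06"), ("p1", 1, "male", "M54"),
                         ("p1", 1, "male", "A09")])
        got = cooccurrence_counts(c, eligible={"J06", "M54"})
        assert got == {("J06", "M54"): 1}


class TestRelativeRisk:
    def test_zero_cooccurrence(self):
        assert relative_risk(0, 100, 10, 10) == 0.0

    def test_independence_point(self):
        assert relative_risk(1, 100, 10, 10) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert relative_risk(10, 1000, 50, 40) == pytest.approx(5.0)

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            relative_risk(1, 100, 0, 10)
        with pytest.raises(DataError):
            relative_risk(11, 100, 10, 10)

    def test_rr_constructed_cohort(self):
        """RR from a cohort engineered to have N=1000, P_i=50, P_j=40, C=10."""
        rows = []
        for p in range(1000):
            rows.append((f"p{p}", 30, "male", "Z00"))  # everyone is in the data
            if p < 10:
                rows.extend([(f"p{p}", 30, "male", "J06"), (f"p{p}", 30, "male", "M54")])
            elif p < 50:
                rows.append((f"p{p}", 30, "male", "J06"))
            elif p < 80:
                rows.append((f"p{p}", 30, "male", "M54"))
        net = build_network(make_cohort(rows))
        edge = net.edges.set_index(["code_i", "code_j"]).loc[("J06", "M54")]
        assert edge["C"] == 10
        assert edge["RR"] == pytest.approx(5.0, abs=1e-12)


class TestBuildNetwork:
    def test_single_code(self):
        net = build_network(make_cohort([("p1", 1, "male", "J06")]))
        assert net.nodes == {"J06": 1} and net.n_edges == 0

    def test_invariants_on_random_cohort(self):
        rng = np.random.default_rng(13)
        cohort = random_cohort(rng, 40, ["A09", "I10", "J06", "M54"])
        net = build_network(cohort)
        for r in net.edges.itertuples(index=False):
            assert 0 < r.C <= min(net.nodes[r.code_i], net.nodes[r.code_j])
            assert r.code_i < r.code_j
            recovered = r.RR * net.nodes[r.code_i] * net.nodes[r.code_j] / net.N
            assert recovered == pytest.approx(r.C, abs=1e-9)

    def test_visit_multiplicity_invariance(self):
        rng = np.random.default_rng(14)
        cohort = random_cohort(rng, 20, ["A09", "J06", "M54"])
        doubled = Cohort(pd.concat([cohort.records, cohort.records], ignore_index=True))
        a, b = build_network(cohort), build_network(doubled)
        assert a.nodes == b.nodes and a.N == b.N
        assert a.edges.equals(b.edges)

    def test_min_prevalence_filter(self):
        c = make_cohort([("p1", 1, "male", "J06"), ("p2", 2, "male", "J06"),
                         ("p1", 1, "male", "M54")])
        net = build_network(c, min_prevalence=2)
        assert set(net.nodes) == {"J06"}

    def test_independence_mean_rr_near_one(self):
        """Codes assigned independently at fixed rates: mean RR over
        supported edges sits at 1."""
        rng = np.random.default_rng(15)
        n = 20_000
        pid = np.array([f"p{i}" for i in range(n)])
        frames = [pd.DataFrame({"patient_id": pid, "age": 30, "sex": "male",
                                "code": "Z00"})]
        for i, rate in enumerate(np.linspace(0.02, 0.06, 12)):
            idx = np.flatnonzero(rng.random(n) < rate)
            frames.append(pd.DataFrame({"patient_id": pid[idx], "age": 30,
                                        "sex": "male", "code": f"J{i:02d}"}))
        net = build_network(Cohort(pd.concat(frames, ignore_index=True)))
        e = net.edges[(net.edges.C >= 5) & (net.edges.code_i != "Z00")
                      & (net.edges.code_j != "Z00")]
        assert abs(e["RR"].mean() - 1.0) < 0.05


class TestTopEdges:
    def _network(self, rr_c_pairs):
        edges = pd.DataFrame(
            {
                "code_i": [f"A{i:02d}" for i in range(len(rr_c_pairs))],
                "code_j": [f"B{i:02d}" for i in range(len(rr_c_pairs))],
                "C": [c for _, c in rr_c_pairs],
                "RR": [r for r, _ in rr_c_pairs],
            }
        )
        nodes = {c: 10 for c in pd.concat([edges.code_i, edges.code_j])}
        return ComorbidityNetwork(nodes, 100, edges)

    def test_identity_when_m_large(self):
        net = self._network([(5, 1), (3, 2)])
        assert top_edges(net, 10).edges.equals(
            net.edges.sort_values(["RR", "C"], ascending=False).reset_index(drop=True))

    def test_single_max(self):
        net = self._network([(5, 1), (3, 2), (1, 9)])
        top = top_edges(net, 1)
        assert top.n_edges == 1 and top.edges.loc[0, "RR"] == 5

    def test_tie_broken_by_larger_c(self):
        net = self._network([(5, 1), (3, 2), (3, 7), (1, 9)])
        top = top_edges(net, 2)
        assert list(top.edges["RR"]) == [5, 3]
        assert top.edges.loc[1, "C"] == 7

    def test_incident_nodes_kept(self):
        net = self._network([(5, 1), (3, 2)])
        top = top_edges(net, 1)
        assert set(top.nodes) == {"A00", "B00"}


class TestPartitionAndCompare:
    def _toy(self):
        edges = pd.DataFrame(
            {
                "code_i": ["A01", "A01", "A02", "B01", "B01"],
                "code_j": ["A02", "B01", "B02", "B02", "C01"],
                "C": [3, 1, 2, 4, 1],
                "RR": [4.0, 0.5, 3.0, 2.5, 0.7],
            }
        )
        nodes = dict.fromkeys(["A01", "A02", "B01", "B02", "C01"], 10)
        return ComorbidityNetwork(nodes, 100, edges)

    def test_k1_all_intra(self):
        net = self._toy()
        asg = ClusterAssignment(dict.fromkeys(net.nodes, 1), 1)
        intra, inter = partition_edges(net, asg)
        assert len(intra) == 5 and len(inter) == 0

    def test_singletons_all_inter(self):
        net = self._toy()
        asg = ClusterAssignment({c: i + 1 for i, c in enumerate(sorted(net.nodes))}, 5)
        intra, inter = partition_edges(net, asg)
        assert len(intra) == 0 and len(inter) == 5

    def test_hand_labeled_partition(self):
        net = self._toy()
        asg = ClusterAssignment(
            {"A01": 1, "A02": 1, "B01": 2, "B02": 2, "C01": 3}, 3
        )
        intra, inter = partition_edges(net, asg)
        assert sorted(zip(intra.code_i, intra.code_j)) == [("A01", "A02"), ("B01", "B02")]
        assert len(inter) == 3

    def test_unlabeled_nodes_dropped(self):
        net = self._toy()
        asg = ClusterAssignment({"A01": 1, "A02": 1, "B01": 2, "B02": 2}, 2)
        intra, inter = partition_edges(net, asg)
        assert len(intra) + len(inter) == 4  # C01 edge dropped

    def test_identical_samples_zero_divergence(self):
        vals = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        cmp = compare_rr_distributions(vals, vals.copy())
        assert cmp.ks_statistic == 0.0
        assert cmp.js_divergence == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_full_separation(self):
        cmp = compare_rr_distributions(np.array([10.0, 20.0, 30.0]),
                                       np.array([0.1, 0.2, 0.3]))
        assert cmp.ks_statistic == 1.0
        assert cmp.js_divergence > 0.9

    def test_empty_side_rejected(self):
        with pytest.raises(DataError):
            compare_rr_distributions(np.array([]), np.array([1.0]))
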