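"""Signed adjacency, topological overlap (against a triple-loop oracle),
module detection, and the connectivity statistic."""

import numpy as np
import pandas as pd
import pytest

from lncons.coexpression import (
    UNASSIGNED,
    AdjacencyMatrix,
    ModulePartition,
    NetworkConfig,
    compare_connectivity,
    detect_modules,
    module_connectivity,
    signed_adjacency,
    topological_overlap,
)


def tom_triple_loop(a):
    """Independent oracle: literal evaluation of the TOM formula."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def adjacency_of(values):
    values = np.asarray(values, dtype=float)
    return AdjacencyMatrix(node_ids=[f"n{i}" for i in range(len(values))],
                           values=values)


class TestSignedAdjacency:
    def test_perfect_correlation_fixed_point(self):
        x = np.arange(10.0)
        df = pd.DataFrame([x, 2 * x + 1], index=["a", "b"])
        adj = signed_adjacency(df, NetworkConfig(beta=7))
        assert adj.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelation_suppressed(self):
        x = np.arange(10.0)
        df = pd.DataFrame([x, -x], index=["a", "b"])
        adj = signed_adjacency(df, NetworkConfig(beta=7))
        assert adj.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_value(self):
        # cor = 0 with beta 12: ((1+0)/2)^12 = 1/4096
        x = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        y = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        df = pd.DataFrame([x, y], index=["a", "b"])
        adj = signed_adjacency(df, NetworkConfig(beta=12))
        assert adj.values[0, 1] == pytest.approx(0.5**12)

    def test_constant_features_dropped(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "b", "c"])
        df.loc["b"] = 5.0
        adj = signed_adjacency(df, NetworkConfig(beta=2))
        assert adj.node_ids == ["a", "c"]

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(beta=0)


class TestTOM:
    def test_clique_of_ones(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = topological_overlap(adjacency_of(a))
        off = tom.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_two_nodes_tom_equals_adjacency(self):
        a = np.array([[0.0, 0.5], [0.5, 0.0]])
        tom = topological_overlap(adjacency_of(a))
        assert tom.values[0, 1] == pytest.approx(0.5)

    def test_zero_adjacency_zero_tom(self):
        tom = topological_overlap(adjacency_of(np.zeros((4, 4))))
        assert np.allclose(tom.values[~np.eye(4, dtype=bool)], 0.0)

    def test_two_node_limit_on_random_weights(self, rng):
        for _ in range(20):
            w = float(rng.uniform(0, 1))
            a = np.array([[0.0, w], [w, 0.0]])
            tom = topological_overlap(adjacency_of(a))
            assert tom.values[0, 1] == pytest.approx(w, abs=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(25):
            raw = rng.uniform(0, 1, size=(6, 6))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = topological_overlap(adjacency_of(a))
            assert np.allclose(tom.values, tom_triple_loop(a), atol=1e-12)

    def test_symmetry_and_range(self, rng):
        raw = rng.uniform(0, 1, size=(12, 12))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(adjacency_of(a)).values
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1


class TestDetectModules:
    def test_too_few_nodes_all_unassigned(self, rng):
        raw = rng.uniform(0, 1, size=(10, 10))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0)
        tom = topological_overlap(adjacency_of(a))
        part = detect_modules(tom, NetworkConfig(beta=6, min_module_size=30))
        assert all(v == UNASSIGNED for v in part.assignment.values())

    def test_duplicated_rows_cocluster(self):
        block = np.full((4, 4), 0.9)
        tom = np.kron(np.eye(2), block)
        tom[tom == 0] = 0.05
        np.fill_diagonal(tom, 1.0)
        df = pd.DataFrame(tom, index=[f"n{i}" for i in range(8)],
                          columns=[f"n{i}" for i in range(8)])
        part = detect_modules(df, NetworkConfig(beta=6, min_module_size=4,
                                                cut_height=0.5))
        labels = part.assignment
        assert labels["n0"] == labels["n1"] == labels["n2"] == labels["n3"]
        assert labels["n4"] == labels["n7"]
        assert labels["n0"] != labels["n4"]

    def test_labels_deterministic_by_size(self):
        # larger block must be M1
        sizes = [6, 4]
        n = sum(sizes)
        tom = np.full((n, n), 0.02)
        tom[:6, :6] = 0.9
        tom[6:, 6:] = 0.9
        np.fill_diagonal(tom, 1.0)
        df = pd.DataFrame(tom, index=[f"n{i}" for i in range(n)],
                          columns=[f"n{i}" for i in range(n)])
        part = detect_modules(df, NetworkConfig(beta=6, min_module_size=3,
                                                cut_height=0.5))
        assert part.assignment["n0"] == "M1"
        assert part.assignment["n6"] == "M2"


class TestConnectivity:
    def cfg(self):
        return NetworkConfig(beta=6, tom_edge_cutoff=0.2)

    def frame_for(self, tom, assignment, types=None):
        df = pd.DataFrame(tom, index=list(assignment),
                          columns=list(assignment))
        part = ModulePartition(dict(assignment))
        return module_connectivity(df, part, self.cfg(), types or {})

    def test_symmetric_triangle(self):
        tom = np.full((3, 3), 0.3)
        np.fill_diagonal(tom, 1.0)
        table = self.frame_for(tom, {"a": "M1", "b": "M1", "c": "M1"})
        assert list(table.frame["degree"]) == [2, 2, 2]
        assert np.allclose(table.frame["connectivity"], 1 / 3)

    def test_path_topology(self):
        tom = np.array([
            [1.0, 0.3, 0.1],
            [0.3, 1.0, 0.3],
            [0.1, 0.3, 1.0],
        ])
        table = self.frame_for(tom, {"a": "M1", "b": "M1", "c": "M1"})
        assert list(table.frame["degree"]) == [1, 2, 1]
        assert list(table.frame["connectivity"]) == [0.25, 0.5, 0.25]

    def test_isolated_node_zero(self):
        tom = np.array([
            [1.0, 0.3, 0.05],
            [0.3, 1.0, 0.05],
            [0.05, 0.05, 1.0],
        ])
        table = self.frame_for(tom, {"a": "M1", "b": "M1", "c": "M1"})
        assert table.frame.loc[table.frame["node"] == "c",
                               "connectivity"].item() == 0.0

    def test_connectivity_sums_to_one_per_module(self, rng):
        n = 30
        tom = rng.uniform(0, 1, size=(n, n))
        tom = (tom + tom.T) / 2
        np.fill_diagonal(tom, 1.0)
        assignment = {f"n{i}": ("M1" if i < 15 else "M2") for i in range(n)}
        table = self.frame_for(tom, assignment)
        sums = table.frame.groupby("module")["connectivity"].sum()
        for module, s in sums.items():
            if module != UNASSIGNED:
                assert s == pytest.approx(1.0)


class TestCompareConnectivity:
    def make_table(self, lnc, pcg):
        rows = [{"node": f"l{i}", "module": "M1", "degree": 1,
                 "connectivity": v, "node_type": "lncRNA"}
                for i, v in enumerate(lnc)]
        rows += [{"node": f"p{i}", "module": "M1", "degree": 1,
                  "connectivity": v, "node_type": "PCG"}
                 for i, v in enumerate(pcg)]
        from lncons.coexpression import ConnectivityTable
        return ConnectivityTable(frame=pd.DataFrame(rows))

    def test_identical_distributions_near_half(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5] * 4
        _, p, _ = compare_connectivity(self.make_table(vals, list(vals)))
        assert 0.3 < p < 0.7

    def test_separated_distributions(self, rng):
        lnc = 0.9 + 0.001 * rng.normal(size=20)
        pcg = 0.1 + 0.001 * rng.normal(size=20)
        _, p, med = compare_connectivity(self.make_table(lnc, pcg))
        assert p < 1e-6
        assert med["lncRNA"] > med["PCG"]

    def test_missing_type_errors(self):
        with pytest.raises(ValueError):
            compare_connectivity(self.make_table([0.1, 0.2, 0.3], []))
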