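"""Signal propagation: the recursive rule, cycles, bounds and normalization."""

import numpy as np
import pandas as pd
import pytest

from conftest import (
    make_circuit,
    random_cyclic_circuit,
    random_dag_circuit,
    random_node_values,
    recursive_signal,
)
from pathact.graphs import extract_circuits
from pathact.propagation import (
    PropagationConfig,
    compute_activity_matrix,
    node_values,
    normalize_path_activity,
    propagate_circuit,
)


def _vals(mapping):
    return pd.DataFrame({"s0": mapping})


class TestRule:
    def test_single_activation_input(self):
        c = make_circuit([("A", "B", 1)])
        s, _ = propagate_circuit(c, _vals({"A": 0.5, "B": 1.0}))
        assert s[0] == pytest.approx(0.5)  # 1 * (1 - (1 - 0.5))

    def test_mixed_activations_and_inhibition(self):
        c = make_circuit(
            [("A1", "E", 1), ("A2", "E", 1), ("I1", "E", -1)], effector="E"
        )
        s, _ = propagate_circuit(c, _vals({"A1": 0.5, "A2": 0.5, "I1": 0.25, "E": 0.8}))
        assert s[0] == pytest.approx(0.8 * (1 - 0.25) * 0.75)  # = 0.45

    def test_saturating_inhibitor_kills_signal(self):
        c = make_circuit([("A", "B", 1), ("I", "B", -1)], effector="B")
        s, _ = propagate_circuit(c, _vals({"A": 0.9, "I": 1.0, "B": 1.0}))
        assert s[0] == pytest.approx(0.0)

    def test_chain_multiplies_values(self):
        c = make_circuit([("A", "B", 1), ("B", "C", 1)])
        s, _ = propagate_circuit(c, _vals({"A": 0.5, "B": 0.5, "C": 0.5}))
        assert s[0] == pytest.approx(0.125)

    def test_receptor_emits_own_value(self):
        c = make_circuit([], nodes=["X"], effector="X")
        s, _ = propagate_circuit(c, _vals({"X": 0.7}))
        assert s[0] == pytest.approx(0.7)


class TestSolvers:
    def test_jacobi_matches_recursion_on_random_dags(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            c = random_dag_circuit(rng, int(rng.integers(2, 9)))
            nv = random_node_values(rng, c)
            oracle = recursive_signal(c, nv)
            jac, ok = propagate_circuit(c, nv, method="jacobi")
            assert ok
            assert np.allclose(jac, oracle, atol=1e-9)
            topo, _ = propagate_circuit(c, nv, method="topo")
            assert np.allclose(topo, oracle, atol=1e-12)

    def test_bounds_all_nodes_all_samples(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            c = random_cyclic_circuit(rng, int(rng.integers(3, 10)))
            nv = random_node_values(rng, c)
            s, _ = propagate_circuit(c, nv, return_all_nodes=True)
            arr = s.to_numpy()
            assert np.all(arr >= 0) and np.all(arr <= 1)

    def test_activator_monotonicity(self):
        """In an all-activation circuit, raising any node value never lowers
        the effector signal."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            c = random_dag_circuit(rng, int(rng.integers(2, 8)), inhibition_prob=0.0)
            nv = random_node_values(rng, c, n_samples=1)
            base, _ = propagate_circuit(c, nv)
            node = sorted(c.member_nodes)[int(rng.integers(len(c.member_nodes)))]
            bumped = nv.copy()
            bumped.loc[node] = min(1.0, float(nv.loc[node].iloc[0]) + rng.uniform(0, 0.5))
            up, _ = propagate_circuit(c, bumped)
            assert up[0] >= base[0] - 1e-12

    def test_inhibitor_anti_monotonicity(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            c0 = random_dag_circuit(rng, int(rng.integers(2, 7)), inhibition_prob=0.0)
            names = sorted(c0.member_nodes)
            target = names[int(rng.integers(len(names)))]
            edges = [(e.source, e.target, e.sign) for e in c0.member_edges]
            edges.append(("Z", target, -1))
            c = make_circuit(edges, nodes=names + ["Z"], effector=c0.effector)
            nv = random_node_values(rng, c, n_samples=1)
            base, _ = propagate_circuit(c, nv)
            bumped = nv.copy()
            bumped.loc["Z"] = min(1.0, float(nv.loc["Z"].iloc[0]) + rng.uniform(0, 0.5))
            up, _ = propagate_circuit(c, bumped)
            assert up[0] <= base[0] + 1e-12

    def test_cycles_converge_and_flag(self):
        rng = np.random.default_rng(15)
        n_conv = 0
        trials = 200
        for _ in range(trials):
            c = random_cyclic_circuit(rng, int(rng.integers(4, 13)), n_back=3)
            nv = random_node_values(rng, c, n_samples=2)
            _, ok = propagate_circuit(c, nv)
            n_conv += ok
        assert n_conv / trials >= 0.99

    def test_non_convergence_is_flagged_not_silent(self):
        c = make_circuit([("A", "B", 1), ("B", "A", 1), ("B", "C", 1)])
        nv = _vals({"A": 0.9, "B": 0.9, "C": 0.9})
        _, ok = propagate_circuit(c, nv, PropagationConfig(tol=1e-6, max_iter=2))
        assert ok is False


class TestNodeValues:
    def test_mean_summary(self, chain_graph):
        scaled = pd.DataFrame({"s0": {"g1": 0.1, "g2": 0.2, "g3": 0.4, "g4": 0.9}})
        nv = node_values(scaled, chain_graph)
        assert nv.loc["B", "s0"] == pytest.approx(0.3)
        assert nv.loc["A", "s0"] == pytest.approx(0.1)  # single gene: identity
        assert "F" not in nv.index  # function nodes are not propagated

    def test_empty_gene_relay_is_transparent(self):
        c = make_circuit([("A", "M", 1), ("M", "B", 1)])
        nv_in = _vals({"A": 0.5, "M": 1.0, "B": 1.0})
        s, _ = propagate_circuit(c, nv_in)
        assert s[0] == pytest.approx(0.5)

    def test_missing_gene_raises(self, chain_graph):
        scaled = pd.DataFrame({"s0": {"g1": 0.1, "g2": 0.2}})
        with pytest.raises(KeyError, match="g3"):
            node_values(scaled, chain_graph)


class TestLengthNormalization:
    def test_geometric_chain_reaches_one_at_half_values(self):
        c = make_circuit([("A", "B", 1), ("B", "C", 1)])
        raw = np.array([0.125])
        out = normalize_path_activity(raw, c, PropagationConfig(length_norm="geometric"))
        assert out[0] == pytest.approx(1.0)

    def test_none_is_identity(self):
        c = make_circuit([("A", "B", 1)])
        raw = np.array([0.3, 0.6])
        out = normalize_path_activity(raw, c, PropagationConfig(length_norm="none"))
        assert np.array_equal(out, raw)

    @pytest.mark.parametrize("mode", ["geometric", "reference", "none"])
    def test_constant_factor_preserves_ratios(self, mode):
        rng = np.random.default_rng(16)
        c = random_dag_circuit(rng, 6)
        raw = np.array([0.1, 0.2])
        out = normalize_path_activity(raw, c, PropagationConfig(length_norm=mode))
        assert out[1] / out[0] == pytest.approx(2.0)
        assert np.all(out >= 0)

    def test_reference_mode_saturation_gives_one_for_activation_chain(self):
        c = make_circuit([("A", "B", 1), ("B", "C", 1)])
        raw = np.array([1.0])  # signal at v == 1 everywhere
        out = normalize_path_activity(raw, c, PropagationConfig(length_norm="reference"))
        assert out[0] == pytest.approx(1.0)


class TestActivityMatrix:
    def _catalog_and_scaled(self, chain_graph, fill):
        cat = extract_circuits(chain_graph)
        scaled = pd.DataFrame(fill, index=["g1", "g2", "g3", "g4"], columns=["s0", "s1", "s2"])
        return cat, scaled

    def test_shape_contract(self, chain_graph):
        cat, scaled = self._catalog_and_scaled(chain_graph, 0.5)
        act = compute_activity_matrix(cat, scaled)
        assert act.values.shape == (len(cat), 3)
        assert list(act.values.columns) == ["s0", "s1", "s2"]

    def test_saturation_and_extinction(self, chain_graph):
        cat, ones = self._catalog_and_scaled(chain_graph, 1.0)
        act = compute_activity_matrix(cat, ones)
        assert np.allclose(act.raw.to_numpy(), 1.0)
        cat, zeros = self._catalog_and_scaled(chain_graph, 0.0)
        act0 = compute_activity_matrix(cat, zeros)
        assert np.allclose(act0.values.to_numpy(), 0.0)

    def test_length_norm_choice_does_not_move_scale_free_statistics(self, chain_graph):
        """Downstream inference is invariant to the per-circuit constant."""
        from pathact.differential import DesignSpec, differential_table
        from pathact.survival import cox_per_circuit

        rng = np.random.default_rng(17)
        cat = extract_circuits(chain_graph)
        scaled = pd.DataFrame(
            rng.uniform(size=(4, 40)), index=["g1", "g2", "g3", "g4"],
            columns=[f"s{i}" for i in range(40)],
        )
        acts = {
            mode: compute_activity_matrix(cat, scaled, PropagationConfig(length_norm=mode))
            for mode in ("geometric", "none", "reference")
        }
        cond = pd.Series(["case"] * 20 + ["control"] * 20, index=scaled.columns)
        design = DesignSpec(condition=cond, contrast=("case", "control"))
        tstats = {
            mode: differential_table(a.values, design, d0=0)[0].set_index("feature_id")["t_mod"]
            for mode, a in acts.items()
        }
        assert np.allclose(tstats["geometric"], tstats["none"].reindex(tstats["geometric"].index))
        assert np.allclose(tstats["geometric"], tstats["reference"].reindex(tstats["geometric"].index))

        records = pd.DataFrame(
            {"sample_id": scaled.columns,
             "time": rng.exponential(100, size=40).round(2) + 1,
             "event": rng.uniform(size=40) < 0.8}
        )
        cox = {mode: cox_per_circuit(a.values, records, standardize=True) for mode, a in acts.items()}
        assert np.allclose(cox["geometric"]["p"], cox["none"]["p"], rtol=1e-6)
        assert np.allclose(cox["geometric"]["p"], cox["reference"]["p"], rtol=1e-6)
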