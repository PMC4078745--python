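"""Structure learning: worked examples, recovery properties, oracle interchange."""

from itertools import combinations

import numpy as np
import pytest

from dyncausal import fixtures
from dyncausal.exceptions import InferenceError, InvalidArgumentError
from dyncausal.graphs import (
    CausalStructure,
    skeleton,
    unroll,
    v_structures,
)
from dyncausal.inference import (
    GaussianGrangerOracle,
    GraphCIOracle,
    GraphicalGrangerOracle,
    ListCIOracle,
    ic,
    ic_star,
    icg_star,
    temporal_ic,
)
from dyncausal.separation import d_separated
from dyncausal.var_gaussian import ObservationMap, VARModel

from conftest import random_dag, random_process_graph, var_from_process_graph


def pattern_v_structures(p):
    out = set()
    for a, c in p.directed:
        for b, c2 in p.directed:
            if c == c2 and a != b and not p.adjacent(a, b):
                lo, hi = sorted((a, b))
                out.add((lo, c, hi))
    return out


class TestIC:
    def test_single_independence_given_z_yields_undirected_path(self):
        p = ic(ListCIOracle([("X", "Y", {"Z"})]), ["X", "Y", "Z"])
        assert p.directed == frozenset()
        assert p.undirected == frozenset(
            {frozenset(("X", "Z")), frozenset(("Y", "Z"))}
        )

    def test_marginal_independence_yields_collider(self):
        p = ic(ListCIOracle([("X", "Y", ())]), ["X", "Y", "Z"])
        assert p.directed == frozenset({("X", "Z"), ("Y", "Z")})
        assert p.undirected == frozenset()

    def test_all_independent_yields_edgeless(self):
        indeps = [
            (a, b, S)
            for a, b in combinations("XYZ", 2)
            for S in [(), tuple({"X", "Y", "Z"} - {a, b})]
        ]
        p = ic(ListCIOracle(indeps), ["X", "Y", "Z"])
        assert not p.directed and not p.undirected

    def test_inconsistent_oracle_raises(self):
        # A _||_ C and B _||_ D over a 4-cycle demand head-to-head arrowheads
        # on the same edge, which no pattern can represent
        oracle = ListCIOracle([("A", "C", ()), ("B", "D", ())])
        with pytest.raises(InferenceError):
            ic(oracle, ["A", "B", "C", "D"])

    def test_recovers_skeleton_and_v_structures_of_random_dags(self, rng):
        for _ in range(15):
            s = random_dag(rng, int(rng.integers(4, 8)), p=0.4)
            p = ic(GraphCIOracle(s), sorted(s.nodes))
            assert set(map(frozenset, skeleton(p).edges())) == set(
                map(frozenset, skeleton(s).edges())
            )
            assert pattern_v_structures(p) == v_structures(s)

    def test_pattern_reproduces_oracle_independencies(self, rng):
        """Reading the output back: d-separation on the pattern equals
        d-separation on the generating DAG for every query."""
        for _ in range(8):
            s = random_dag(rng, 5, p=0.4)
            p = ic(GraphCIOracle(s), sorted(s.nodes))
            nodes = sorted(s.nodes)
            for a, b in combinations(nodes, 2):
                others = [n for n in nodes if n not in (a, b)]
                for k in range(len(others) + 1):
                    for S in combinations(others, k):
                        assert d_separated(p, a, b, frozenset(S)) == d_separated(
                            s, a, b, frozenset(S)
                        )

    def test_no_directed_cycles_in_output(self, rng):
        for _ in range(10):
            s = random_dag(rng, 6, p=0.5)
            p = ic(GraphCIOracle(s), sorted(s.nodes))
            # Pattern construction itself validates acyclicity of arrows
            assert p.nodes == s.nodes


class TestICStar:
    def test_marginal_independence_yields_potential_causes(self):
        e = ic_star(ListCIOracle([("X", "Y", ())]), ["X", "Y", "Z"])
        assert e.potential == frozenset({("X", "Z"), ("Y", "Z")})
        assert not e.genuine and not e.undirected and not e.bidirectional

    def test_genuine_cause_via_rule_3r1(self):
        e = ic_star(GraphCIOracle(fixtures.genuine_cause_quartet()), ["A", "B", "X", "Y"])
        assert e.potential == frozenset({("A", "X"), ("B", "X")})
        assert e.genuine == frozenset({("X", "Y")})

    def test_all_independent_yields_edgeless(self):
        indeps = [(a, b, ()) for a, b in combinations("XYZ", 2)]
        e = ic_star(ListCIOracle(indeps), ["X", "Y", "Z"])
        assert not (e.undirected | e.potential | e.genuine | e.bidirectional)

    def test_chain_yields_undirected_edges(self):
        e = ic_star(GraphCIOracle(fixtures.three_node_chain()), ["X", "Y", "Z"])
        assert e.undirected == frozenset(
            {frozenset(("X", "Z")), frozenset(("Y", "Z"))}
        )

    def test_embedded_pattern_reproduces_oracle_independencies(self, rng):
        for _ in range(8):
            s = random_dag(rng, 5, p=0.4)
            e = ic_star(GraphCIOracle(s), sorted(s.nodes))
            nodes = sorted(s.nodes)
            for a, b in combinations(nodes, 2):
                others = [n for n in nodes if n not in (a, b)]
                for k in range(len(others) + 1):
                    for S in combinations(others, k):
                        assert d_separated(e, a, b, frozenset(S)) == d_separated(
                            s, a, b, frozenset(S)
                        )


class TestTemporalIC:
    def test_recovers_unidirectional_system(self):
        g = fixtures.unidirectional_processes()
        window = 4
        truth = unroll(g, window)
        rec = temporal_ic(GraphCIOracle(truth), sorted(g.nodes), 1, window)
        assert rec == truth

    def test_edgeless_ground_truth(self):
        truth = CausalStructure(
            nodes=frozenset({("X", t) for t in range(3)} | {("Y", t) for t in range(3)}),
            edges=frozenset(),
        )
        rec = temporal_ic(GraphCIOracle(truth), ["X", "Y"], 1, 3)
        assert not rec.edges

    def test_exact_recovery_of_random_process_graphs(self, rng):
        for _ in range(6):
            g = random_process_graph(rng, n_proc=3, max_lag=2, p=0.3)
            window = 5
            truth = unroll(g, window)
            rec = temporal_ic(GraphCIOracle(truth), sorted(g.nodes), 2, window)
            assert rec == truth

    def test_latent_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            temporal_ic(ListCIOracle([]), ["X", "Y"], 1, 3, latent=("Y",))


def gaussian_system(name):
    """Stable VAR + observation map realising each worked-example topology."""
    if name == "bidirectional_pair_graph":
        m = VARModel(np.array([[0.5, 0.4], [0.4, 0.5]]), names=("X", "Y"))
        return m, None, ["X", "Y"]
    if name == "common_driver_pair":
        C = np.diag([0.5, 0.5, 0.5]).astype(float)
        C[0, 1] = C[2, 1] = 0.5
        m = VARModel(C, names=("X", "a", "Y"))
        return m, ObservationMap.selecting(m, ("X", "Y")), ["X", "Y"]
    if name == "latent_mediator":
        C = np.diag([0.5, 0.5, 0.5]).astype(float)
        C[1, 0] = C[2, 1] = 0.5
        m = VARModel(C, names=("X", "a", "Y"))
        return m, ObservationMap.selecting(m, ("X", "Y")), ["X", "Y"]
    if name == "observed_chain":
        C = np.diag([0.5, 0.5, 0.5]).astype(float)
        C[1, 0] = C[2, 1] = 0.5
        m = VARModel(C, names=("X", "Z", "Y"))
        return m, None, ["X", "Y", "Z"]
    raise KeyError(name)


EXPECTED_MACRO = {
    "bidirectional_pair_graph": ({("X", "Y"), ("Y", "X")}, set()),
    "common_driver_pair": (set(), {frozenset(("X", "Y"))}),
    "latent_mediator": ({("X", "Y")}, set()),
    "observed_chain": ({("X", "Z"), ("Z", "Y")}, set()),
}


class TestICGStar:
    @pytest.mark.parametrize("name", sorted(EXPECTED_MACRO))
    def test_worked_examples_graphical_oracle(self, name):
        g = fixtures.GRAPH_FIXTURES[name]()
        result = icg_star(GraphicalGrangerOracle(g), sorted(g.observed))
        directed, bidi = EXPECTED_MACRO[name]
        assert set(result.directed) == directed
        assert set(result.bidirectional) == bidi

    @pytest.mark.parametrize("name", sorted(EXPECTED_MACRO))
    def test_worked_examples_gaussian_oracle_matches(self, name):
        model, obs, procs = gaussian_system(name)
        result = icg_star(GaussianGrangerOracle(model, obs), procs)
        directed, bidi = EXPECTED_MACRO[name]
        assert set(result.directed) == directed
        assert set(result.bidirectional) == bidi

    def test_oracle_interchangeability_on_random_latent_free_systems(self, rng):
        for _ in range(6):
            names = ("P0", "P1", "P2")
            edges = {(nm, nm, 1) for nm in names}
            for a in names:
                for b in names:
                    if a != b and rng.random() < 0.4:
                        edges.add((a, b, 1))
            from dyncausal.graphs import ProcessGraph

            g = ProcessGraph(nodes=frozenset(names), edges=frozenset(edges))
            model = var_from_process_graph(rng, g)
            from_graph = icg_star(GraphicalGrangerOracle(g), sorted(names))
            from_model = icg_star(GaussianGrangerOracle(model), sorted(names))
            assert from_graph == from_model

    def test_no_directed_edge_on_bidirectional_pair(self, rng):
        for _ in range(5):
            g = random_process_graph(rng, n_proc=3, max_lag=1, p=0.4)
            # make one process latent (it is autocausal by construction)
            latent = sorted(g.nodes)[0]
            g = type(g)(nodes=g.nodes, edges=g.edges, latent=frozenset({latent}))
            result = icg_star(GraphicalGrangerOracle(g), sorted(g.observed))
            for a, b in result.directed:
                assert frozenset((a, b)) not in result.bidirectional
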