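"""Named worked-example systems used throughout the documentation and tests.

Graph fixtures encode the classic three-node equivalence-class examples
(chain, fork, collider), the four-node genuine-cause configuration, and the
dynamic-process ground truths: a bidirectionally coupled pair, a pair driven
by a latent common driver, a latent mediator, a unidirectional pair and its
subordinate-signal variant.  Model fixtures provide the two spatial-
aggregation VAR systems with their printed default parameters.

Figure-style static shapes are reconstructed from their verbal descriptions
(chain/fork variants over {X, Z, Y}; a collider for the distinguishable
case).
"""

from __future__ import annotations

from .experiments import (
    TwoAreaConfig,
    IntegratedAreasConfig,
    build_two_area,
    build_integrated_areas,
    subordinate_process_graph,
    unidirectional_process_graph,
)
from .exceptions import InvalidArgumentError
from .graphs import CausalStructure, ProcessGraph


def _dag(nodes, edges) -> CausalStructure:
    return CausalStructure(nodes=frozenset(nodes), edges=frozenset(edges))


def _pg(nodes, edges, latent=()) -> ProcessGraph:
    return ProcessGraph(
        nodes=frozenset(nodes), edges=frozenset(edges), latent=frozenset(latent)
    )


def three_node_chain() -> CausalStructure:
    """X → Z → Y: one of three observationally equivalent structures."""
    return _dag("XZY", {("X", "Z"), ("Z", "Y")})


def three_node_chain_reversed() -> CausalStructure:
    """X ← Z ← Y: equivalent to the chain."""
    return _dag("XZY", {("Y", "Z"), ("Z", "X")})


def three_node_fork() -> CausalStructure:
    """X ← Z → Y: equivalent to the chains."""
    return _dag("XZY", {("Z", "X"), ("Z", "Y")})


def three_node_collider() -> CausalStructure:
    """X → Z ← Y: distinguishable (X and Y are d-separated by the empty set)."""
    return _dag("XZY", {("X", "Z"), ("Y", "Z")})


def genuine_cause_quartet() -> CausalStructure:
    """A → X ← B with X → Y: rule 3R1 infers the genuine cause X → Y."""
    return _dag("ABXY", {("A", "X"), ("B", "X"), ("X", "Y")})


def bidirectional_pair_graph() -> ProcessGraph:
    """Two processes coupled in both directions, no latents."""
    return _pg(
        "XY",
        {("X", "X", 1), ("Y", "Y", 1), ("X", "Y", 1), ("Y", "X", 1)},
    )


def common_driver_pair() -> ProcessGraph:
    """X and Y driven by a latent autocausal process α, no direct coupling."""
    return _pg(
        {"X", "Y", "a"},
        {("X", "X", 1), ("Y", "Y", 1), ("a", "a", 1), ("a", "X", 1), ("a", "Y", 1)},
        latent={"a"},
    )


def latent_mediator() -> ProcessGraph:
    """X → α → Y with α latent and autocausal: an indirect genuine cause."""
    return _pg(
        {"X", "Y", "a"},
        {("X", "X", 1), ("Y", "Y", 1), ("a", "a", 1), ("X", "a", 1), ("a", "Y", 1)},
        latent={"a"},
    )


def observed_chain() -> ProcessGraph:
    """X → Z → Y with everything observed (conditioning on Z separates)."""
    return _pg(
        {"X", "Y", "Z"},
        {("X", "X", 1), ("Y", "Y", 1), ("Z", "Z", 1), ("X", "Z", 1), ("Z", "Y", 1)},
    )


def unidirectional_processes() -> ProcessGraph:
    """Unidirectional causal connections from process Y to process X."""
    return unidirectional_process_graph()


def subordinate_observation() -> ProcessGraph:
    """The unidirectional pair observed through subordinate signals X*, Y*."""
    return subordinate_process_graph()


def two_area_system(cfg: TwoAreaConfig | None = None):
    """Two-area spatial-aggregation VAR with its weighted-sum observation."""
    return build_two_area(cfg or TwoAreaConfig())


def integrated_areas_system(cfg: IntegratedAreasConfig | None = None):
    """N-processes-per-area VAR with per-area-average observation."""
    return build_integrated_areas(cfg or IntegratedAreasConfig())


GRAPH_FIXTURES = {
    "three_node_chain": three_node_chain,
    "three_node_chain_reversed": three_node_chain_reversed,
    "three_node_fork": three_node_fork,
    "three_node_collider": three_node_collider,
    "genuine_cause_quartet": genuine_cause_quartet,
    "bidirectional_pair_graph": bidirectional_pair_graph,
    "common_driver_pair": common_driver_pair,
    "latent_mediator": latent_mediator,
    "observed_chain": observed_chain,
    "unidirectional_processes": unidirectional_processes,
    "subordinate_observation": subordinate_observation,
}

MODEL_FIXTURES = {
    "two_area_system": two_area_system,
    "integrated_areas_system": integrated_areas_system,
}


def get_graph(name: str):
    try:
        return GRAPH_FIXTURES[name]()
    except KeyError:
        raise InvalidArgumentError(
            f"unknown graph fixture {name!r}; known: {sorted(GRAPH_FIXTURES)}"
        ) from None
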