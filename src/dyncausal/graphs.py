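"""Graph flavors used in causal analysis of dynamic processes.

A dynamic system is described at three scales.  The *process graph* is the
macroscopic ground truth: one node per process, directed edges carrying an
integer lag (>= 1), and a subset of processes flagged latent.  Unrolling the
process graph over a finite time window produces the *causal structure*, the
microscopic DAG over (process, time-index) variables that mirrors the parent
sets of the functional model.  Structure-learning algorithms output partial
representations of equivalence classes: *patterns* (directed + undirected
edges), *embedded patterns* (undirected / potential / genuine / bidirectional
edges) and *mixed macroscopic graphs* (directed Granger arrows and
bidirectional latent-common-driver arrows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import networkx as nx

from .exceptions import InvalidArgumentError

#: A microscopic node: (process identifier, 0-based time index).
TimedNode = tuple[str, int]


def _node_key(n):
    """Deterministic total order over heterogeneous node labels."""
    return repr(n)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProcessGraph:
    """Macroscopic ground-truth description of a set of dynamic processes.

    Edges are (source, target, lag) with lag >= 1: the ground truth contains
    no instantaneous arrows; same-time dependence between observed signals can
    only arise downstream, from latent drivers or aggregation.  Self-edges
    (autocausal links) are expected for dynamic processes.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str, int]]
    latent: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        object.__setattr__(self, "latent", frozenset(self.latent))
        for src, dst, lag in self.edges:
            if src not in self.nodes or dst not in self.nodes:
                raise InvalidArgumentError(f"edge ({src},{dst}) uses unknown node")
            if not (isinstance(lag, int) and lag >= 1):
                raise InvalidArgumentError(
                    f"edge ({src},{dst}) has lag {lag!r}; ground-truth lags must be integers >= 1"
                )
        if not self.latent <= self.nodes:
            raise InvalidArgumentError("latent flags must refer to existing nodes")

    @property
    def observed(self) -> frozenset[str]:
        return self.nodes - self.latent

    @property
    def max_lag(self) -> int:
        return max((lag for _, _, lag in self.edges), default=0)


@dataclass(frozen=True)
class CausalStructure:
    """Time-unrolled DAG over (process, time-index) nodes.

    This is the microscopic representation: every edge points forward in time
    when produced by :func:`unroll`, and the graph is acyclic by construction.
    """

    nodes: frozenset
    edges: frozenset[tuple]

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise InvalidArgumentError(f"edge ({a},{b}) uses unknown node")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise InvalidArgumentError("causal structure must be acyclic")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node) -> set:
        return {a for a, b in self.edges if b == node}


@dataclass(frozen=True)
class Pattern:
    """Partial DAG returned by the IC algorithm.

    Directed edges are orientations shared by every member of the equivalence
    class; undirected edges are left to be completed (subject to creating no
    new v-structure and no directed cycle).
    """

    nodes: frozenset
    directed: frozenset[tuple]
    undirected: frozenset[frozenset]

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "directed", frozenset(self.directed))
        object.__setattr__(
            self, "undirected", frozenset(frozenset(e) for e in self.undirected)
        )
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidArgumentError("pattern has a directed cycle")

    def adjacent(self, a, b) -> bool:
        return (a, b) in self.directed or (b, a) in self.directed or frozenset(
            (a, b)
        ) in self.undirected


#: Edge types of an embedded pattern, ordered from least to most specific.
#: Undirected edges subsume potential causes, which subsume genuine causes
#: and common drivers.
EMBEDDED_EDGE_TYPES = ("undirected", "potential", "genuine", "bidirectional")


@dataclass(frozen=True)
class EmbeddedPattern:
    """Hybrid acyclic graph returned by the IC* algorithm.

    ``potential`` edges (dashed arrows a ⇢ b) stand for either a causal link
    a → b or a latent common driver a ← α → b; ``genuine`` edges (solid
    arrows) are certain causal connections; ``bidirectional`` edges are
    certain latent common drivers.
    """

    nodes: frozenset
    undirected: frozenset[frozenset] = field(default_factory=frozenset)
    potential: frozenset[tuple] = field(default_factory=frozenset)
    genuine: frozenset[tuple] = field(default_factory=frozenset)
    bidirectional: frozenset[frozenset] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(
            self, "undirected", frozenset(frozenset(e) for e in self.undirected)
        )
        object.__setattr__(self, "potential", frozenset(self.potential))
        object.__setattr__(self, "genuine", frozenset(self.genuine))
        object.__setattr__(
            self, "bidirectional", frozenset(frozenset(e) for e in self.bidirectional)
        )
        # no directed cycle through single-headed arrows
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.potential)
        g.add_edges_from(self.genuine)
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidArgumentError("embedded pattern has a hybrid directed cycle")

    def edge_type(self, a, b) -> str | None:
        pair = frozenset((a, b))
        if pair in self.undirected:
            return "undirected"
        if (a, b) in self.potential or (b, a) in self.potential:
            return "potential"
        if (a, b) in self.genuine or (b, a) in self.genuine:
            return "genuine"
        if pair in self.bidirectional:
            return "bidirectional"
        return None


@dataclass(frozen=True)
class MixedMacroGraph:
    """Macroscopic mixed graph: the output alphabet of the ICG* algorithm.

    Directed edges mark Granger causation; bidirectional edges mark pairs
    whose instantaneous dependence cannot be removed by conditioning on any
    observed set, i.e. pairs driven by at least one latent common driver.
    ``instantaneous`` is an optional undirected-dotted annotation used in
    summaries of raw Granger analyses (not produced by ICG*).
    """

    nodes: frozenset[str]
    directed: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    bidirectional: frozenset[frozenset] = field(default_factory=frozenset)
    instantaneous: frozenset[frozenset] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "directed", frozenset(self.directed))
        object.__setattr__(
            self, "bidirectional", frozenset(frozenset(e) for e in self.bidirectional)
        )
        object.__setattr__(
            self, "instantaneous", frozenset(frozenset(e) for e in self.instantaneous)
        )
        for a, b in self.directed:
            if frozenset((a, b)) in self.bidirectional:
                raise InvalidArgumentError(
                    f"pair ({a},{b}) carries both a directed and a bidirectional edge"
                )


GraphLike = Union[CausalStructure, Pattern, EmbeddedPattern, MixedMacroGraph]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def unroll(g: ProcessGraph, window: int) -> CausalStructure:
    """Unroll a process graph into its microscopic causal structure.

    Nodes are (process, t) for t in [0, window); a process edge (a, b, lag)
    yields microscopic edges (a, t) → (b, t + lag) for every t with
    t + lag < window.
    """
    if window < g.max_lag + 1 or window < 1:
        raise InvalidArgumentError(
            f"window {window} too small: need at least max lag + 1 = {g.max_lag + 1}"
        )
    nodes = {(p, t) for p in g.nodes for t in range(window)}
    edges = {
        ((src, t), (dst, t + lag))
        for src, dst, lag in g.edges
        for t in range(window - lag)
    }
    return CausalStructure(nodes=frozenset(nodes), edges=frozenset(edges))


def skeleton(s: CausalStructure | Pattern | EmbeddedPattern | MixedMacroGraph) -> nx.Graph:
    """Undirected adjacency structure: the links without their orientations."""
    g = nx.Graph()
    g.add_nodes_from(s.nodes)
    if isinstance(s, CausalStructure):
        g.add_edges_from(s.edges)
    elif isinstance(s, Pattern):
        g.add_edges_from(s.directed)
        g.add_edges_from(tuple(e) for e in s.undirected)
    elif isinstance(s, EmbeddedPattern):
        g.add_edges_from(s.potential)
        g.add_edges_from(s.genuine)
        g.add_edges_from(tuple(e) for e in s.undirected)
        g.add_edges_from(tuple(e) for e in s.bidirectional)
    elif isinstance(s, MixedMacroGraph):
        g.add_edges_from(s.directed)
        g.add_edges_from(tuple(e) for e in s.bidirectional)
        g.add_edges_from(tuple(e) for e in s.instantaneous)
    else:
        raise InvalidArgumentError(f"unsupported graph type {type(s).__name__}")
    return g


def v_structures(s: CausalStructure) -> set[tuple]:
    """All v-structures a → c ← b with a, b non-adjacent.

    Each triple is reported once, canonically ordered as
    (min(a, b), c, max(a, b)).
    """
    skel = skeleton(s)
    out = set()
    for c in s.nodes:
        parents = sorted(s.parents(c), key=_node_key)
        for i, a in enumerate(parents):
            for b in parents[i + 1 :]:
                if not skel.has_edge(a, b):
                    lo, hi = sorted((a, b), key=_node_key)
                    out.add((lo, c, hi))
    return out


def observationally_equivalent(s1: CausalStructure, s2: CausalStructure) -> bool:
    """Same skeleton and same v-structures: identical readable independencies."""
    if s1.nodes != s2.nodes:
        raise InvalidArgumentError("structures must share their node set")
    if set(map(frozenset, skeleton(s1).edges())) != set(
        map(frozenset, skeleton(s2).edges())
    ):
        return False
    return v_structures(s1) == v_structures(s2)


def ancestors(s: CausalStructure, targets: Iterable) -> set:
    """Closure of ``targets`` under the parent relation (targets included).

    A node is an ancestor of a target if a directed path from it reaches the
    target by following arrows forward (equivalently, walking backwards from
    the target).
    """
    targets = set(targets)
    unknown = targets - set(s.nodes)
    if unknown:
        raise InvalidArgumentError(f"unknown nodes: {sorted(unknown, key=_node_key)}")
    g = s.to_networkx()
    out = set(targets)
    for t in targets:
        out |= nx.ancestors(g, t)
    return out
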