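"""Reading conditional independencies off graphs.

The central operation is d-separation, extended to every graph flavor used in
the package: on hybrid graphs (patterns, embedded patterns, mixed macroscopic
graphs) a collider on a path is any node receiving head-to-head arrowheads of
*any* of the edge types present, and undirected or dashed tails never
contribute an arrowhead.

Two interchangeable engines are provided: a memoized reachability traversal
(linear in the graph size, used by default) and an explicit path enumerator
(exponential, kept as the reference semantics for small instances).  A third
routine implements the classical graph-pruning procedure (restrict to
ancestors, cut the arrows leaving the conditioning set, test connectivity),
which is convenient for reading Granger-causality relations off unrolled
structures by hand.
"""

from __future__ import annotations

from collections import deque
from typing import Hashable, Iterable

import networkx as nx

from .exceptions import InvalidArgumentError
from .graphs import (
    CausalStructure,
    EmbeddedPattern,
    GraphLike,
    MixedMacroGraph,
    Pattern,
    ancestors,
)

# A hybrid edge: (u, v, head_at_u, head_at_v).
_HybridEdge = tuple[Hashable, Hashable, bool, bool]


def hybrid_edges(g: GraphLike) -> list[_HybridEdge]:
    """Flatten any graph flavor into a list of edges with endpoint-arrowhead flags."""
    if isinstance(g, CausalStructure):
        return [(a, b, False, True) for a, b in g.edges]
    if isinstance(g, Pattern):
        out = [(a, b, False, True) for a, b in g.directed]
        out += [(*sorted(e, key=repr), False, False) for e in g.undirected]
        return out
    if isinstance(g, EmbeddedPattern):
        out = [(a, b, False, True) for a, b in g.potential]
        out += [(a, b, False, True) for a, b in g.genuine]
        out += [(*sorted(e, key=repr), False, False) for e in g.undirected]
        out += [(*sorted(e, key=repr), True, True) for e in g.bidirectional]
        return out
    if isinstance(g, MixedMacroGraph):
        out = [(a, b, False, True) for a, b in g.directed]
        out += [(*sorted(e, key=repr), True, True) for e in g.bidirectional]
        out += [(*sorted(e, key=repr), False, False) for e in g.instantaneous]
        return out
    raise InvalidArgumentError(f"unsupported graph type {type(g).__name__}")


def _incidence(edges: list[_HybridEdge]) -> dict:
    """Per-node list of (other endpoint, head at this node, head at other)."""
    inc: dict = {}
    for u, v, hu, hv in edges:
        inc.setdefault(u, []).append((v, hu, hv))
        inc.setdefault(v, []).append((u, hv, hu))
    return inc


def _ancestral_closure(edges: list[_HybridEdge], seeds: set) -> set:
    """Seeds plus every node with a directed path into the seeds.

    Only single-headed edges (tail at one end, head at the other) confer
    ancestry; bidirectional and undirected edges do not.
    """
    parent_of: dict = {}
    for u, v, hu, hv in edges:
        if hv and not hu:
            parent_of.setdefault(v, set()).add(u)
        elif hu and not hv:
            parent_of.setdefault(u, set()).add(v)
    out = set(seeds)
    frontier = deque(seeds)
    while frontier:
        w = frontier.popleft()
        for p in parent_of.get(w, ()):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def _as_node_set(g: GraphLike, x) -> frozenset:
    """Interpret ``x`` as a node of ``g`` or as an iterable of nodes."""
    if x in g.nodes:
        return frozenset((x,))
    try:
        xs = frozenset(x)
    except TypeError:
        raise InvalidArgumentError(f"{x!r} is not a node of the graph") from None
    unknown = xs - set(g.nodes)
    if unknown:
        raise InvalidArgumentError(f"unknown nodes: {sorted(unknown, key=repr)}")
    return xs


def _check_query(g: GraphLike, a, b, S):
    A, B = _as_node_set(g, a), _as_node_set(g, b)
    Sset = frozenset() if not S else _as_node_set(g, S)
    if A & B:
        raise InvalidArgumentError("endpoint sets must be disjoint")
    if (A | B) & Sset:
        raise InvalidArgumentError("conditioning set overlaps an endpoint")
    return A, B, Sset


def d_separated(g: GraphLike, a, b, S=()) -> bool:
    """True iff every path between ``a`` and ``b`` is blocked given ``S``.

    A path is blocked if it contains a non-collider in ``S``, or a collider
    that is neither in ``S`` nor an ancestor of a node in ``S``.  Endpoints
    may be single nodes or node sets.  Uses a memoized head-state reachability
    traversal equivalent to explicit path enumeration.
    """
    A, B, Sset = _check_query(g, a, b, S)
    edges = hybrid_edges(g)
    inc = _incidence(edges)
    anc_S = _ancestral_closure(edges, set(Sset))

    # State (node, arrived-with-arrowhead-at-node); B reached => d-connected.
    seen = set()
    queue = deque()
    for src in A:
        for other, _head_here, head_other in inc.get(src, ()):
            st = (other, head_other)
            if st not in seen:
                seen.add(st)
                queue.append(st)
    while queue:
        w, in_head = queue.popleft()
        if w in B:
            return False
        for other, head_w, head_other in inc.get(w, ()):
            collider = in_head and head_w
            passable = (w in anc_S) if collider else (w not in Sset)
            if passable:
                st = (other, head_other)
                if st not in seen:
                    seen.add(st)
                    queue.append(st)
    return True


def d_separated_paths(g: GraphLike, a, b, S=()) -> bool:
    """Reference d-separation by explicit enumeration of all simple paths.

    Exponential in the graph size; intended as the small-instance oracle
    against which the traversal engine is validated.
    """
    A, B, Sset = _check_query(g, a, b, S)
    edges = hybrid_edges(g)
    inc = _incidence(edges)
    anc_S = _ancestral_closure(edges, set(Sset))

    def path_active(heads_at: list, nodes: list) -> bool:
        # nodes: n0..nk; heads_at[i] = (head at entry into n_{i+1}?, ...)
        for i in range(1, len(nodes) - 1):
            w = nodes[i]
            in_head = heads_at[i - 1][1]
            out_head = heads_at[i][0]
            collider = in_head and out_head
            if collider:
                if w not in anc_S:
                    return False
            else:
                if w in Sset:
                    return False
        return True

    def dfs(node, nodes, heads) -> bool:
        for other, head_here, head_other in inc.get(node, ()):
            if other in nodes:
                continue
            new_nodes = nodes + [other]
            new_heads = heads + [(head_here, head_other)]
            if other in B:
                if path_active(new_heads, new_nodes):
                    return True
                continue
            if dfs(other, new_nodes, new_heads):
                return True
        return False

    for src in A:
        if dfs(src, [src], []):
            return False
    return True


def d_separated_pruned(s: CausalStructure, a, b, S=()) -> bool:
    """d-separation via the three-step graph-pruning procedure (DAGs only).

    (1) restrict the graph to the ancestors of a, b and S; (2) delete every
    arrow coming out of a node in S; (3) report whether a and b are
    disconnected in what remains, ignoring edge directions.
    """
    if not isinstance(s, CausalStructure):
        raise InvalidArgumentError("pruning procedure is defined for DAGs only")
    A, B, Sset = _check_query(s, a, b, S)
    anc = ancestors(s, A | B | Sset)
    g = nx.Graph()
    g.add_nodes_from(anc)
    for u, v in s.edges:
        if u in anc and v in anc and u not in Sset:
            g.add_edge(u, v)
    for src in A:
        reach = nx.node_connected_component(g, src)
        if reach & B:
            return False
    return True


def _macro_restricted_separated(
    m: MixedMacroGraph, X, Y, S, need_head_at_x: bool, need_head_at_y: bool
) -> bool:
    """Blocked-ness of every path whose end edges carry the required arrowheads."""
    A, B, Sset = _check_query(m, X, Y, S)
    edges = hybrid_edges(m)
    inc = _incidence(edges)
    anc_S = _ancestral_closure(edges, set(Sset))

    def path_active(nodes, heads) -> bool:
        if need_head_at_x and not heads[0][0]:
            return False
        if need_head_at_y and not heads[-1][1]:
            return False
        for i in range(1, len(nodes) - 1):
            w = nodes[i]
            collider = heads[i - 1][1] and heads[i][0]
            if collider:
                if w not in anc_S:
                    return False
            else:
                if w in Sset:
                    return False
        return True

    def dfs(node, nodes, heads) -> bool:
        for other, head_here, head_other in inc.get(node, ()):
            if other in nodes:
                continue
            new_nodes, new_heads = nodes + [other], heads + [(head_here, head_other)]
            if other in B:
                if path_active(new_nodes, new_heads):
                    return True
                continue
            if dfs(other, new_nodes, new_heads):
                return True
        return False

    return not any(dfs(src, [src], []) for src in A)


def granger_noncausal_graphical(m: MixedMacroGraph, X, Y, S=()) -> bool:
    """Graphical sufficient condition for Granger non-causality.

    True iff X is d-separated from Y by S on every path between them ending
    with an arrowhead at Y.  True implies T_{X→Y|S} = 0 in every compatible
    model; under stability/faithfulness the condition is also necessary.
    """
    return _macro_restricted_separated(m, X, Y, S, need_head_at_x=False, need_head_at_y=True)


def instantaneous_noncausal_graphical(m: MixedMacroGraph, X, Y, S=()) -> bool:
    """Graphical sufficient condition for instantaneous non-causality.

    As :func:`granger_noncausal_graphical`, but restricted to paths carrying
    an arrowhead at X *and* an arrowhead at Y.  True implies T_{X·Y|S} = 0.
    """
    return _macro_restricted_separated(m, X, Y, S, need_head_at_x=True, need_head_at_y=True)
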