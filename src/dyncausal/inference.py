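"""Structure-learning algorithms driven by pluggable independence oracles.

Four algorithms are provided, in increasing specialisation to dynamic
processes:

* :func:`ic` — inductive causation without latent variables; output is a
  pattern (partial DAG) representing the observational equivalence class.
* :func:`ic_star` — inductive causation allowing latent variables; output is
  an embedded pattern over undirected / potential / genuine / bidirectional
  edges.
* :func:`temporal_ic` — the IC algorithm specialised to latent-free dynamic
  processes: temporal precedence orients every edge, so the output is the
  complete microscopic DAG, unique within its equivalence class.
* :func:`icg_star` — inductive causation with latent processes using Granger
  causality: conditional-independence queries between single variables are
  replaced by transfer-entropy and instantaneous-causality queries between
  whole processes, and the output is a macroscopic mixed graph in which
  bidirectional edges mark latent common drivers.

Oracles answer the independence queries.  Graphical oracles read d-separation
off a known ground-truth structure; the Gaussian oracle computes the analytic
measures of :mod:`dyncausal.var_gaussian`.  The two are interchangeable on
faithful models.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Protocol, Sequence

import networkx as nx

from .exceptions import InferenceError, InvalidArgumentError
from .graphs import (
    CausalStructure,
    EmbeddedPattern,
    GraphLike,
    MixedMacroGraph,
    Pattern,
    ProcessGraph,
    unroll,
)
from .separation import d_separated
from .var_gaussian import (
    DEFAULT_LAG_DEPTH,
    NUMERICAL_ZERO,
    ObservationMap,
    VARModel,
    instantaneous_causality,
    transfer_entropy,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


class CIOracle(Protocol):
    """Conditional-independence oracle over variables (symmetric in a, b)."""

    def independent(self, a, b, S: frozenset) -> bool: ...


class GraphCIOracle:
    """Answers CI queries by d-separation on a known structure.

    ``observed`` restricts the variables the algorithms may condition on;
    latent nodes stay in the graph and keep transmitting dependence.
    """

    def __init__(self, structure: GraphLike, observed: Iterable | None = None):
        self.structure = structure
        self.observed = frozenset(observed) if observed is not None else frozenset(
            structure.nodes
        )
        self._cache: dict = {}

    def independent(self, a, b, S: frozenset) -> bool:
        key = (frozenset((a, b)), frozenset(S))
        if key not in self._cache:
            self._cache[key] = d_separated(self.structure, a, b, frozenset(S))
            logger.debug(
                "CI query %r _||_ %r | %r -> %s", a, b, sorted(S, key=repr),
                "independent" if self._cache[key] else "dependent",
            )
        return self._cache[key]


class ListCIOracle:
    """Oracle defined by an explicit list of conditional independencies.

    ``independencies`` is an iterable of (a, b, S) triples; the oracle is
    symmetric in a and b and reports dependence for every unlisted query.
    """

    def __init__(self, independencies: Iterable[tuple]):
        self._set = {
            (frozenset((a, b)), frozenset(S)) for a, b, S in independencies
        }

    def independent(self, a, b, S: frozenset) -> bool:
        return (frozenset((a, b)), frozenset(S)) in self._set


class ProcessGrangerOracle(Protocol):
    """Granger-level oracle over processes: non-negative te/inst + zero threshold."""

    threshold: float

    def te(self, src: str, dst: str, S: frozenset) -> float: ...

    def inst(self, a: str, b: str, S: frozenset) -> float: ...


class GraphicalGrangerOracle:
    """Granger oracle answering from d-separation on the unrolled ground truth.

    The infinite pasts of the Granger criteria are truncated to a history
    window of H time steps; by default H = 3 · (number of processes) · max
    lag, which exceeds the longest latent-mediated dependence horizon in the
    systems treated here.  Returns 1.0 for "dependent" and 0.0 for
    "independent" — the graphical oracle knows signs, not magnitudes.
    """

    def __init__(self, g: ProcessGraph, history: int | None = None):
        self.graph = g
        self.history = history or max(3 * len(g.nodes) * max(g.max_lag, 1), 3)
        self.structure = unroll(g, self.history + 1)
        self.threshold = 0.5
        self._cache: dict = {}

    def _past(self, procs: Iterable[str]) -> set:
        return {(p, t) for p in procs for t in range(self.history)}

    def te(self, src: str, dst: str, S: frozenset) -> float:
        key = ("te", src, dst, frozenset(S))
        if key not in self._cache:
            sep = d_separated(
                self.structure,
                {(dst, self.history)},
                self._past([src]),
                self._past([dst, *S]),
            )
            self._cache[key] = 0.0 if sep else 1.0
        return self._cache[key]

    def inst(self, a: str, b: str, S: frozenset) -> float:
        key = ("inst", frozenset((a, b)), frozenset(S))
        if key not in self._cache:
            sep = d_separated(
                self.structure,
                {(a, self.history)},
                {(b, self.history)},
                self._past([a, b, *S]),
            )
            self._cache[key] = 0.0 if sep else 1.0
        return self._cache[key]


class GaussianGrangerOracle:
    """Granger oracle computing the analytic Gaussian measures.

    Processes named by the observation map's signal names; answers are exact
    transfer-entropy / instantaneous-causality values in nats at lag depth L.
    """

    def __init__(
        self,
        model: VARModel,
        observation: ObservationMap | None = None,
        L: int = DEFAULT_LAG_DEPTH,
        threshold: float = NUMERICAL_ZERO,
    ):
        self.model = model
        self.observation = observation or ObservationMap.identity(model.names)
        self.L = L
        self.threshold = threshold
        self._cache: dict = {}

    def te(self, src: str, dst: str, S: frozenset) -> float:
        key = ("te", src, dst, frozenset(S))
        if key not in self._cache:
            self._cache[key] = transfer_entropy(
                self.model, self.observation, src, dst, tuple(sorted(S)), L=self.L
            ).value
            logger.debug("TE %s->%s | %r = %.3e nats", src, dst, sorted(S), self._cache[key])
        return self._cache[key]

    def inst(self, a: str, b: str, S: frozenset) -> float:
        key = ("inst", frozenset((a, b)), frozenset(S))
        if key not in self._cache:
            self._cache[key] = instantaneous_causality(
                self.model, self.observation, a, b, tuple(sorted(S)), L=self.L
            ).value
            logger.debug("T_{%s.%s} | %r = %.3e nats", a, b, sorted(S), self._cache[key])
        return self._cache[key]


def _subsets(pool: Sequence, cap: int | None):
    """Subsets in increasing cardinality, lexicographic within cardinality."""
    pool = sorted(pool, key=repr)
    cap = len(pool) if cap is None else min(cap, len(pool))
    for k in range(cap + 1):
        yield from (frozenset(c) for c in combinations(pool, k))


# ---------------------------------------------------------------------------
# IC
# ---------------------------------------------------------------------------


def _find_skeleton(oracle: CIOracle, variables: Sequence, max_cond: int | None):
    """Step 1 shared by IC and IC*: adjacency iff no separating set exists."""
    variables = sorted(variables, key=repr)
    sepsets: dict[frozenset, frozenset] = {}
    adj: set[frozenset] = set()
    for a, b in combinations(variables, 2):
        others = [v for v in variables if v not in (a, b)]
        for S in _subsets(others, max_cond):
            if oracle.independent(a, b, S):
                sepsets[frozenset((a, b))] = S
                break
        else:
            adj.add(frozenset((a, b)))
    return variables, adj, sepsets


def ic(oracle: CIOracle, variables: Sequence, max_cond: int | None = None) -> Pattern:
    """Inductive causation: recover the pattern of the equivalence class.

    Step 1 links a and b iff no separating set S_ab is found; Step 2 orients
    v-structures a → c ← b for non-adjacent a, b whose separating set does
    not contain their common neighbour c; Step 3 orients as many remaining
    edges as possible subject to creating no new v-structure and no directed
    cycle (Meek's completion rules R1–R3, which are equivalent to that
    closure when no background knowledge is supplied).
    """
    variables, adj, sepsets = _find_skeleton(oracle, variables, max_cond)
    und: set[frozenset] = set(adj)
    arrows: set[tuple] = set()

    def adjacent(x, y):
        return frozenset((x, y)) in und or (x, y) in arrows or (y, x) in arrows

    def orient(x, y):  # x -> y
        e = frozenset((x, y))
        if (y, x) in arrows:
            raise InferenceError(
                f"conflicting orientations demanded for edge {set(e)}: "
                "the oracle's answers are inconsistent with a DAG"
            )
        if e in und:
            und.discard(e)
            arrows.add((x, y))
            return True
        return False

    # Step 2: v-structures
    for pair, S in sepsets.items():
        a, b = sorted(pair, key=repr)
        for c in variables:
            if c in pair or c in S:
                continue
            if adjacent(a, c) and adjacent(b, c):
                for x in (a, b):
                    e = frozenset((x, c))
                    if e in und:
                        orient(x, c)
                    elif (c, x) in arrows:
                        raise InferenceError(
                            f"v-structure at {c} conflicts with existing orientation {c}->{x}"
                        )

    # Step 3: Meek rules R1-R3 to a fixed point
    changed = True
    while changed:
        changed = False
        for e in list(und):
            x, y = sorted(e, key=repr)
            for u, v in ((x, y), (y, x)):
                # R1: w -> u, u - v, w and v non-adjacent  =>  u -> v
                if any(
                    (w, u) in arrows and not adjacent(w, v) and w != v
                    for w in variables
                ):
                    changed |= orient(u, v)
                    break
                # R2: u -> w -> v and u - v  =>  u -> v
                if any(
                    (u, w) in arrows and (w, v) in arrows for w in variables
                ):
                    changed |= orient(u, v)
                    break
                # R3: u - w1, u - w2, w1 -> v, w2 -> v, w1,w2 non-adjacent, u - v
                half = [
                    w
                    for w in variables
                    if frozenset((u, w)) in und and (w, v) in arrows
                ]
                if any(
                    not adjacent(w1, w2)
                    for w1, w2 in combinations(half, 2)
                ):
                    changed |= orient(u, v)
                    break
            if changed:
                break
    return Pattern(
        nodes=frozenset(variables), directed=frozenset(arrows), undirected=frozenset(und)
    )


# ---------------------------------------------------------------------------
# IC*
# ---------------------------------------------------------------------------


def ic_star(
    oracle: CIOracle, variables: Sequence, max_cond: int | None = None
) -> EmbeddedPattern:
    """Inductive causation with latent variables: recover the embedded pattern.

    Steps 1–2 as in IC, with v-structure orientations recorded as dashed
    (potential-cause) arrowheads; Step 3 applies rules 3R1 (promote to a
    genuine solid arrow the only orientation that creates no new v-structure)
    and 3R2 (cycle avoidance) to a fixed point.
    """
    variables, adj, sepsets = _find_skeleton(oracle, variables, max_cond)
    # per-edge state: heads ⊆ endpoints carrying an arrowhead, solid flag
    heads: dict[frozenset, set] = {e: set() for e in adj}
    solid: dict[frozenset, bool] = {e: False for e in adj}

    def adjacent(x, y):
        return frozenset((x, y)) in heads

    # Step 2: potential causes into common neighbours of separated pairs
    for pair, S in sepsets.items():
        a, b = sorted(pair, key=repr)
        for c in variables:
            if c in pair or c in S:
                continue
            if adjacent(a, c) and adjacent(b, c):
                heads[frozenset((a, c))].add(c)
                heads[frozenset((b, c))].add(c)

    def oriented_edges():
        """Single-headed edges as (tail, head) pairs."""
        out = []
        for e, h in heads.items():
            if len(h) == 1:
                (head,) = h
                (tail,) = e - h
                out.append((tail, head))
        return out

    def directed_path(src, dst, excluding: frozenset) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(variables)
        g.add_edges_from(t for t in oriented_edges() if frozenset(t) != excluding)
        return nx.has_path(g, src, dst)

    changed = True
    while changed:
        changed = False
        # 3R1: a, b non-adjacent, common neighbour c; a-c has head at c,
        # c-b has no head at c  =>  genuine c -> b
        for pair in sepsets:
            a, b = sorted(pair, key=repr)
            for c in variables:
                if c in pair or not (adjacent(a, c) and adjacent(b, c)):
                    continue
                for x, y in ((a, b), (b, a)):
                    exy = frozenset((y, c))
                    if c in heads[frozenset((x, c))] and c not in heads[exy]:
                        if not (heads[exy] == {y} and solid[exy]):
                            heads[exy] = {y}
                            solid[exy] = True
                            changed = True
        # 3R2: a link whose causal-direction reading would close a directed
        # cycle is replaced by the type immediately below in the hierarchy
        # that excludes the cycle (undirected -> potential, potential ->
        # bidirectional; a genuine arrow closing a cycle is an inconsistency).
        for e in list(heads):
            x, y = sorted(e, key=repr)
            h = heads[e]
            if len(h) == 0:
                # completing y -> x would close a cycle iff a path x ~> y exists
                if directed_path(x, y, excluding=e):
                    heads[e] = {y}
                    changed = True
                elif directed_path(y, x, excluding=e):
                    heads[e] = {x}
                    changed = True
            elif len(h) == 1:
                (head,) = h
                (tail,) = e - h
                if directed_path(head, tail, excluding=e):
                    if solid[e]:
                        raise InferenceError(
                            f"genuine arrow {tail}->{head} closes a directed cycle: "
                            "the oracle's answers are inconsistent"
                        )
                    heads[e] = {x, y}
                    changed = True

    und, pot, gen, bidi = set(), set(), set(), set()
    for e in heads:
        h = heads[e]
        if len(h) == 0:
            und.add(e)
        elif len(h) == 2:
            bidi.add(e)
        else:
            (head,) = h
            (tail,) = e - h
            (gen if solid[e] else pot).add((tail, head))
    return EmbeddedPattern(
        nodes=frozenset(variables),
        undirected=frozenset(und),
        potential=frozenset(pot),
        genuine=frozenset(gen),
        bidirectional=frozenset(bidi),
    )


# ---------------------------------------------------------------------------
# temporal IC
# ---------------------------------------------------------------------------


def temporal_ic(
    oracle: CIOracle,
    processes: Sequence[str],
    max_lag: int,
    window: int,
    latent: Iterable[str] = (),
) -> CausalStructure:
    """IC specialised to latent-free dynamic processes.

    Temporal precedence orients every arrow, and conditioning on the whole
    observed past minus the candidate source blocks every path between the
    two variables except a direct arrow.  The edge (j, i) → (j′, i+d) is
    therefore present iff that single conditional independence fails, and the
    output is the complete microscopic DAG (unique in its equivalence class).
    """
    if tuple(latent):
        raise InvalidArgumentError("temporal IC assumes no latent processes")
    if window < max_lag + 1:
        raise InvalidArgumentError("window must be at least max_lag + 1")
    processes = sorted(processes)
    nodes = {(p, t) for p in processes for t in range(window)}
    edges = set()
    for t_to in range(1, window):
        past = {(p, t) for p in processes for t in range(t_to)}
        for d in range(1, min(max_lag, t_to) + 1):
            t_from = t_to - d
            for j in processes:
                for j2 in processes:
                    a, b = (j, t_from), (j2, t_to)
                    S = frozenset(past - {a})
                    if not oracle.independent(a, b, S):
                        edges.add((a, b))
    return CausalStructure(nodes=frozenset(nodes), edges=frozenset(edges))


# ---------------------------------------------------------------------------
# ICG*
# ---------------------------------------------------------------------------


def icg_star(
    oracle: ProcessGrangerOracle,
    processes: Sequence[str],
    max_cond: int | None = None,
) -> MixedMacroGraph:
    """Inductive causation with latent processes using Granger causality.

    Step 1: link a ↔ b iff no conditioning set of observed processes cancels
    the instantaneous causality — such pairs are driven by at least one
    latent common driver (which is assumed, like every latent process, to be
    causal on its own past).  Steps 2–3: for the remaining pairs, link a → b
    (resp. a ← b) iff no conditioning set cancels the transfer entropy in
    that direction.  Conditioning sets are searched over subsets of the other
    observed processes in increasing cardinality.
    """
    processes = sorted(processes)
    thr = oracle.threshold
    bidi: set[frozenset] = set()
    for a, b in combinations(processes, 2):
        others = [p for p in processes if p not in (a, b)]
        if not any(oracle.inst(a, b, S) <= thr for S in _subsets(others, max_cond)):
            bidi.add(frozenset((a, b)))
    directed: set[tuple] = set()
    for a, b in combinations(processes, 2):
        if frozenset((a, b)) in bidi:
            continue  # Step 1 excludes these pairs; Granger causality there
            # is implied by the common driver (Eq.-12-type signature)
        others = [p for p in processes if p not in (a, b)]
        for src, dst in ((a, b), (b, a)):
            if not any(
                oracle.te(src, dst, S) <= thr for S in _subsets(others, max_cond)
            ):
                directed.add((src, dst))
    return MixedMacroGraph(
        nodes=frozenset(processes),
        directed=frozenset(directed),
        bidirectional=frozenset(bidi),
    )
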