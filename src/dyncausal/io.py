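"""Serialization: graph JSON, DOT export, VAR model configs (YAML/JSON).

The graph schema is shared by all flavors::

    {"kind": "process|structure|pattern|embedded|macro",
     "nodes": [...],                  # strings; [process, t] pairs for "structure"
     "edges": [{"src": ..., "dst": ..., "type": ..., "lag": int?}, ...],
     "latent": [...]}                 # "process" kind only

Edge types by kind: process/structure use "directed" (process edges carry a
lag >= 1); patterns add "undirected"; embedded patterns use "undirected",
"potential", "genuine", "bidirectional"; macroscopic mixed graphs use
"directed", "bidirectional" and "undirected" (the dotted instantaneous
annotation).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ParseError
from .graphs import (
    CausalStructure,
    EmbeddedPattern,
    GraphLike,
    MixedMacroGraph,
    Pattern,
    ProcessGraph,
)
from .var_gaussian import ObservationMap, VARModel

AnyGraph = ProcessGraph | CausalStructure | Pattern | EmbeddedPattern | MixedMacroGraph


# ---------------------------------------------------------------------------
# graph JSON
# ---------------------------------------------------------------------------


def graph_to_dict(g: AnyGraph) -> dict:
    if isinstance(g, ProcessGraph):
        return {
            "kind": "process",
            "nodes": sorted(g.nodes),
            "edges": [
                {"src": s, "dst": d, "lag": lag, "type": "directed"}
                for s, d, lag in sorted(g.edges)
            ],
            "latent": sorted(g.latent),
        }
    if isinstance(g, CausalStructure):
        enc = lambda n: list(n) if isinstance(n, tuple) else n
        return {
            "kind": "structure",
            "nodes": [enc(n) for n in sorted(g.nodes, key=repr)],
            "edges": [
                {"src": enc(a), "dst": enc(b), "type": "directed"}
                for a, b in sorted(g.edges, key=repr)
            ],
        }
    if isinstance(g, Pattern):
        edges = [
            {"src": a, "dst": b, "type": "directed"} for a, b in sorted(g.directed)
        ]
        edges += [
            {"src": a, "dst": b, "type": "undirected"}
            for a, b in sorted(tuple(sorted(e)) for e in g.undirected)
        ]
        return {"kind": "pattern", "nodes": sorted(g.nodes), "edges": edges}
    if isinstance(g, EmbeddedPattern):
        edges = []
        for a, b in sorted(tuple(sorted(e)) for e in g.undirected):
            edges.append({"src": a, "dst": b, "type": "undirected"})
        for a, b in sorted(g.potential):
            edges.append({"src": a, "dst": b, "type": "potential"})
        for a, b in sorted(g.genuine):
            edges.append({"src": a, "dst": b, "type": "genuine"})
        for a, b in sorted(tuple(sorted(e)) for e in g.bidirectional):
            edges.append({"src": a, "dst": b, "type": "bidirectional"})
        return {"kind": "embedded", "nodes": sorted(g.nodes), "edges": edges}
    if isinstance(g, MixedMacroGraph):
        edges = [
            {"src": a, "dst": b, "type": "directed"} for a, b in sorted(g.directed)
        ]
        edges += [
            {"src": a, "dst": b, "type": "bidirectional"}
            for a, b in sorted(tuple(sorted(e)) for e in g.bidirectional)
        ]
        edges += [
            {"src": a, "dst": b, "type": "undirected"}
            for a, b in sorted(tuple(sorted(e)) for e in g.instantaneous)
        ]
        return {"kind": "macro", "nodes": sorted(g.nodes), "edges": edges}
    raise ParseError(f"cannot serialize object of type {type(g).__name__}")


def graph_from_dict(d: dict) -> AnyGraph:
    kind = d.get("kind")
    nodes = d.get("nodes")
    edges = d.get("edges", [])
    if kind is None or nodes is None:
        raise ParseError("graph dict needs 'kind' and 'nodes'", location="$")

    def typed(edge, i, allowed):
        t = edge.get("type", "directed")
        if t not in allowed:
            raise ParseError(
                f"edge type {t!r} not allowed for kind {kind!r}",
                location=f"edges[{i}]",
            )
        return edge["src"], edge["dst"], t

    try:
        if kind == "process":
            pe = set()
            for i, e in enumerate(edges):
                s, t, _ = typed(e, i, {"directed"})
                lag = e.get("lag")
                if not isinstance(lag, int) or lag < 1:
                    raise ParseError(
                        f"process edge needs an integer lag >= 1, got {lag!r}",
                        location=f"edges[{i}]",
                    )
                pe.add((s, t, lag))
            return ProcessGraph(
                nodes=frozenset(nodes),
                edges=frozenset(pe),
                latent=frozenset(d.get("latent", [])),
            )
        if kind == "structure":
            dec = lambda n: tuple(n) if isinstance(n, list) else n
            nn = frozenset(dec(n) for n in nodes)
            ee = set()
            for i, e in enumerate(edges):
                s, t, _ = typed(e, i, {"directed"})
                ee.add((dec(s), dec(t)))
            return CausalStructure(nodes=nn, edges=frozenset(ee))
        if kind == "pattern":
            di, un = set(), set()
            for i, e in enumerate(edges):
                s, t, ty = typed(e, i, {"directed", "undirected"})
                (di.add((s, t)) if ty == "directed" else un.add(frozenset((s, t))))
            return Pattern(
                nodes=frozenset(nodes), directed=frozenset(di), undirected=frozenset(un)
            )
        if kind == "embedded":
            un, po, ge, bi = set(), set(), set(), set()
            bucket = {"undirected": un, "potential": po, "genuine": ge, "bidirectional": bi}
            for i, e in enumerate(edges):
                s, t, ty = typed(
                    e, i, {"undirected", "potential", "genuine", "bidirectional"}
                )
                if ty in ("undirected", "bidirectional"):
                    bucket[ty].add(frozenset((s, t)))
                else:
                    bucket[ty].add((s, t))
            return EmbeddedPattern(
                nodes=frozenset(nodes),
                undirected=frozenset(un),
                potential=frozenset(po),
                genuine=frozenset(ge),
                bidirectional=frozenset(bi),
            )
        if kind == "macro":
            di, bi, inst = set(), set(), set()
            for i, e in enumerate(edges):
                s, t, ty = typed(e, i, {"directed", "bidirectional", "undirected"})
                if ty == "directed":
                    di.add((s, t))
                elif ty == "bidirectional":
                    bi.add(frozenset((s, t)))
                else:
                    inst.add(frozenset((s, t)))
            return MixedMacroGraph(
                nodes=frozenset(nodes),
                directed=frozenset(di),
                bidirectional=frozenset(bi),
                instantaneous=frozenset(inst),
            )
    except ParseError:
        raise
    except Exception as exc:  # invariant violations surface as parse errors
        raise ParseError(str(exc)) from exc
    raise ParseError(f"unknown graph kind {kind!r}", location="kind")


def write_graph(g: AnyGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(graph_to_dict(g), indent=2) + "\n")


def read_graph(path: str | Path) -> AnyGraph:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}", location=str(path)) from exc
    return graph_from_dict(d)


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------

_DOT_STYLE = {
    "directed": 'style=solid',
    "potential": 'style=dashed',
    "genuine": 'style=bold',
    "bidirectional": 'dir=both, style=solid',
    "undirected": 'dir=none, style=solid',
    "instantaneous": 'dir=none, style=dotted',
}


def _q(x) -> str:
    return '"' + str(x).replace('"', r"\"") + '"'


def to_dot(g: AnyGraph, name: str = "G") -> str:
    """Graphviz DOT text; the four embedded-pattern edge types map to four styles."""
    lines = [f"digraph {name} {{"]
    latent = getattr(g, "latent", frozenset())
    for n in sorted(g.nodes, key=repr):
        attrs = ' [style=dashed]' if n in latent else ""
        lines.append(f"  {_q(n)}{attrs};")

    def edge(a, b, kind, extra=""):
        lines.append(f"  {_q(a)} -> {_q(b)} [{_DOT_STYLE[kind]}{extra}];")

    if isinstance(g, ProcessGraph):
        for s, t, lag in sorted(g.edges):
            edge(s, t, "directed", f', label="{lag}"')
    elif isinstance(g, CausalStructure):
        for a, b in sorted(g.edges, key=repr):
            edge(a, b, "directed")
    elif isinstance(g, Pattern):
        for a, b in sorted(g.directed):
            edge(a, b, "directed")
        for e in sorted(map(sorted, g.undirected)):
            edge(e[0], e[1], "undirected")
    elif isinstance(g, EmbeddedPattern):
        for e in sorted(map(sorted, g.undirected)):
            edge(e[0], e[1], "undirected")
        for a, b in sorted(g.potential):
            edge(a, b, "potential")
        for a, b in sorted(g.genuine):
            edge(a, b, "genuine")
        for e in sorted(map(sorted, g.bidirectional)):
            edge(e[0], e[1], "bidirectional")
    elif isinstance(g, MixedMacroGraph):
        for a, b in sorted(g.directed):
            edge(a, b, "directed")
        for e in sorted(map(sorted, g.bidirectional)):
            edge(e[0], e[1], "bidirectional")
        for e in sorted(map(sorted, g.instantaneous)):
            edge(e[0], e[1], "instantaneous")
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# VAR model configs
# ---------------------------------------------------------------------------


def model_to_dict(m: VARModel, o: ObservationMap | None = None) -> dict:
    d = {
        "names": list(m.names),
        "coefficients": m.coefficients.tolist(),
        "innovation_cov": m.innovation_cov.tolist(),
    }
    if o is not None:
        d["observation"] = {
            "weights": o.weights.tolist(),
            "signal_names": list(o.signal_names),
            "noise_variances": o.noise_variances.tolist(),
            "subsample": o.subsample,
        }
    return d


def model_from_dict(d: dict) -> tuple[VARModel, ObservationMap | None]:
    try:
        m = VARModel(
            np.asarray(d["coefficients"], dtype=float),
            None
            if d.get("innovation_cov") is None
            else np.asarray(d["innovation_cov"], dtype=float),
            names=tuple(d["names"]) if "names" in d else None,
        )
    except KeyError as exc:
        raise ParseError(f"model config missing key {exc}", location="$") from exc
    except Exception as exc:
        raise ParseError(str(exc), location="coefficients") from exc
    o = None
    if "observation" in d:
        od = d["observation"]
        try:
            o = ObservationMap(
                np.asarray(od["weights"], dtype=float),
                signal_names=tuple(od["signal_names"]) if "signal_names" in od else None,
                noise_variances=od.get("noise_variances"),
                subsample=int(od.get("subsample", 1)),
            )
        except Exception as exc:
            raise ParseError(str(exc), location="observation") from exc
    return m, o


def write_model(m: VARModel, o: ObservationMap | None, path: str | Path) -> None:
    path = Path(path)
    d = model_to_dict(m, o)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2) + "\n")


def read_model(path: str | Path) -> tuple[VARModel, ObservationMap | None]:
    """Read a model config; YAML is a superset of JSON so one loader serves both."""
    try:
        d = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"invalid config: {exc}", location=str(path)) from exc
    if not isinstance(d, dict):
        raise ParseError("model config must be a mapping", location=str(path))
    return model_from_dict(d)
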