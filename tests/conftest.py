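"""Shared generators: seeded random DAGs, process graphs and stable VAR models."""

from __future__ import annotations

import string

import numpy as np
import pytest

from dyncausal.graphs import CausalStructure, ProcessGraph
from dyncausal.var_gaussian import VARModel


def random_dag(rng: np.random.Generator, n: int, p: float = 0.4) -> CausalStructure:
    """Random DAG over letter-named nodes, edges forward in a random order."""
    names = list(string.ascii_uppercase[:n])
    order = list(rng.permutation(names))
    edges = {
        (order[i], order[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    }
    return CausalStructure(nodes=frozenset(names), edges=frozenset(edges))


def all_dags_on(nodes: tuple[str, ...]):
    """Every DAG on the given nodes with edges respecting the listed order.

    Orientation-complete enumeration is not needed for the separation
    equivalence checks (relabelling covers the rest), so one topological
    order suffices.
    """
    pairs = [
        (nodes[i], nodes[j])
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
    ]
    for mask in range(2 ** len(pairs)):
        edges = {pairs[k] for k in range(len(pairs)) if mask >> k & 1}
        yield CausalStructure(nodes=frozenset(nodes), edges=frozenset(edges))


def random_process_graph(
    rng: np.random.Generator,
    n_proc: int = 3,
    max_lag: int = 2,
    p: float = 0.35,
    latent: frozenset = frozenset(),
) -> ProcessGraph:
    """Random process graph with autocausal self-loops on every process."""
    names = [f"P{i}" for i in range(n_proc)]
    edges = {(nm, nm, 1) for nm in names}
    for a in names:
        for b in names:
            if a == b:
                continue
            for lag in range(1, max_lag + 1):
                if rng.random() < p:
                    edges.add((a, b, lag))
    return ProcessGraph(
        nodes=frozenset(names), edges=frozenset(edges), latent=frozenset(latent)
    )


def random_stable_var(
    rng: np.random.Generator,
    n: int,
    names: tuple[str, ...] | None = None,
    radius: float | None = None,
) -> VARModel:
    """Dense random coefficients rescaled to a target spectral radius."""
    C = rng.normal(0.0, 1.0, (n, n))
    rho = max(np.abs(np.linalg.eigvals(C)))
    target = radius if radius is not None else rng.uniform(0.3, 0.9)
    C *= target / rho
    return VARModel(C, names=names)


def var_from_process_graph(
    rng: np.random.Generator, g: ProcessGraph, lo: float = 0.3, hi: float = 0.7
) -> VARModel:
    """Lag-1 VAR whose nonzero coefficients follow the graph's lag-1 edges.

    Coefficient magnitudes are drawn uniformly; the matrix is rescaled (if
    needed) to spectral radius 0.9 to guarantee stationarity.  Only lag-1
    edges are representable in an order-1 model.
    """
    names = tuple(sorted(g.nodes))
    n = len(names)
    C = np.zeros((n, n))
    for src, dst, lag in g.edges:
        if lag != 1:
            raise ValueError("order-1 model: only lag-1 edges")
        sign = 1 if rng.random() < 0.5 else -1
        C[names.index(dst), names.index(src)] = sign * rng.uniform(lo, hi)
    rho = max(np.abs(np.linalg.eigvals(C)))
    if rho > 0.9:
        C *= 0.9 / rho
    return VARModel(C, names=names)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
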