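"""Brute-force ground truth: explicit trap-space enumeration, state
transition graphs, trap sets and attractors.

Everything here works by exhaustive iteration over states or candidate
spaces and is intended for small networks only; it serves as the
reference the symbolic/siphon pipeline is checked against.
"""

from __future__ import annotations

import itertools
from enum import Enum
from typing import Iterable

import networkx as nx

from .model import (
    MVN,
    CapacityError,
    Semantics,
    Space,
    is_subspace,
    is_trap_space,
    stepwise_target,
)

__all__ = [
    "Concurrency",
    "enumerate_trap_spaces",
    "build_stg",
    "attractors",
    "is_trap_set",
    "stg_to_dot",
]

DEFAULT_SPACE_LIMIT = 10**6


class Concurrency(str, Enum):
    ASYNCHRONOUS = "asynchronous"
    SYNCHRONOUS = "synchronous"


def _nonempty_subsets(levels: Iterable[int]) -> list[tuple[int, ...]]:
    vals = tuple(levels)
    out = []
    for r in range(1, len(vals) + 1):
        out.extend(itertools.combinations(vals, r))
    return out


def enumerate_trap_spaces(
    mvn: MVN,
    semantics: Semantics,
    which: str = "all",
    *,
    limit: int = DEFAULT_SPACE_LIMIT,
) -> list[Space]:
    """Enumerate trap spaces by testing every candidate space.

    ``which`` selects ``all`` trap spaces (including the total space),
    ``minimal`` (no proper trap subspace), ``maximal`` (proper trap
    spaces with no proper trap superspace), or ``fixed`` (singleton trap
    spaces, i.e. fixed points).  Output is sorted canonically.
    """
    if which not in {"all", "minimal", "maximal", "fixed"}:
        raise ValueError(f"unknown selector {which!r}")
    n_candidates = 1
    for v in mvn.variables:
        n_candidates *= 2 ** len(mvn.levels(v)) - 1
    if n_candidates > limit:
        raise CapacityError(f"{n_candidates} candidate spaces exceed limit {limit}")

    per_var = [_nonempty_subsets(mvn.levels(v)) for v in mvn.variables]
    traps = [
        Space(dict(zip(mvn.variables, combo)))
        for combo in itertools.product(*per_var)
        if is_trap_space(
            mvn, Space(dict(zip(mvn.variables, combo))), semantics, limit=limit
        )
    ]

    if which == "all":
        result = traps
    elif which == "fixed":
        result = [m for m in traps if m.is_singleton()]
    elif which == "minimal":
        result = [
            m
            for m in traps
            if not any(is_subspace(o, m, strict=True) for o in traps)
        ]
    else:  # maximal: proper trap spaces below no other proper trap space
        total = mvn.total_space()
        proper = [m for m in traps if m != total]
        result = [
            m
            for m in proper
            if not any(is_subspace(m, o, strict=True) for o in proper)
        ]
    return sorted(result, key=Space.sort_key)


def build_stg(
    mvn: MVN,
    semantics: Semantics,
    concurrency: Concurrency = Concurrency.ASYNCHRONOUS,
    *,
    limit: int = DEFAULT_SPACE_LIMIT,
) -> nx.DiGraph:
    """State-transition graph under the chosen semantics and concurrency.

    Asynchronous mode adds one edge per variable whose stepwise target
    differs from its current level, plus an explicit self-loop on states
    where nothing can change; synchronous mode adds the single edge
    where all variables step together (possibly a self-loop).
    """
    if mvn.n_states() > limit:
        raise CapacityError(f"{mvn.n_states()} states exceed limit {limit}")
    concurrency = Concurrency(concurrency)
    g = nx.DiGraph()
    for x in mvn.states():
        g.add_node(x)
        targets = [stepwise_target(mvn, v, x, semantics) for v in mvn.variables]
        if concurrency is Concurrency.ASYNCHRONOUS:
            moved = False
            for i, (xv, t) in enumerate(zip(x, targets)):
                if t != xv:
                    y = x[:i] + (t,) + x[i + 1 :]
                    g.add_edge(x, y)
                    moved = True
            if not moved:
                g.add_edge(x, x)
        else:
            g.add_edge(x, tuple(targets))
    return g


def attractors(stg: nx.DiGraph) -> list[frozenset]:
    """Bottom strongly connected components (minimal trap sets)."""
    out = []
    for scc in nx.strongly_connected_components(stg):
        if all(y in scc for x in scc for y in stg.successors(x)):
            out.append(frozenset(scc))
    return sorted(out, key=lambda s: sorted(s))


def is_trap_set(stg: nx.DiGraph, states: Iterable[tuple]) -> bool:
    """True iff no edge leaves the given state set."""
    states = set(states)
    for x in states:
        if x not in stg:
            raise ValueError(f"state {x} not in the transition graph")
    return all(y in states for x in states for y in stg.successors(x))


def stg_to_dot(stg: nx.DiGraph) -> str:
    """Small DOT export for debugging (node label = state tuple)."""
    lines = ["digraph stg {"]
    for x in sorted(stg.nodes):
        lines.append(f'  "{x}";')
    for x, y in sorted(stg.edges):
        lines.append(f'  "{x}" -> "{y}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
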