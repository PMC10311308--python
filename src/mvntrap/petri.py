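"""One-safe Petri-net encoding of asynchronous MVN dynamics.

Each level of each variable becomes a place ``p_{v=i}``; a valid marking
holds exactly one token per variable block and encodes a state.  For
every stepwise update ``(v=l) -> (v=k)`` we enumerate the satisfying
partial valuations of ``p_{v=l} ∧ B̂_k`` (the stepwise condition for
output ``k``) and emit one transition per concrete-level expansion: the
transition moves the token from ``p_{v=l}`` to ``p_{v=k}`` while testing
(borrowing and returning) one token per constrained context variable.

The firing graph over valid markings is then isomorphic to the
asynchronous state-transition graph with self-loops removed — the
central correctness property the test suite checks against the
exhaustive oracle.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .bdd import BDD, FALSE
from .model import MVN, CapacityError, Semantics, Space
from .series import BddSeries, OneHotVars, build_onehot, stepwise_series

__all__ = [
    "Place",
    "Transition",
    "PetriNet",
    "EncodingConfig",
    "encode",
    "choose_ordering",
    "reorder_series",
    "mirror",
    "unmirror",
    "fire",
    "enabled",
    "marking_of_state",
    "state_of_marking",
    "firing_graph",
    "to_pnml",
    "to_asp_facts",
]

Place = tuple[str, int]  # (variable, level)
Marking = frozenset  # frozenset[Place]


@dataclass(frozen=True)
class Transition:
    """Moves ``variable`` from ``from_level`` to ``to_level`` under a
    context of read conditions on other variables."""

    variable: str
    from_level: int
    to_level: int
    context: frozenset  # frozenset[Place]

    def __post_init__(self) -> None:
        if self.to_level == self.from_level:
            raise ValueError("self-transitions are never emitted")
        ctx_vars = [v for v, _ in self.context]
        if self.variable in ctx_vars:
            raise ValueError("context must not mention the moving variable")
        if len(ctx_vars) != len(set(ctx_vars)):
            raise ValueError("context mentions a variable twice")

    @property
    def pred(self) -> frozenset:
        return self.context | {(self.variable, self.from_level)}

    @property
    def succ(self) -> frozenset:
        return self.context | {(self.variable, self.to_level)}

    def sort_key(self) -> tuple:
        return (self.variable, self.from_level, self.to_level,
                tuple(sorted(self.context)))


@dataclass(frozen=True)
class PetriNet:
    """One-safe net with one place per (variable, level)."""

    blocks: tuple[tuple[str, tuple[int, ...]], ...]  # declaration order
    transitions: tuple[Transition, ...]

    @property
    def places(self) -> frozenset:
        return frozenset(
            (v, i) for v, levels in self.blocks for i in levels
        )

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for v, _ in self.blocks)

    def levels(self, variable: str) -> tuple[int, ...]:
        for v, lv in self.blocks:
            if v == variable:
                return lv
        raise KeyError(f"unknown variable {variable!r}")


@dataclass(frozen=True)
class EncodingConfig:
    """Knobs of the encoder.

    ``ordering_trials`` seeded random indicator orderings are tried per
    update function and the one yielding the fewest transitions wins.
    """

    ordering_trials: int = 5
    seed: int = 0
    max_transitions: int = 10**6

    def __post_init__(self) -> None:
        if self.ordering_trials < 1:
            raise ValueError("ordering_trials must be >= 1")


# ---------------------------------------------------------------------------
# transition generation
# ---------------------------------------------------------------------------


def _expand_path(
    onehot: OneHotVars,
    path: Mapping[int, bool],
    moving: str,
    from_level: int,
) -> Iterable[frozenset]:
    """Concrete-level context expansions of one satisfying partial
    valuation.

    A variable constrained only negatively on the path is expanded into
    every level consistent with the path (read arcs can only test token
    presence); unconstrained variables yield no arcs; expansions that
    cover no valid one-hot state are dropped.
    """
    positives: dict[str, set[int]] = {}
    negatives: dict[str, set[int]] = {}
    for idx, polarity in path.items():
        u, i = onehot.variable_of(idx)
        (positives if polarity else negatives).setdefault(u, set()).add(i)

    # moving variable: the path must be compatible with v = from_level
    if positives.get(moving, {from_level}) != {from_level}:
        return  # path only covers invalid assignments
    allowed: list[tuple[str, list[int]]] = []
    for u in set(positives) | set(negatives):
        if u == moving:
            continue
        pos = positives.get(u, set())
        if len(pos) > 1:
            return  # two indicators of one block forced true: invalid only
        if pos:
            levels = [next(iter(pos))]
        else:
            levels = [i for i in onehot.levels(u) if i not in negatives[u]]
            if not levels:
                return
        allowed.append((u, levels))
    names = [u for u, _ in allowed]
    for combo in itertools.product(*(lv for _, lv in allowed)):
        yield frozenset(zip(names, combo))


def _transitions_of_series(
    hat: BddSeries, *, max_transitions: int = 10**6
) -> list[Transition]:
    """All transitions of one stepwise series (its moving variable)."""
    bdd = hat.manager
    onehot = hat.onehot
    v = hat.target
    out: set[Transition] = set()
    for k, node in hat.entries:
        for l in onehot.levels(v):
            if l == k:
                continue
            cond = bdd.apply_and(bdd.var(onehot.index[(v, l)]), node)
            if cond == FALSE:
                continue
            for path in bdd.sat_paths(cond):
                for context in _expand_path(onehot, path, v, l):
                    out.add(Transition(v, l, k, context))
                    if len(out) > max_transitions:
                        raise CapacityError(
                            f"more than {max_transitions} transitions for {v!r}"
                        )
    return sorted(out, key=Transition.sort_key)


def reorder_series(series: BddSeries, onehot: OneHotVars) -> BddSeries:
    """Rebuild a series in a fresh manager under a different indicator
    order (function-preserving: each satisfying path becomes a cube)."""
    bdd = BDD(onehot.num_vars)
    entries = []
    for level, node in series.entries:
        cubes = []
        for path in series.manager.sat_paths(node):
            lits = {
                onehot.index[series.onehot.variable_of(idx)]: pol
                for idx, pol in path.items()
            }
            cubes.append(bdd.cube(lits))
        entries.append((level, bdd.disj(cubes)))
    return BddSeries(bdd, onehot, series.target, tuple(entries))


def choose_ordering(
    series: BddSeries,
    config: EncodingConfig,
    semantics: Semantics = Semantics.GENERAL,
) -> OneHotVars:
    """Pick, out of ``ordering_trials`` seeded random block orders, the
    one whose rebuilt series yields the fewest transitions (ties broken
    by first-found; deterministic for a fixed seed)."""
    rng = random.Random(f"{config.seed}:{series.target}")
    variables = list(series.onehot.variables())
    domains = {v: lv for v, lv in series.onehot.blocks}
    best: tuple[int, OneHotVars] | None = None
    for _ in range(config.ordering_trials):
        order = variables[:]
        rng.shuffle(order)
        blocks = tuple((v, domains[v]) for v in order)
        index = {}
        for v, levels in blocks:
            for i in levels:
                index[(v, i)] = len(index)
        candidate = OneHotVars(blocks, index)
        rebuilt = stepwise_series(reorder_series(series, candidate), semantics)
        count = len(
            _transitions_of_series(rebuilt, max_transitions=config.max_transitions)
        )
        if best is None or count < best[0]:
            best = (count, candidate)
    assert best is not None
    return best[1]


def encode(
    mvn: MVN,
    series: Mapping[str, BddSeries],
    semantics: Semantics,
    config: EncodingConfig = EncodingConfig(),
) -> PetriNet:
    """Encode an MVN (given its per-variable condition series) as a
    one-safe Petri net under the chosen semantics."""
    transitions: list[Transition] = []
    for v in mvn.variables:
        s = series[v]
        if config.ordering_trials > 1:
            ordering = choose_ordering(s, config, semantics)
            s = reorder_series(s, ordering)
        hat = stepwise_series(s, semantics)
        transitions.extend(
            _transitions_of_series(hat, max_transitions=config.max_transitions)
        )
        if len(transitions) > config.max_transitions:
            raise CapacityError(
                f"net exceeds {config.max_transitions} transitions"
            )
    blocks = tuple((v, tuple(mvn.levels(v))) for v in mvn.variables)
    return PetriNet(blocks, tuple(transitions))


# ---------------------------------------------------------------------------
# mirror map and firing semantics
# ---------------------------------------------------------------------------


def mirror(space: Space, mvn: MVN) -> frozenset:
    """Places excluded by a space: ``{p_{v=i} | i ∉ m(v)}``."""
    return frozenset(
        (v, i)
        for v in mvn.variables
        for i in mvn.levels(v)
        if i not in space[v]
    )


def unmirror(places: Iterable[Place], mvn: MVN) -> Space:
    """Inverse of :func:`mirror`; fails if any variable loses all levels."""
    excluded = set(places)
    levels = {}
    for v in mvn.variables:
        keep = tuple(i for i in mvn.levels(v) if (v, i) not in excluded)
        if not keep:
            raise ValueError(f"place set excludes every level of {v!r}")
        levels[v] = keep
    return Space(levels)


def marking_of_state(mvn: MVN, state: Sequence[int]) -> Marking:
    return frozenset(zip(mvn.variables, state))


def state_of_marking(net: PetriNet, marking: Marking) -> tuple:
    by_var = dict(marking)
    if len(by_var) != len(marking) or set(by_var) != set(net.variables):
        raise ValueError("marking is not a valid state encoding")
    return tuple(by_var[v] for v in net.variables)


def enabled(marking: Marking, transition: Transition) -> bool:
    return transition.pred <= marking


def fire(net: PetriNet, marking: Marking, transition: Transition) -> Marking:
    """Fire an enabled transition: ``(M \\ pred) ∪ succ``."""
    if not enabled(marking, transition):
        raise ValueError(f"transition {transition} not enabled")
    return frozenset(marking - transition.pred) | transition.succ


def firing_graph(net: PetriNet, mvn: MVN) -> nx.DiGraph:
    """Reachability structure over all valid markings, with nodes decoded
    to state tuples (no self-loops by construction)."""
    g = nx.DiGraph()
    for x in mvn.states():
        m = marking_of_state(mvn, x)
        g.add_node(x)
        for t in net.transitions:
            if enabled(m, t):
                g.add_edge(x, state_of_marking(net, fire(net, m, t)))
    return g


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def _pid(place: Place) -> str:
    return f"p_{place[0]}_{place[1]}"


def to_pnml(net: PetriNet) -> str:
    """Standard PNML rendering (places, transitions, arcs)."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<pnml xmlns="http://www.pnml.org/version-2009/grammar/pnml">',
        '  <net id="mvn" type="http://www.pnml.org/version-2009/grammar/ptnet">',
        '    <page id="page0">',
    ]
    for v, levels in net.blocks:
        for i in levels:
            lines.append(
                f'      <place id="{_pid((v, i))}">'
                f"<name><text>{v}={i}</text></name></place>"
            )
    for n, t in enumerate(net.transitions):
        lines.append(f'      <transition id="t{n}"/>')
        for p in sorted(t.pred):
            lines.append(
                f'      <arc id="a{n}_in_{_pid(p)}" source="{_pid(p)}" target="t{n}"/>'
            )
        for p in sorted(t.succ):
            lines.append(
                f'      <arc id="a{n}_out_{_pid(p)}" source="t{n}" target="{_pid(p)}"/>'
            )
    lines += ["    </page>", "  </net>", "</pnml>"]
    return "\n".join(lines) + "\n"


def to_asp_facts(net: PetriNet) -> str:
    """Plain fact listing: place/2, trans/1, pre/2, post/2."""
    lines = []
    for v, levels in net.blocks:
        for i in levels:
            lines.append(f'place("{v}",{i}).')
    for n, t in enumerate(net.transitions):
        lines.append(f"trans({n}).")
        for u, i in sorted(t.pred):
            lines.append(f'pre({n},p("{u}",{i})).')
        for u, i in sorted(t.succ):
            lines.append(f'post({n},p("{u}",{i})).')
    return "\n".join(lines) + "\n"
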