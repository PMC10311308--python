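"""Update functions as series of boolean conditions over one-hot level
indicators.

Each multi-valued update function ``f_v`` is stored as an ordered list
of pairs ``(output level, condition)`` where the condition is a reduced
ordered BDD over indicator variables ``p_{u=i}`` (one per level of each
network variable).  On every *valid* one-hot assignment (exactly one
indicator true per variable block) exactly one condition holds, so the
series is a partition of the state space; invalid assignments are
don't-cares.  This is the representation the Petri-net transition
generator consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .bdd import BDD, FALSE, TRUE
from .model import MVN, CapacityError, Semantics

__all__ = [
    "OneHotVars",
    "BddSeries",
    "build_onehot",
    "series_from_table",
    "stepwise_series",
    "check_partition",
    "support",
]

DEFAULT_TABLE_LIMIT = 10**6


@dataclass(frozen=True)
class OneHotVars:
    """Ordered one-hot indicator variables ``p_{v=i}``.

    ``blocks`` lists ``(variable, levels)`` in BDD order; levels are
    ascending within a block.  ``index`` maps ``(variable, level)`` to
    the BDD variable index.
    """

    blocks: tuple[tuple[str, tuple[int, ...]], ...]
    index: Mapping[tuple[str, int], int]

    @property
    def num_vars(self) -> int:
        return len(self.index)

    def levels(self, variable: str) -> tuple[int, ...]:
        for v, lv in self.blocks:
            if v == variable:
                return lv
        raise KeyError(f"unknown variable {variable!r}")

    def variables(self) -> tuple[str, ...]:
        return tuple(v for v, _ in self.blocks)

    def variable_of(self, idx: int) -> tuple[str, int]:
        for (v, i), j in self.index.items():
            if j == idx:
                return v, i
        raise IndexError(idx)

    def encode_state(self, mvn: MVN, state: Sequence[int]) -> list[bool]:
        """One-hot boolean assignment of a full state."""
        assignment = [False] * self.num_vars
        for v, x in zip(mvn.variables, state):
            assignment[self.index[(v, x)]] = True
        return assignment


def build_onehot(mvn: MVN, block_order: Sequence[str] | None = None) -> OneHotVars:
    """One indicator per (variable, level); blocks follow ``block_order``
    (default: declaration order), levels ascending within a block."""
    order = tuple(block_order) if block_order is not None else mvn.variables
    if sorted(order) != sorted(mvn.variables):
        raise ValueError("block order must be a permutation of the variables")
    blocks = []
    index: dict[tuple[str, int], int] = {}
    for v in order:
        levels = tuple(mvn.levels(v))
        blocks.append((v, levels))
        for i in levels:
            index[(v, i)] = len(index)
    return OneHotVars(tuple(blocks), index)


@dataclass(frozen=True)
class BddSeries:
    """One update function as a level-indexed series of BDD conditions."""

    manager: BDD
    onehot: OneHotVars
    target: str
    entries: tuple[tuple[int, int], ...]  # (output level, BDD node)

    def evaluate(self, mvn: MVN, state: Sequence[int]) -> int:
        """Function value on a concrete state (via one-hot encoding)."""
        assignment = self.onehot.encode_state(mvn, state)
        hits = [
            level
            for level, node in self.entries
            if self.manager.evaluate(node, assignment)
        ]
        if len(hits) != 1:
            raise ValueError(
                f"series for {self.target!r} is not a partition at {tuple(state)}"
            )
        return hits[0]

    def condition(self, level: int) -> int:
        for y, node in self.entries:
            if y == level:
                return node
        return FALSE


def series_from_table(
    mvn: MVN,
    variable: str,
    ordering: OneHotVars | None = None,
    *,
    manager: BDD | None = None,
    limit: int = DEFAULT_TABLE_LIMIT,
) -> BddSeries:
    """Build the condition series of ``f_variable`` from its full table.

    The condition of each output level is the disjunction, over all
    input states mapping to it, of the cube of positive indicators
    ``p_{u=x_u}``; levels absent from the image are omitted.
    """
    if mvn.n_states() > limit:
        raise CapacityError(f"{mvn.n_states()} table rows exceed limit {limit}")
    onehot = ordering if ordering is not None else build_onehot(mvn)
    bdd = manager if manager is not None else BDD(onehot.num_vars)
    # cubes range only over the variables the function actually reads,
    # so constants reduce to TRUE and contexts stay compact
    relevant = _relevant_variables(mvn, variable)
    seen: set[tuple] = set()
    by_level: dict[int, list[int]] = {}
    for x in mvn.states():
        key = tuple(xv for v, xv in zip(mvn.variables, x) if v in relevant)
        if key in seen:
            continue
        seen.add(key)
        y = mvn.functions[variable](x)
        cube = bdd.cube({onehot.index[(v, xv)]: True
                         for v, xv in zip(mvn.variables, x) if v in relevant})
        by_level.setdefault(y, []).append(cube)
    entries = tuple(
        (level, bdd.disj(by_level[level])) for level in sorted(by_level)
    )
    return BddSeries(bdd, onehot, variable, entries)


def _relevant_variables(mvn: MVN, variable: str) -> frozenset[str]:
    """Variables whose level can change the function's output."""
    f = mvn.functions[variable]
    table = {x: f(x) for x in mvn.states()}
    out: set[str] = set()
    for i, u in enumerate(mvn.variables):
        for x, y in table.items():
            for alt in mvn.levels(u):
                if alt != x[i] and table[x[:i] + (alt,) + x[i + 1 :]] != y:
                    out.add(u)
                    break
            if u in out:
                break
    return frozenset(out)


def stepwise_series(series: BddSeries, semantics: Semantics) -> BddSeries:
    """Series of the stepwise function ``f̂`` for the chosen semantics.

    General semantics is the identity transform.  Unitary semantics
    redistributes each condition: the part of the level-``o`` condition
    where the target variable currently sits at level ``l`` is reassigned
    to output ``l + sign(o - l)``.
    """
    if Semantics(semantics) is Semantics.GENERAL:
        return series
    bdd = series.manager
    onehot = series.onehot
    v = series.target
    valid = _valid_states_bdd(bdd, onehot)
    by_level: dict[int, list[int]] = {}
    for l in onehot.levels(v):
        at_l = bdd.var(onehot.index[(v, l)])
        for o, node in series.entries:
            step = l + (o > l) - (o < l)
            part = bdd.apply_and(at_l, node)
            # keep only parts that cover some *valid* one-hot state
            if bdd.apply_and(part, valid) != FALSE:
                by_level.setdefault(step, []).append(part)
    entries = tuple((level, bdd.disj(by_level[level]))
                    for level in sorted(by_level))
    return BddSeries(bdd, onehot, v, entries)


def _valid_states_bdd(bdd: BDD, onehot: OneHotVars) -> int:
    """Constraint: exactly one indicator true per variable block."""
    out = TRUE
    for v, levels in onehot.blocks:
        one = FALSE
        for i in levels:
            cube = bdd.cube(
                {onehot.index[(v, j)]: (j == i) for j in levels}
            )
            one = bdd.apply_or(one, cube)
        out = bdd.apply_and(out, one)
    return out


def check_partition(
    series: BddSeries, domains: Mapping[str, tuple[int, int]] | None = None
) -> bool:
    """True iff the conditions partition the valid one-hot states.

    Pairwise disjointness and joint exhaustiveness are both checked
    symbolically, restricted to valid assignments.
    """
    bdd = series.manager
    valid = _valid_states_bdd(bdd, series.onehot)
    nodes = [node for _, node in series.entries]
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if bdd.conj([nodes[i], nodes[j], valid]) != FALSE:
                return False
    union = bdd.disj(nodes)
    return bdd.apply_and(valid, bdd.apply_not(union)) == FALSE


def support(series: BddSeries) -> frozenset[str]:
    """Variables whose indicators survive in any reduced condition."""
    out: set[str] = set()
    for _, node in series.entries:
        for idx in series.manager.support(node):
            out.add(series.onehot.variable_of(idx)[0])
    return frozenset(out)
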