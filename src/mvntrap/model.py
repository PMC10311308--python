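"""Multi-valued logical networks: data model and elementary dynamics.

A multi-valued network (MVN) assigns each variable an integer interval
domain ``[lo, hi]`` and an update function from full network states to a
value in that domain.  Two stepwise semantics are supported:

* **general** — a variable jumps directly to its update-function target;
* **unitary** — a variable moves by at most one level per step toward
  the target (``x + sign(f(x) - x)``).

States are tuples of integers aligned with :attr:`MVN.variables`; spaces
assign each variable a non-empty subset of its domain and are read as
the set of states they contain.  A *trap space* is a space no stepwise
update can leave, independently of update concurrency.
"""

from __future__ import annotations

import itertools
import random
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "MVN",
    "Space",
    "Semantics",
    "CapacityError",
    "evaluate",
    "stepwise_target",
    "is_trap_space",
    "is_subspace",
    "intersect_spaces",
    "apply_knockout",
    "random_mvn",
    "worked_example",
    "parse_native",
    "format_native",
]

State = tuple  # alias for readability: tuple of ints aligned with MVN.variables

#: refuse exhaustive iteration over spaces larger than this many states
DEFAULT_STATE_LIMIT = 10**6


class CapacityError(RuntimeError):
    """An exhaustive operation would exceed its configured size limit."""


class Semantics(str, Enum):
    """Stepwise update semantics of an MVN."""

    GENERAL = "general"
    UNITARY = "unitary"


@dataclass(frozen=True)
class MVN:
    """A multi-valued network ``(V, K, F)``.

    Parameters
    ----------
    variables
        Ordered variable names; must be unique.
    domains
        Per-variable inclusive integer bounds ``(lo, hi)`` with ``lo <= hi``.
    functions
        Per-variable update function mapping a full state tuple to an
        integer inside the variable's domain.
    """

    variables: tuple[str, ...]
    domains: Mapping[str, tuple[int, int]]
    functions: Mapping[str, Callable[[State], int]]

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")
        for v in self.variables:
            if v not in self.domains:
                raise ValueError(f"missing domain for {v!r}")
            lo, hi = self.domains[v]
            if lo > hi:
                raise ValueError(f"empty domain for {v!r}: [{lo}, {hi}]")
            if v not in self.functions:
                raise ValueError(f"missing update function for {v!r}")

    # -- helpers ---------------------------------------------------------

    def index(self, variable: str) -> int:
        try:
            return self.variables.index(variable)
        except ValueError:
            raise KeyError(f"unknown variable {variable!r}") from None

    def levels(self, variable: str) -> range:
        lo, hi = self.domains[variable]
        return range(lo, hi + 1)

    def n_states(self) -> int:
        n = 1
        for v in self.variables:
            lo, hi = self.domains[v]
            n *= hi - lo + 1
        return n

    def states(self) -> Iterator[State]:
        """All states in lexicographic order of the variable tuple."""
        yield from itertools.product(*(self.levels(v) for v in self.variables))

    def validate_state(self, state: Sequence[int]) -> State:
        if len(state) != len(self.variables):
            raise ValueError(
                f"state has {len(state)} components, expected {len(self.variables)}"
            )
        for v, x in zip(self.variables, state):
            lo, hi = self.domains[v]
            if not (lo <= x <= hi):
                raise ValueError(f"value {x} of {v!r} outside domain [{lo}, {hi}]")
        return tuple(state)

    def total_space(self) -> "Space":
        return Space({v: tuple(self.levels(v)) for v in self.variables})

    def function_table(self, variable: str) -> dict[State, int]:
        """Fully enumerated lookup table of one update function."""
        f = self.functions[variable]
        return {x: f(x) for x in self.states()}


@dataclass(frozen=True)
class Space:
    """Per-variable non-empty value subsets, read as a set of states."""

    levels: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        norm = {v: tuple(sorted(set(vals))) for v, vals in self.levels.items()}
        for v, vals in norm.items():
            if not vals:
                raise ValueError(f"empty level set for {v!r}")
        object.__setattr__(self, "levels", norm)

    def __getitem__(self, variable: str) -> tuple[int, ...]:
        return self.levels[variable]

    def __contains__(self, state: Sequence[int]) -> bool:
        return all(x in self.levels[v] for v, x in zip(self.levels, state))

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.levels.items())))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Space) and dict(self.levels) == dict(other.levels)

    def n_states(self) -> int:
        n = 1
        for vals in self.levels.values():
            n *= len(vals)
        return n

    def states(self, order: Sequence[str]) -> Iterator[State]:
        yield from itertools.product(*(self.levels[v] for v in order))

    def is_singleton(self) -> bool:
        return all(len(vals) == 1 for vals in self.levels.values())

    def sort_key(self) -> tuple:
        return tuple(self.levels[v] for v in self.levels)

    def __str__(self) -> str:
        return " ".join(
            f"{v}:{{{','.join(map(str, vals))}}}" for v, vals in self.levels.items()
        )


def validate_space(mvn: MVN, space: Space) -> None:
    if set(space.levels) != set(mvn.variables):
        raise ValueError("space variables do not match the network")
    for v, vals in space.levels.items():
        lo, hi = mvn.domains[v]
        for x in vals:
            if not (lo <= x <= hi):
                raise ValueError(f"level {x} of {v!r} outside domain [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# elementary dynamics
# ---------------------------------------------------------------------------


def evaluate(mvn: MVN, variable: str, state: Sequence[int]) -> int:
    """Raw update-function value ``f_v(x)``."""
    mvn.index(variable)
    x = mvn.validate_state(state)
    y = mvn.functions[variable](x)
    lo, hi = mvn.domains[variable]
    if not (lo <= y <= hi):
        raise ValueError(
            f"update function of {variable!r} returned {y} outside [{lo}, {hi}]"
        )
    return y


def stepwise_target(
    mvn: MVN, variable: str, state: Sequence[int], semantics: Semantics
) -> int:
    """Target level of one stepwise update of ``variable`` in ``state``.

    General semantics returns ``f_v(x)`` itself; unitary semantics moves
    the current level one step toward it (``x_v + sign(f_v(x) - x_v)``).
    """
    y = evaluate(mvn, variable, state)
    if Semantics(semantics) is Semantics.GENERAL:
        return y
    xv = state[mvn.index(variable)]
    return xv + (y > xv) - (y < xv)


def is_trap_space(
    mvn: MVN,
    space: Space,
    semantics: Semantics,
    *,
    limit: int = DEFAULT_STATE_LIMIT,
) -> bool:
    """Exhaustively check that no stepwise update can leave ``space``."""
    validate_space(mvn, space)
    if space.n_states() > limit:
        raise CapacityError(f"space holds more than {limit} states")
    sets = {v: set(space[v]) for v in mvn.variables}
    for x in space.states(mvn.variables):
        for v in mvn.variables:
            if stepwise_target(mvn, v, x, semantics) not in sets[v]:
                return False
    return True


def is_subspace(a: Space, b: Space, *, strict: bool = False) -> bool:
    """Componentwise inclusion ``a(v) ⊆ b(v)``; ``strict`` adds ``a != b``."""
    if set(a.levels) != set(b.levels):
        raise ValueError("spaces range over different variables")
    sub = all(set(a[v]) <= set(b[v]) for v in a.levels)
    return sub and (a != b if strict else True)


def intersect_spaces(a: Space, b: Space) -> Space | None:
    """Componentwise intersection; ``None`` when any component is empty."""
    if set(a.levels) != set(b.levels):
        raise ValueError("spaces range over different variables")
    out = {}
    for v in a.levels:
        common = set(a[v]) & set(b[v])
        if not common:
            return None
        out[v] = tuple(sorted(common))
    return Space(out)


def apply_knockout(mvn: MVN, variable: str, level: int) -> MVN:
    """Pin ``variable`` to a constant ``level`` (all other functions kept)."""
    lo, hi = mvn.domains[variable]
    if not (lo <= level <= hi):
        raise ValueError(f"level {level} outside domain [{lo}, {hi}] of {variable!r}")
    functions = dict(mvn.functions)
    functions[variable] = lambda x, _k=level: _k
    return MVN(mvn.variables, dict(mvn.domains), functions)


# ---------------------------------------------------------------------------
# fixtures and generators
# ---------------------------------------------------------------------------


class _Table:
    """Picklable/printable lookup-table update function."""

    __slots__ = ("table",)

    def __init__(self, table: Mapping[State, int]):
        self.table = dict(table)

    def __call__(self, state: State) -> int:
        return self.table[tuple(state)]


def random_mvn(n_vars: int, max_level: int, seed: int) -> MVN:
    """Seeded random MVN with fully enumerated lookup-table functions.

    Each variable gets a domain ``[0, h]`` with ``h`` drawn uniformly from
    ``1..max_level`` and a table whose entries are drawn uniformly from
    that domain.  Deterministic for a fixed seed.
    """
    if n_vars < 1 or max_level < 1:
        raise ValueError("need n_vars >= 1 and max_level >= 1")
    rng = random.Random(seed)
    variables = tuple(f"v{i + 1}" for i in range(n_vars))
    domains = {v: (0, rng.randint(1, max_level)) for v in variables}
    states = list(
        itertools.product(*(range(domains[v][1] + 1) for v in variables))
    )
    functions = {}
    for v in variables:
        hi = domains[v][1]
        functions[v] = _Table({x: rng.randint(0, hi) for x in states})
    return MVN(variables, domains, functions)


def worked_example() -> MVN:
    """Two-variable worked example: ``K1 = [0,1]``, ``K2 = [0,1,2]``.

    ``f1`` is 1 only at state (1,1); ``f2`` maps (0,0) to 2, (0,2) to 0
    and everything else to 1.  Under general semantics this network has
    exactly six trap spaces (three minimal, two maximal) and three
    asynchronous attractors; under unitary semantics two minimal and
    three maximal trap spaces and two attractors.
    """
    variables = ("v1", "v2")
    domains = {"v1": (0, 1), "v2": (0, 2)}
    f1 = _Table({x: 1 if x == (1, 1) else 0
                 for x in itertools.product(range(2), range(3))})
    f2 = _Table({x: 2 if x == (0, 0) else (0 if x == (0, 2) else 1)
                 for x in itertools.product(range(2), range(3))})
    return MVN(variables, domains, {"v1": f1, "v2": f2})


# ---------------------------------------------------------------------------
# native plain-text fixture format
# ---------------------------------------------------------------------------
#
# Grammar (one statement per line, '#' starts a comment):
#
#   <name>: <lo>..<hi>             declare a variable and its domain
#   <name>(<t1>,<t2>,...) = <val>  one function-table row; the tuple is a
#                                  full state in declaration order
#   <name>(*) = <val>              constant-function shorthand
#
# Every variable needs either the constant shorthand or a complete table.

_DECL_RE = re.compile(r"^(\w+)\s*:\s*(-?\d+)\s*\.\.\s*(-?\d+)$")
_ROW_RE = re.compile(r"^(\w+)\s*\(\s*([^)]*)\s*\)\s*=\s*(-?\d+)$")


def parse_native(text: str) -> MVN:
    """Parse the plain-text fixture format (grammar documented above)."""
    variables: list[str] = []
    domains: dict[str, tuple[int, int]] = {}
    rows: dict[str, dict[State, int]] = {}
    constants: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _DECL_RE.match(line)
        if m:
            name, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
            if name in domains:
                raise ValueError(f"line {lineno}: duplicate variable {name!r}")
            if lo > hi:
                raise ValueError(f"line {lineno}: empty domain {lo}..{hi}")
            if hi - lo + 1 < 1:
                raise ValueError(f"line {lineno}: empty domain")
            variables.append(name)
            domains[name] = (lo, hi)
            continue
        m = _ROW_RE.match(line)
        if m:
            name, args, val = m.group(1), m.group(2).strip(), int(m.group(3))
            if name not in domains:
                raise ValueError(f"line {lineno}: unknown variable {name!r}")
            if args == "*":
                constants[name] = val
                continue
            state = tuple(int(a) for a in args.split(","))
            rows.setdefault(name, {})[state] = val
            continue
        raise ValueError(f"line {lineno}: cannot parse {raw!r}")

    functions: dict[str, Callable[[State], int]] = {}
    all_states = list(
        itertools.product(*(range(domains[v][0], domains[v][1] + 1)
                            for v in variables))
    )
    for v in variables:
        lo, hi = domains[v]
        if v in constants:
            c = constants[v]
            if not (lo <= c <= hi):
                raise ValueError(f"constant for {v!r} outside its domain")
            functions[v] = _Table({x: c for x in all_states})
        elif v in rows:
            table = rows[v]
            missing = [x for x in all_states if x not in table]
            if missing:
                raise ValueError(f"incomplete table for {v!r}: missing {missing[0]}")
            for x, y in table.items():
                if len(x) != len(variables):
                    raise ValueError(f"row arity mismatch for {v!r} at {x}")
                if not (lo <= y <= hi):
                    raise ValueError(f"table value {y} of {v!r} outside domain")
            functions[v] = _Table(table)
        else:
            raise ValueError(f"no function given for {v!r}")
    return MVN(tuple(variables), domains, functions)


def format_native(mvn: MVN) -> str:
    """Serialize an MVN (as full tables) into the native fixture format."""
    lines = []
    for v in mvn.variables:
        lo, hi = mvn.domains[v]
        lines.append(f"{v}: {lo}..{hi}")
    for v in mvn.variables:
        for x in mvn.states():
            lines.append(f"{v}({','.join(map(str, x))}) = {mvn.functions[v](x)}")
    return "\n".join(lines) + "\n"
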