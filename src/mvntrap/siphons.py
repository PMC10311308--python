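"""Trap-space enumeration through conflict-free Petri-net siphons.

A place set ``S`` is a *siphon* when every transition with a successor
in ``S`` also has a predecessor in ``S`` (once token-free it stays
token-free), and *conflict-free* when it omits at least one place of
every variable block.  Under the one-hot encoding, a space is a trap
space exactly when its mirror (the excluded places) is a conflict-free
siphon; subset-maximal conflict-free siphons decode to minimal trap
spaces and subset-minimal non-empty ones to maximal trap spaces.
Deadlocks (valid markings enabling no transition) decode to fixed
points.

Enumeration is phrased as an answer-set program (see :func:`build_asp`);
:func:`solve` drives an external ASP solver when one is importable or on
``PATH`` and otherwise falls back to the exact brute-force enumerator,
which is also the reference oracle.  Every answer is re-verified with
:func:`is_siphon` / :func:`is_conflict_free` before being reported.
"""

from __future__ import annotations

import itertools
import shutil
import subprocess
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .model import MVN, CapacityError, Space
from .petri import PetriNet, Place, Transition, enabled, marking_of_state, unmirror

__all__ = [
    "QueryMode",
    "SiphonQuery",
    "SiphonResult",
    "is_siphon",
    "is_conflict_free",
    "build_asp",
    "solve",
    "brute_force_siphons",
    "brute_force_deadlocks",
]

#: brute-force enumeration refuses nets with more places than this
DEFAULT_PLACE_BOUND = 20


class QueryMode(str, Enum):
    MAX_SIPHON = "max_siphon"  # -> minimal trap spaces
    MIN_SIPHON = "min_siphon"  # -> maximal trap spaces
    FIXED_DEADLOCK = "fixed_deadlock"  # -> fixed points via deadlocks
    FIXED_SIPHON = "fixed_siphon"  # -> fixed points via siphons


@dataclass(frozen=True)
class SiphonQuery:
    net: PetriNet
    mode: QueryMode
    limit: int = 0  # max solutions; 0 = all

    def __post_init__(self) -> None:
        if self.limit < 0:
            raise ValueError("limit must be >= 0")


@dataclass(frozen=True)
class SiphonResult:
    """Raw place sets plus their decoded spaces (or states for the
    fixed-point modes)."""

    place_sets: tuple
    spaces: tuple  # Spaces, or state tuples in fixed modes


# ---------------------------------------------------------------------------
# predicates
# ---------------------------------------------------------------------------


def is_siphon(net: PetriNet, S: Iterable[Place]) -> bool:
    """Classic siphon check: every transition with a successor in S has
    a predecessor in S (equivalently ``S ∩ pred(t) = ∅`` implies
    ``S ∩ succ(t) = ∅``), so a token-free S can never be refilled."""
    S = frozenset(S)
    if not S <= net.places:
        raise ValueError("foreign places in candidate siphon")
    return all(
        not (S & t.succ) or bool(S & t.pred) for t in net.transitions
    )


def is_conflict_free(net: PetriNet, S: Iterable[Place]) -> bool:
    """At least one place of every variable block lies outside S."""
    S = frozenset(S)
    return all(
        any((v, i) not in S for i in levels) for v, levels in net.blocks
    )


# ---------------------------------------------------------------------------
# ASP program generation
# ---------------------------------------------------------------------------


def _atom(place: Place) -> str:
    return f'pl("{place[0]}",{place[1]})'


def _matom(place: Place) -> str:
    return f'm("{place[0]}",{place[1]})'


def build_asp(query: SiphonQuery) -> str:
    """Deterministic ASP-Core-2 text for the query.

    Siphon modes use one choice atom per place, per-transition siphon
    constraints, per-block conflict-freeness constraints, and domain
    heuristic directives for subset-optimal enumeration.  The deadlock
    mode instead uses one-hot marking atoms with one constraint per
    transition (some predecessor unmarked).
    """
    net = query.net
    ordered_places = [
        (v, i) for v, levels in net.blocks for i in levels
    ]
    lines = [f"% mode: {query.mode.value}"]
    if query.mode is QueryMode.FIXED_DEADLOCK:
        for v, levels in net.blocks:
            choices = "; ".join(_matom((v, i)) for i in levels)
            lines.append(f"1 {{{choices}}} 1.")
        for t in net.transitions:
            body = ", ".join(_matom(p) for p in sorted(t.pred))
            lines.append(f":- {body}.")
        lines.append("#show m/2.")
        return "\n".join(lines) + "\n"

    for p in ordered_places:
        lines.append(f"{{{_atom(p)}}}.")
    # conflict-freeness: never all places of one block
    for v, levels in net.blocks:
        body = ", ".join(_atom((v, i)) for i in levels)
        lines.append(f":- {body}.")
    # siphon condition: a place of S among the successors forces some
    # place of S among the predecessors
    for t in net.transitions:
        preds = ", ".join(f"not {_atom(p)}" for p in sorted(t.pred))
        for p in sorted(t.succ):
            lines.append(f":- {_atom(p)}{', ' if preds else ''}{preds}.")
    if query.mode is QueryMode.MIN_SIPHON:
        # exclude the empty siphon (the total space is never maximal)
        lines.append(
            ":- " + ", ".join(f"not {_atom(p)}" for p in ordered_places) + "."
        )
        sign = "false"
    elif query.mode is QueryMode.FIXED_SIPHON:
        # complement is a single state: |K_v| - 1 places of each block
        for v, levels in net.blocks:
            choices = "; ".join(_atom((v, i)) for i in levels)
            k = len(levels) - 1
            lines.append(f"{k} {{{choices}}} {k}.")
        sign = "false"
    else:
        sign = "true"
    # domain heuristic: prefer each place atom true (resp. false), and
    # enumerate subset-optimal models via the solver's domRec mode
    for p in ordered_places:
        lines.append(f"#heuristic {_atom(p)}. [1,{sign}]")
    lines.append("#show pl/2.")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# brute-force reference enumeration
# ---------------------------------------------------------------------------


def _subset_optima(sets: list[frozenset], *, maximal: bool) -> list[frozenset]:
    out = []
    for s in sets:
        if maximal:
            dominated = any(s < o for o in sets)
        else:
            dominated = any(o < s for o in sets)
        if not dominated:
            out.append(s)
    return out


def _decode(place_sets: Sequence[frozenset], mvn: MVN) -> tuple:
    spaces = [unmirror(s, mvn) for s in place_sets]
    order = sorted(range(len(spaces)), key=lambda i: spaces[i].sort_key())
    return (
        tuple(place_sets[i] for i in order),
        tuple(spaces[i] for i in order),
    )


def _net_mvn_stub(net: PetriNet) -> MVN:
    """A function-less carrier of the net's variables/domains, good
    enough for unmirror (which only reads variables and levels)."""
    variables = net.variables
    domains = {v: (min(lv), max(lv)) for v, lv in net.blocks}
    functions = {v: (lambda x: 0) for v in variables}
    return MVN(variables, domains, functions)


def brute_force_siphons(
    net: PetriNet,
    mode: QueryMode,
    *,
    mvn: MVN | None = None,
    bound: int = DEFAULT_PLACE_BOUND,
) -> SiphonResult:
    """Exact reference enumeration over all ``2^{|P|}`` place sets.

    Bitmask-based; refuses nets with more than ``bound`` places.
    """
    mode = QueryMode(mode)
    if mode is QueryMode.FIXED_DEADLOCK:
        raise ValueError("deadlock mode is handled by brute_force_deadlocks")
    places = sorted(net.places)
    if len(places) > bound:
        raise CapacityError(f"{len(places)} places exceed bound {bound}")
    pidx = {p: n for n, p in enumerate(places)}
    pred_masks = []
    succ_masks = []
    for t in net.transitions:
        pm = sm = 0
        for p in t.pred:
            pm |= 1 << pidx[p]
        for p in t.succ:
            sm |= 1 << pidx[p]
        pred_masks.append(pm)
        succ_masks.append(sm)
    block_masks = []
    for v, levels in net.blocks:
        bm = 0
        for i in levels:
            bm |= 1 << pidx[(v, i)]
        block_masks.append(bm)

    found: list[frozenset] = []
    for mask in range(1 << len(places)):
        if any((mask & bm) == bm for bm in block_masks):
            continue  # not conflict-free
        ok = True
        for pm, sm in zip(pred_masks, succ_masks):
            if (mask & sm) and not (mask & pm):
                ok = False
                break
        if ok:
            found.append(
                frozenset(p for p in places if mask & (1 << pidx[p]))
            )

    decode_mvn = mvn if mvn is not None else _net_mvn_stub(net)
    if mode is QueryMode.MAX_SIPHON:
        optima = _subset_optima(found, maximal=True)
        # the empty siphon survives only when it is the unique CF siphon,
        # in which case the total space is the single minimal trap space
        place_sets, spaces = _decode(optima, decode_mvn)
    elif mode is QueryMode.MIN_SIPHON:
        nonempty = [s for s in found if s]
        optima = _subset_optima(nonempty, maximal=False)
        place_sets, spaces = _decode(optima, decode_mvn)
    else:  # FIXED_SIPHON: complement is a single state
        singles = [
            s
            for s in found
            if all(
                sum((v, i) not in s for i in levels) == 1
                for v, levels in net.blocks
            )
        ]
        place_sets, spaces = _decode(singles, decode_mvn)
        spaces = tuple(
            tuple(sp[v][0] for v in net.variables) for sp in spaces
        )
    return SiphonResult(place_sets, spaces)


def brute_force_deadlocks(net: PetriNet, mvn: MVN) -> list[tuple]:
    """Valid markings enabling no transition, decoded as states."""
    out = []
    for x in mvn.states():
        m = marking_of_state(mvn, x)
        if not any(enabled(m, t) for t in net.transitions):
            out.append(x)
    return sorted(out)


# ---------------------------------------------------------------------------
# solver front end
# ---------------------------------------------------------------------------


class SolverUnavailableError(RuntimeError):
    pass


def _clingo_answer_sets(program: str, mode: QueryMode, limit: int) -> list[set] | None:
    """Run an external ASP solver if one is reachable; None otherwise.

    Subset-optimal enumeration relies on the solver's domain-heuristic
    recording mode; answers come back as lists of ``pl``/``m`` atoms.
    """
    args = ["--models", str(limit)]
    if mode is not QueryMode.FIXED_DEADLOCK:
        args += ["--heuristic=Domain", "--enum-mode=domRec", "--dom-mod=neg,opt"]
    try:  # in-process bindings first
        import clingo  # type: ignore

        ctl = clingo.Control(args)
        ctl.add("base", [], program)
        ctl.ground([("base", [])])
        answers: list[set] = []
        with ctl.solve(yield_=True) as handle:  # pragma: no cover
            for model in handle:
                answers.append(
                    {str(a) for a in model.symbols(shown=True)}
                )
        return answers
    except ImportError:
        pass
    exe = shutil.which("clingo")
    if exe is None:
        return None
    proc = subprocess.run(  # pragma: no cover
        [exe, *args, "--verbose=0"],
        input=program,
        capture_output=True,
        text=True,
    )
    if proc.returncode not in (10, 20, 30):  # pragma: no cover
        raise RuntimeError(f"ASP solver failed: {proc.stderr}")
    answers = []  # pragma: no cover
    for line in proc.stdout.splitlines():  # pragma: no cover
        line = line.strip()
        if line.startswith(("pl(", "m(")):
            answers.append(set(line.split()))
    return answers  # pragma: no cover


def _parse_atom(atom: str) -> Place:
    inner = atom[atom.index("(") + 1 : atom.rindex(")")]
    name, level = inner.rsplit(",", 1)
    return name.strip('"'), int(level)


def solve(
    query: SiphonQuery,
    *,
    mvn: MVN | None = None,
    bound: int = DEFAULT_PLACE_BOUND,
) -> SiphonResult:
    """Enumerate the query's answers and decode them.

    Prefers an external ASP solver when available, otherwise falls back
    to brute force (refusing nets above ``bound`` places).  Every answer
    is re-verified against the siphon and conflict-freeness predicates;
    results are canonically sorted and truncated to ``query.limit``.
    """
    net = query.net
    mode = query.mode
    program = build_asp(query)
    answers = _clingo_answer_sets(program, mode, query.limit)
    if answers is None:
        if len(net.places) > bound and mode is not QueryMode.FIXED_DEADLOCK:
            raise SolverUnavailableError(
                f"no ASP solver on the execution path and the net has "
                f"{len(net.places)} > {bound} places; install clingo or "
                f"raise the brute-force bound"
            )
        if mode is QueryMode.FIXED_DEADLOCK:
            decode_mvn = mvn if mvn is not None else _net_mvn_stub(net)
            states = brute_force_deadlocks(net, decode_mvn)
            place_sets = tuple(
                frozenset(marking_of_state(decode_mvn, x)) for x in states
            )
            result = SiphonResult(place_sets, tuple(states))
        else:
            result = brute_force_siphons(net, mode, mvn=mvn, bound=bound)
    else:  # pragma: no cover - exercised only when a solver is installed
        decode_mvn = mvn if mvn is not None else _net_mvn_stub(net)
        place_sets = [frozenset(_parse_atom(a) for a in ans) for ans in answers]
        if mode is QueryMode.FIXED_DEADLOCK:
            states = sorted(
                state_tuple
                for state_tuple in (
                    tuple(dict(s)[v] for v in net.variables) for s in place_sets
                )
            )
            result = SiphonResult(tuple(place_sets), tuple(states))
        else:
            ps, spaces = _decode(place_sets, decode_mvn)
            result = SiphonResult(ps, spaces)

    # post-hoc verification (defence against encoding/solver bugs)
    if mode in (QueryMode.MAX_SIPHON, QueryMode.MIN_SIPHON, QueryMode.FIXED_SIPHON):
        for s in result.place_sets:
            if not (is_siphon(net, s) and is_conflict_free(net, s)):
                raise RuntimeError(f"reported answer fails verification: {s}")
    if query.limit:
        result = SiphonResult(
            result.place_sets[: query.limit], result.spaces[: query.limit]
        )
    return result
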