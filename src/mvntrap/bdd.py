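"""A minimal reduced ordered binary decision diagram (ROBDD) engine.

Hash-consed nodes over a fixed variable order, with the usual ITE-based
boolean operations, restriction, support and satisfying-path
enumeration.  Deliberately small: the package only needs conjunction /
disjunction / negation over a few dozen indicator variables, plus path
enumeration to turn conditions into Petri-net transitions.

Node ids: 0 is FALSE, 1 is TRUE; internal nodes are integers >= 2.
"""

from __future__ import annotations

from typing import Iterator

__all__ = ["BDD", "FALSE", "TRUE"]

FALSE = 0
TRUE = 1


class BDD:
    """A manager for ROBDDs over ``num_vars`` ordered variables.

    Variable indices 0..num_vars-1 are ordered by index: smaller index
    closer to the root.
    """

    def __init__(self, num_vars: int):
        self.num_vars = num_vars
        # node id -> (var, low, high); terminals have no entry
        self._nodes: dict[int, tuple[int, int, int]] = {}
        self._unique: dict[tuple[int, int, int], int] = {}
        self._ite_cache: dict[tuple[int, int, int], int] = {}
        self._next_id = 2

    # -- construction ----------------------------------------------------

    def _mk(self, var: int, low: int, high: int) -> int:
        if low == high:
            return low
        key = (var, low, high)
        node = self._unique.get(key)
        if node is None:
            node = self._next_id
            self._next_id += 1
            self._unique[key] = node
            self._nodes[node] = key
        return node

    def var(self, index: int) -> int:
        if not (0 <= index < self.num_vars):
            raise IndexError(f"variable index {index} out of range")
        return self._mk(index, FALSE, TRUE)

    def _top_var(self, *nodes: int) -> int:
        return min(self._nodes[u][0] for u in nodes if u > TRUE)

    def _cofactors(self, u: int, var: int) -> tuple[int, int]:
        if u <= TRUE:
            return u, u
        v, low, high = self._nodes[u]
        if v == var:
            return low, high
        return u, u

    def ite(self, f: int, g: int, h: int) -> int:
        """If-then-else: ``(f ∧ g) ∨ (¬f ∧ h)``."""
        if f == TRUE:
            return g
        if f == FALSE:
            return h
        if g == h:
            return g
        key = (f, g, h)
        cached = self._ite_cache.get(key)
        if cached is not None:
            return cached
        var = self._top_var(f, g, h)
        f0, f1 = self._cofactors(f, var)
        g0, g1 = self._cofactors(g, var)
        h0, h1 = self._cofactors(h, var)
        out = self._mk(var, self.ite(f0, g0, h0), self.ite(f1, g1, h1))
        self._ite_cache[key] = out
        return out

    def apply_and(self, f: int, g: int) -> int:
        return self.ite(f, g, FALSE)

    def apply_or(self, f: int, g: int) -> int:
        return self.ite(f, TRUE, g)

    def apply_not(self, f: int) -> int:
        return self.ite(f, FALSE, TRUE)

    def conj(self, nodes) -> int:
        out = TRUE
        for u in nodes:
            out = self.apply_and(out, u)
        return out

    def disj(self, nodes) -> int:
        out = FALSE
        for u in nodes:
            out = self.apply_or(out, u)
        return out

    def cube(self, literals: dict[int, bool]) -> int:
        """Conjunction of literals given as ``{var_index: polarity}``."""
        out = TRUE
        for idx in sorted(literals, reverse=True):
            v = self.var(idx)
            lit = v if literals[idx] else self.apply_not(v)
            out = self.apply_and(lit, out)
        return out

    # -- queries ---------------------------------------------------------

    def restrict(self, u: int, var: int, value: bool) -> int:
        if u <= TRUE:
            return u
        v, low, high = self._nodes[u]
        if v > var:
            return u
        if v == var:
            return high if value else low
        return self._mk(v, self.restrict(low, var, value),
                        self.restrict(high, var, value))

    def evaluate(self, u: int, assignment) -> bool:
        """Evaluate under a full assignment (indexable by variable)."""
        while u > TRUE:
            var, low, high = self._nodes[u]
            u = high if assignment[var] else low
        return u == TRUE

    def support(self, u: int) -> frozenset[int]:
        seen: set[int] = set()
        out: set[int] = set()
        stack = [u]
        while stack:
            w = stack.pop()
            if w <= TRUE or w in seen:
                continue
            seen.add(w)
            var, low, high = self._nodes[w]
            out.add(var)
            stack.extend((low, high))
        return frozenset(out)

    def sat_paths(self, u: int) -> Iterator[dict[int, bool]]:
        """Partial assignments labelling each root-to-TRUE path.

        Paths are pairwise disjoint as assignment regions and jointly
        cover the satisfying set; variables absent from a path are
        unconstrained on it.
        """
        path: dict[int, bool] = {}

        def walk(w: int) -> Iterator[dict[int, bool]]:
            if w == FALSE:
                return
            if w == TRUE:
                yield dict(path)
                return
            var, low, high = self._nodes[w]
            path[var] = False
            yield from walk(low)
            path[var] = True
            yield from walk(high)
            del path[var]

        yield from walk(u)
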