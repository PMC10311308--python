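"""Test-harness Van Ham booleanization.

A variable with domain [0, h] expands into h ordered boolean variables;
level k is encoded as the first k bits true.  Bit vectors that encode no
level (a gap before a set bit) are completed by decoding through the
count of set bits, which preserves minimal trap spaces of unitary
networks — the cross-validation route for the siphon pipeline.
"""

from __future__ import annotations

from mvntrap.model import MVN, Space


def van_ham(mvn: MVN) -> tuple[MVN, list[tuple[str, str, int]]]:
    """Booleanize a unitary MVN; returns the boolean network and the
    list of (bit name, source variable, threshold j)."""
    bits: list[tuple[str, str, int]] = []
    for v in mvn.variables:
        lo, h = mvn.domains[v]
        assert lo == 0, "Van Ham expansion assumes 0-based domains"
        for j in range(1, h + 1):
            bits.append((f"{v}__{j}", v, j))
    bit_names = tuple(b[0] for b in bits)
    positions = {
        v: [i for i, (_, vv, _j) in enumerate(bits) if vv == v]
        for v in mvn.variables
    }
    var_index = {v: i for i, v in enumerate(mvn.variables)}

    def decode(bstate) -> tuple:
        return tuple(
            sum(bstate[i] for i in positions[v]) for v in mvn.variables
        )

    def make_bit_function(v: str, j: int):
        def f(bstate) -> int:
            x = decode(bstate)
            y = mvn.functions[v](x)
            xv = x[var_index[v]]
            target = xv + (y > xv) - (y < xv)  # unitary step
            return 1 if target >= j else 0

        return f

    functions = {name: make_bit_function(v, j) for name, v, j in bits}
    domains = {name: (0, 1) for name in bit_names}
    return MVN(bit_names, domains, functions), bits


def decode_space(bspace: Space, mvn: MVN, bits) -> Space | None:
    """Map a boolean space back to a multi-valued space; ``None`` when
    it contains no validly encoded state for some variable."""
    levels = {}
    for v in mvn.variables:
        _, h = mvn.domains[v]
        keep = []
        for k in range(h + 1):
            if all(
                (1 if j <= k else 0) in bspace[name]
                for name, vv, j in bits
                if vv == v
            ):
                keep.append(k)
        if not keep:
            return None
        levels[v] = tuple(keep)
    return Space(levels)
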