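"""High-level pipeline: MVN -> condition series -> Petri net -> siphon
query -> decoded trap spaces / fixed points."""

from __future__ import annotations

from typing import Mapping

from .model import MVN, Semantics, Space
from .petri import EncodingConfig, PetriNet, encode
from .series import BddSeries, series_from_table
from .siphons import QueryMode, SiphonQuery, solve

__all__ = [
    "encode_mvn",
    "minimal_trap_spaces",
    "maximal_trap_spaces",
    "fixed_points",
]


def encode_mvn(
    mvn: MVN,
    semantics: Semantics,
    config: EncodingConfig = EncodingConfig(),
    series: Mapping[str, BddSeries] | None = None,
) -> PetriNet:
    """Build the one-safe Petri net of an MVN (series from full tables
    unless supplied, e.g. by the SBML-qual term translation)."""
    if series is None:
        series = {v: series_from_table(mvn, v) for v in mvn.variables}
    return encode(mvn, series, semantics, config)


def minimal_trap_spaces(
    mvn: MVN,
    semantics: Semantics,
    *,
    limit: int = 0,
    config: EncodingConfig = EncodingConfig(),
    net: PetriNet | None = None,
) -> list[Space]:
    """Minimal trap spaces via subset-maximal conflict-free siphons."""
    if net is None:
        net = encode_mvn(mvn, semantics, config)
    result = solve(SiphonQuery(net, QueryMode.MAX_SIPHON, limit), mvn=mvn)
    return list(result.spaces)


def maximal_trap_spaces(
    mvn: MVN,
    semantics: Semantics,
    *,
    limit: int = 0,
    config: EncodingConfig = EncodingConfig(),
    net: PetriNet | None = None,
) -> list[Space]:
    """Maximal proper trap spaces via subset-minimal non-empty
    conflict-free siphons."""
    if net is None:
        net = encode_mvn(mvn, semantics, config)
    result = solve(SiphonQuery(net, QueryMode.MIN_SIPHON, limit), mvn=mvn)
    return list(result.spaces)


def fixed_points(
    mvn: MVN,
    semantics: Semantics = Semantics.GENERAL,
    *,
    limit: int = 0,
    config: EncodingConfig = EncodingConfig(),
    net: PetriNet | None = None,
    via: str = "deadlock",
) -> list[tuple]:
    """Fixed points, via Petri-net deadlocks (default) or via siphons
    whose complement is a single state.

    Fixed points do not depend on the semantics (a state is fixed under
    the general update iff it is fixed under the unitary one), but the
    net of either semantics may be passed in.
    """
    if via not in {"deadlock", "siphon"}:
        raise ValueError(f"unknown fixed-point route {via!r}")
    if net is None:
        net = encode_mvn(mvn, semantics, config)
    mode = QueryMode.FIXED_DEADLOCK if via == "deadlock" else QueryMode.FIXED_SIPHON
    result = solve(SiphonQuery(net, mode, limit), mvn=mvn)
    return list(result.spaces)
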