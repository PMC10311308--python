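# Methods

## Model and semantics

An MVN is `(V, K, F)` with integer-interval domains and total update
functions `f_v` from full states into `K_v`. Domains are contiguous
inclusive intervals `[lo, hi]`; sparse domains are rejected at parse time.
Spaces, by contrast, store arbitrary non-empty *sorted value sets* per
variable, because under the general semantics trap spaces can be
non-contiguous (the worked example's `{0}×{0,2}` is one).

The stepwise function `f̂_v` realizes the chosen semantics: the general mode
returns `f_v(x)` unchanged; the unitary mode returns
`x_v + sign(f_v(x) − x_v)`, so a variable drifts one level per step toward
its target. On all-boolean domains the two modes coincide. A trap space is a
space closed under `f̂` for every contained state and every variable; this
is checked exhaustively (with a configurable state-count guard, default
10⁶) in the oracle, and symbolically via siphons in the engine.

## Exhaustive oracle

The oracle enumerates every candidate space (all products of non-empty
per-variable subsets, in a fixed lexicographic order) and filters with the
definition directly; minimal / maximal / fixed selections are computed by
pairwise subset comparison on the surviving trap spaces. Maximality is
relative to *proper* trap spaces: the total space is always a trap space
and is excluded from the comparison, matching the definition.

State-transition graphs are built for both concurrency modes. Asynchronous
edges change exactly one variable to its stepwise target; states with no
enabled change receive an explicit self-loop so that bottom-SCC detection
(`networkx` strongly connected components) treats fixed points uniformly.
Attractors are the bottom SCCs. The asynchronous graph is the oracle
default: trap spaces are concurrency-independent anyway, and the worked
example's two-state cyclic attractor arises under it.

## Symbolic function representation

Each update function is stored as a series of conditions, one per attainable
output level, over one-hot boolean indicators `p_{v=i}` (one per level of
each variable). Conditions are reduced ordered BDDs from a small in-house
hash-consed ITE engine; the package needs only conjunction / disjunction /
negation, restriction, support and satisfying-path enumeration over a few
dozen indicators, so the engine stays deliberately minimal.

Validity convention: only assignments with exactly one indicator true per
variable matter; everything else is a don't-care. Conditions built from
tables are disjunctions of positive-literal cubes over the function's
*relevant* variables (those whose level can change the output, detected
from the table), which keeps constants at the true terminal and contexts
small. Conditions built from SBML-qual term formulas map comparisons to
indicator disjunctions and connectives directly; entries whose condition
covers no valid state (a hazard of negation and of the unitary transform)
are pruned against the exactly-one-per-block constraint. Partition checking
(pairwise disjoint, jointly exhaustive) is done symbolically restricted to
valid states.

The unitary transform redistributes condition mass: the part of the
level-`o` condition where the target variable sits at level `l` moves to
output `l + sign(o − l)`. The general transform is the identity.

## Petri-net encoding

Places are all `(variable, level)` pairs; a valid marking holds one token
per variable. For every variable `v`, source level `l` and target level
`k ≠ l` of `f̂_v`, each satisfying path of `p_{v=l} ∧ B̂_k` becomes
transitions: path variables constrained positively pin one context level;
variables constrained only negatively are expanded into every level
consistent with the path (read arcs can only test token presence);
variables absent from the path contribute no arcs. Paths covering only
invalid assignments (two indicators of one block forced true, or no level
left) are dropped. Context places are borrowed and returned (they appear in
both `pred` and `succ`), and self-moves are never emitted. The firing graph
over valid markings then equals the asynchronous state-transition graph
minus self-loops — the central correctness property, tested against the
oracle on every random network in the suite.

Because the number of satisfying paths depends on the indicator order, the
encoder tries a configurable number of seeded random block orders per
function (default 5, seed 0) and keeps the order producing the fewest
transitions; "most compact" is interpreted as fewest transitions, ties
broken by first-found, and the search is deterministic for a fixed seed.

## Siphon characterization and enumeration

The mirror of a space is the set of places it excludes; it is conflict-free
by construction (spaces are non-empty per variable). A space is a trap
space iff its mirror is a conflict-free siphon, where *siphon* is the
classic direction: every transition with a successor in `S` also has a
predecessor in `S`, so a token-free `S` stays token-free. (The equivalent
formulation used throughout the code is `S ∩ pred(t) = ∅ ⇒ S ∩ succ(t) =
∅`.) Order reversal of the mirror then gives: subset-maximal conflict-free
siphons ⇔ minimal trap spaces; subset-minimal non-empty ones ⇔ maximal trap
spaces. The empty siphon corresponds to the total space: it is excluded
from the minimal-siphon (maximal-trap-space) output, and reported as the
unique minimal trap space exactly when no non-empty conflict-free siphon
exists.

Fixed points travel two routes: siphons whose complement is a single state,
and deadlocks (valid markings enabling no transition). Both are implemented
and must agree; the suite checks this on every random network.

Queries are emitted as deterministic ASP-Core-2 text (choice atom per
place, per-transition siphon constraints, per-block conflict-freeness,
domain-heuristic directives for subset-optimal enumeration; the deadlock
query instead uses one-hot marking atoms with one constraint per
transition). `solve()` drives an ASP solver when one is importable or on
`PATH`; otherwise an exact bitmask brute-force enumerator over all `2^|P|`
place sets answers the query (refusing nets above a configurable place
bound, default 20). Every reported answer — from either route — is
re-verified against the siphon and conflict-freeness predicates before
being returned, and all outputs are canonically sorted so runs are
reproducible regardless of enumeration order.

## Format handling

*SBML-qual*: species become variables with domain `[0, maxLevel]`; function
terms are kept in order with first-listed-wins overlap resolution and a
default level for uncovered inputs; species without transitions are inputs
(identity update), or constants at `initialLevel` when flagged constant.
Export writes one function term per series entry (the lowest-level entry
serves as the default term), rendering each condition as a disjunction over
BDD paths of per-variable level-equality disjunctions; round trips are
fixed points at function-table level, which is the contract the tests
enforce (layout and annotations are not preserved).

*BMA*: JSON and XML layouts; target functions over `+ − · /`, `avg`,
`min`, `max`, `ceil`, `floor` with `var(id)`/`var(name)` references,
evaluated in exact rational arithmetic over the fully enumerated input
table and re-encoded as condition series. Inputs are rescaled into the
target's range before use. Conventions chosen where the format leaves
slack, each isolated behind one function: rounding is half-up
(`⌊x + 1/2⌋`, applied to normalization and to the final result, which is
then clamped into the target domain); a missing formula gets the default
target "average of activators minus average of inhibitors", an empty side
contributing zero; division by a syntactic zero constant is rejected at
parse time, while a runtime zero divisor clamps to the domain minimum with
a warning. The operator set is the documented, extensible subset above.
All levels are 0-based in both formats.

*Native format*: one `name: lo..hi` line per variable, then full
function-table rows `name(t1,...,tn) = value` (the tuple is a full state in
declaration order) or the constant shorthand `name(*) = value`; `#` starts
a comment. Incomplete tables are rejected.

## Synthetic data

`random_mvn(n_vars, max_level, seed)` draws each variable's domain top
uniformly from `1..max_level` and fills complete lookup tables uniformly
from the target domain — the bluntest possible function class, chosen so
the correctness checks sweep function space without bias. The test family
uses up to 3 variables and domain sizes up to 4 (21–3375 candidate spaces
per network, at most 64 states), which keeps exhaustive verification of
every candidate space tractable; 200 seeded networks are checked in the
suite and 100 in the acceptance script, each under both semantics. What
passing shows: the symbolic pipeline is equivalent to the definition on
this space of small dense networks. What it does not show: performance or
behaviour on large sparse biological models, whose update functions have
low arity and whose nets this enumeration-based validation cannot reach.

## Cross-validation via booleanization

As an independent route, the test harness expands unitary networks with the
ordered-threshold (Van Ham) encoding — a variable with domain `[0, h]`
becomes `h` boolean threshold bits, level `k` encoded as the first `k` bits
true — completing the update on invalidly encoded bit vectors by decoding
through the count of set bits. Minimal trap spaces of the boolean expansion,
mapped back (boolean spaces decoding to no valid level set are dropped),
must equal the directly computed unitary minimal trap spaces; this holds on
every network of the seeded family. The correspondence is specific to
*minimal* trap spaces of *unitary* networks and is used only as a
cross-check, never as the computation path.

## Intervention screening

`screen_interventions` pins candidate variables to constant levels,
recomputes minimal trap spaces of the pinned model, and reports each
readout's admissible interval (union range over all minimal trap spaces).
The reliability and opportunity scores are explicitly heuristic stand-ins:
worst-case and best-case level of the primary readout over all states of
all minimal trap spaces. Both derive from trap spaces, so they are
independent of update concurrency. Reports sort by the average of the two
scores, descending; an optional `readout <= bound` filter drops candidates
whose best case exceeds the bound.

## Known limitations

* Enumeration-heavy steps (tables, candidate spaces, brute-force siphons)
  are guarded by capacity limits rather than scalable algorithms; the
  package targets desk-scale models and exact verification, not
  benchmark-scale performance.
* Subset-optimal ASP enumeration is generated but exercised only when a
  solver is installed; the brute-force route bounds net size instead.
* Attractor detection is exhaustive (full STG); no symbolic attractor
  computation is attempted.
* SBML round trips preserve function tables, not layout, annotations or
  GINsim extensions.
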