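# mvntrap

Trap spaces of **multi-valued logical networks** (MVNs), computed through a
one-safe Petri-net encoding and conflict-free siphon enumeration.

## The problem

Logical models of gene-regulatory and signalling networks assign each species
a small integer activity level. An MVN is a triple `(V, K, F)`: variables
`v1..vn`, integer-interval domains `K_v = [lo, hi]`, and update functions
`f_v : K_1 × … × K_n → K_v`. Two stepwise semantics are supported:

* **general** — a variable jumps directly to `f_v(x)`;
* **unitary** — it moves one level at a time: `x_v + sign(f_v(x) − x_v)`.

A **space** `m` assigns each variable a non-empty subset of its domain and is
read as the set of states it contains. A **trap space** is a space no
stepwise update can leave — a property independent of whether variables
update synchronously or asynchronously, which makes minimal trap spaces
robust approximations of attractors (each minimal trap space contains at
least one attractor, and distinct minimal trap spaces are disjoint), while
maximal trap spaces underpin succession-diagram analyses.

## The method

The network is encoded as a one-safe Petri net with one place `p_{v=i}` per
level of each variable; a valid marking holds exactly one token per variable
and encodes a state. Update functions are represented as series of BDD
conditions over the one-hot indicators (one condition per attainable output
level, forming a partition of the state space); enumerating the satisfying
partial valuations of `p_{v=l} ∧ B̂_k` yields the net's transitions, and the
firing graph over valid markings reproduces the asynchronous dynamics
exactly.

A space `m` is a trap space **iff** its *mirror* (the set of excluded places)
is a **conflict-free siphon** of this net — a place set that, once
token-free, can never be refilled, and that omits at least one place of every
variable. Consequently:

* subset-**maximal** conflict-free siphons ⇔ **minimal** trap spaces,
* subset-**minimal** non-empty conflict-free siphons ⇔ **maximal** trap spaces,
* deadlocks (valid markings enabling no transition) ⇔ **fixed points**.

Enumeration is phrased as a generated answer-set program; when no ASP solver
is present, an exact brute-force enumerator (which doubles as the test
oracle) handles small nets. An independent exhaustive oracle — explicit
candidate-space enumeration and state-transition-graph analysis — verifies
every pipeline stage on small networks.

Supported inputs: SBML-qual (XML), BMA (JSON or XML, with range-normalized
rational target functions), and a native plain-text table format. BMA models
can be converted to SBML-qual.

## Worked example

The library ships the two-variable network with `K1 = [0,1]`,
`K2 = [0,1,2]`, `f1(x) = 1` iff `x = (1,1)` else 0, and `f2` mapping
`(0,0) ↦ 2`, `(0,2) ↦ 0`, everything else to 1:

```python
from mvntrap import worked_example, Semantics, minimal_trap_spaces, fixed_points

mvn = worked_example()
for m in minimal_trap_spaces(mvn, Semantics.GENERAL):
    print(m)
print(fixed_points(mvn))
```

prints

```
v1:{0} v2:{0,2}
v1:{0} v2:{1}
v1:{1} v2:{1}
[(0, 1), (1, 1)]
```

i.e. three minimal trap spaces under the general semantics — two of them the
fixed points `(0,1)` and `(1,1)`, plus the oscillatory region
`{0}×{0,2}` — exactly the sets found by brute-force enumeration of all 21
candidate spaces (3 non-empty subsets of `K1` × 7 of `K2`). The same model has two maximal proper trap spaces
(general), and under the unitary semantics two minimal and three maximal
trap spaces.

The same is available from the shell:

```sh
mvntrap min model.sbml -s general          # minimal trap spaces, one per line
mvntrap max model.json -s unitary -m one   # one maximal trap space
mvntrap fix model.mvn --json               # fixed points, machine-readable
mvntrap convert model.json model.sbml      # BMA -> SBML-qual
mvntrap screen model.mvn --pin v1=0 --readout v2
```

`screen` applies candidate pins (knockouts), recomputes minimal trap spaces,
and reports each readout's admissible interval plus heuristic
reliability/opportunity scores (worst/best-case readout level over all
minimal trap spaces).

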