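import itertools

import pytest

from mvntrap.analysis import (
    encode_mvn,
    fixed_points,
    maximal_trap_spaces,
    minimal_trap_spaces,
)
from mvntrap.model import (
    Semantics,
    Space,
    intersect_spaces,
    is_trap_space,
    parse_native,
    random_mvn,
)
from mvntrap.oracle import enumerate_trap_spaces
from mvntrap.petri import EncodingConfig, mirror
from mvntrap.siphons import (
    QueryMode,
    SiphonQuery,
    brute_force_deadlocks,
    brute_force_siphons,
    build_asp,
    is_conflict_free,
    is_siphon,
    solve,
)

from conftest import space
from vanham import decode_space, van_ham

CFG = EncodingConfig(ordering_trials=1)


class TestSiphonPredicates:
    def test_empty_and_full_sets_are_siphons(self, example_nets):
        net = example_nets[Semantics.GENERAL]
        assert is_siphon(net, frozenset())
        assert is_siphon(net, net.places)

    def test_mirror_of_printed_trap_space_is_a_siphon(
        self, example, example_nets
    ):
        net = example_nets[Semantics.GENERAL]
        S = mirror(space(v1=(0,), v2=(0, 2)), example)
        assert is_siphon(net, S) and is_conflict_free(net, S)

    def test_foreign_places_rejected(self, example_nets):
        with pytest.raises(ValueError):
            is_siphon(example_nets[Semantics.GENERAL], {("zz", 0)})

    def test_conflict_freeness(self, example_nets):
        net = example_nets[Semantics.GENERAL]
        assert is_conflict_free(net, frozenset())
        assert not is_conflict_free(
            net, {("v2", 0), ("v2", 1), ("v2", 2)}
        )

    def test_mirror_of_any_space_is_conflict_free(self, example, example_nets):
        net = example_nets[Semantics.GENERAL]
        for combo in itertools.product(
            [(0,), (1,), (0, 1)], [(0,), (1,), (0, 2), (0, 1, 2)]
        ):
            m = space(v1=combo[0], v2=combo[1])
            assert is_conflict_free(net, mirror(m, example))

    @pytest.mark.parametrize("semantics", list(Semantics))
    def test_trap_space_iff_mirror_is_conflict_free_siphon(self, semantics):
        """The central correspondence, checked on every candidate space
        of a seeded random family."""
        for seed in range(15):
            mvn = random_mvn(3, 3, seed + 50)
            net = encode_mvn(mvn, semantics, CFG)
            per_var = [
                [
                    c
                    for r in range(1, len(mvn.levels(v)) + 1)
                    for c in itertools.combinations(mvn.levels(v), r)
                ]
                for v in mvn.variables
            ]
            for combo in itertools.product(*per_var):
                m = Space(dict(zip(mvn.variables, combo)))
                S = mirror(m, mvn)
                assert is_trap_space(mvn, m, semantics) == (
                    is_siphon(net, S) and is_conflict_free(net, S)
                )


class TestBuildAsp:
    def test_program_is_deterministic(self, example_nets):
        q = SiphonQuery(example_nets[Semantics.GENERAL], QueryMode.MAX_SIPHON)
        assert build_asp(q) == build_asp(q)

    def test_one_choice_atom_per_place(self, example_nets):
        program = build_asp(
            SiphonQuery(example_nets[Semantics.GENERAL], QueryMode.MAX_SIPHON)
        )
        assert program.count("{pl(") == 5

    def test_transition_free_net_has_no_siphon_constraints(self):
        mvn = parse_native("a: 0..1\na(0) = 0\na(1) = 1\n")
        net = encode_mvn(mvn, Semantics.GENERAL, CFG)
        assert not net.transitions
        program = build_asp(SiphonQuery(net, QueryMode.MAX_SIPHON))
        # only the conflict-freeness constraint remains
        assert program.count(":-") == 1

    def test_deadlock_mode_uses_one_hot_marking_atoms(self, example_nets):
        program = build_asp(
            SiphonQuery(example_nets[Semantics.GENERAL], QueryMode.FIXED_DEADLOCK)
        )
        assert '1 {m("v1",0); m("v1",1)} 1.' in program


class TestSolveWorkedExample:
    def test_general_minimal_trap_spaces(self, example, example_nets):
        spaces = minimal_trap_spaces(
            example, Semantics.GENERAL, net=example_nets[Semantics.GENERAL]
        )
        assert set(spaces) == {
            space(v1=(0,), v2=(1,)),
            space(v1=(1,), v2=(1,)),
            space(v1=(0,), v2=(0, 2)),
        }

    def test_general_maximal_trap_spaces(self, example, example_nets):
        spaces = maximal_trap_spaces(
            example, Semantics.GENERAL, net=example_nets[Semantics.GENERAL]
        )
        assert set(spaces) == {
            space(v1=(0, 1), v2=(1,)),
            space(v1=(0,), v2=(0, 1, 2)),
        }

    def test_unitary_lists(self, example, example_nets):
        net = example_nets[Semantics.UNITARY]
        assert set(minimal_trap_spaces(example, Semantics.UNITARY, net=net)) == {
            space(v1=(0,), v2=(1,)),
            space(v1=(1,), v2=(1,)),
        }
        assert set(maximal_trap_spaces(example, Semantics.UNITARY, net=net)) == {
            space(v1=(0, 1), v2=(0, 1)),
            space(v1=(0, 1), v2=(1, 2)),
            space(v1=(0,), v2=(0, 1, 2)),
        }

    def test_limit_truncates_canonically_sorted_answers(self, example, example_nets):
        net = example_nets[Semantics.GENERAL]
        one = minimal_trap_spaces(example, Semantics.GENERAL, limit=1, net=net)
        full = minimal_trap_spaces(example, Semantics.GENERAL, net=net)
        assert len(one) == 1 and one[0] in full


class TestBruteForce:
    def test_brute_force_agrees_with_solve_in_every_mode(self, example, example_nets):
        net = example_nets[Semantics.GENERAL]
        for mode in (QueryMode.MAX_SIPHON, QueryMode.MIN_SIPHON,
                     QueryMode.FIXED_SIPHON):
            direct = brute_force_siphons(net, mode, mvn=example)
            solved = solve(SiphonQuery(net, mode), mvn=example)
            assert direct.place_sets == solved.place_sets
            assert direct.spaces == solved.spaces

    def test_transitionless_two_level_variable(self):
        mvn = parse_native("a: 0..1\na(0) = 0\na(1) = 1\n")
        net = encode_mvn(mvn, Semantics.GENERAL, CFG)
        result = brute_force_siphons(net, QueryMode.MAX_SIPHON, mvn=mvn)
        assert set(result.place_sets) == {
            frozenset({("a", 0)}), frozenset({("a", 1)}),
        }

    def test_empty_siphon_excluded_from_minimal_mode(self):
        mvn = parse_native("a: 0..1\na(0) = 0\na(1) = 1\n")
        net = encode_mvn(mvn, Semantics.GENERAL, CFG)
        result = brute_force_siphons(net, QueryMode.MIN_SIPHON, mvn=mvn)
        assert frozenset() not in result.place_sets

    def test_total_space_reported_when_no_proper_trap_space_exists(self):
        # boolean negation cycle: the only trap space is the full space
        mvn = parse_native("a: 0..1\na(0) = 1\na(1) = 0\n")
        net = encode_mvn(mvn, Semantics.GENERAL, CFG)
        spaces = minimal_trap_spaces(mvn, Semantics.GENERAL, net=net)
        assert spaces == [mvn.total_space()]

    def test_capacity_bound_respected(self, example_nets):
        from mvntrap.model import CapacityError

        with pytest.raises(CapacityError):
            brute_force_siphons(
                example_nets[Semantics.GENERAL], QueryMode.MAX_SIPHON, bound=3
            )


class TestFixedPoints:
    def test_worked_example_deadlocks_are_the_printed_fixed_points(
        self, example, example_nets
    ):
        assert brute_force_deadlocks(
            example_nets[Semantics.GENERAL], example
        ) == [(0, 1), (1, 1)]

    def test_identity_network_every_state_is_a_deadlock(self):
        mvn = parse_native("a: 0..2\na(0) = 0\na(1) = 1\na(2) = 2\n")
        net = encode_mvn(mvn, Semantics.GENERAL, CFG)
        assert brute_force_deadlocks(net, mvn) == [(0,), (1,), (2,)]

    def test_never_fixed_network_has_no_deadlock(self):
        mvn = parse_native("a: 0..1\na(0) = 1\na(1) = 0\n")
        net = encode_mvn(mvn, Semantics.GENERAL, CFG)
        assert brute_force_deadlocks(net, mvn) == []

    @pytest.mark.parametrize("semantics", list(Semantics))
    def test_deadlock_and_siphon_routes_agree(self, semantics):
        for seed in range(12):
            mvn = random_mvn(3, 3, seed + 200)
            net = encode_mvn(mvn, semantics, CFG)
            assert fixed_points(mvn, semantics, net=net) == fixed_points(
                mvn, semantics, net=net, via="siphon"
            )


class TestEngineVsOracle:
    @pytest.mark.parametrize("semantics", list(Semantics))
    def test_siphon_engine_matches_exhaustive_enumeration(self, semantics):
        for seed in range(15):
            mvn = random_mvn(3, 3, seed + 400)
            net = encode_mvn(mvn, semantics, CFG)
            assert minimal_trap_spaces(
                mvn, semantics, net=net
            ) == enumerate_trap_spaces(mvn, semantics, "minimal")
            assert maximal_trap_spaces(
                mvn, semantics, net=net
            ) == enumerate_trap_spaces(mvn, semantics, "maximal")

    def test_decoded_minimal_trap_spaces_pairwise_disjoint(self):
        for seed in range(10):
            mvn = random_mvn(3, 2, seed + 600)
            spaces = minimal_trap_spaces(mvn, Semantics.GENERAL, config=CFG)
            for a, b in itertools.combinations(spaces, 2):
                assert intersect_spaces(a, b) is None


class TestVanHamCrossCheck:
    def test_unitary_minimal_trap_spaces_survive_booleanization(self):
        """Minimal trap spaces of a unitary MVN equal those of its
        Van Ham boolean expansion mapped back."""
        for seed in range(12):
            mvn = random_mvn(2, 3, seed + 800)
            boolean, bits = van_ham(mvn)
            direct = set(enumerate_trap_spaces(mvn, Semantics.UNITARY, "minimal"))
            mapped = set()
            for bs in enumerate_trap_spaces(boolean, Semantics.GENERAL, "minimal"):
                decoded = decode_space(bs, mvn, bits)
                if decoded is not None:
                    mapped.add(decoded)
            assert direct == mapped
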