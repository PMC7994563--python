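"""Kernel unit and property tests: relations, λ/η/β, entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_function, random_relation
from eamem import (DiscreteFunction, GeometryError, ReductionPolicy, Relation,
                   abstraction, containment, entropy, function_to_relation,
                   reduction, relation_to_function, relax_from_percent,
                   relax_to_percent)
from oracle_ric import (o_abstraction, o_containment, o_entropy,
                        o_identity_reduction, o_triangular_support)


# --- construction ----------------------------------------------------------------

class TestRelation:
    def test_geometry_immutable_and_cells_readonly(self):
        r = Relation(3, 4)
        with pytest.raises(AttributeError):
            r.n_args = 5
        with pytest.raises(ValueError):
            r.cells[0, 0] = True

    def test_cells_must_be_boolean(self):
        with pytest.raises(ValueError):
            Relation(2, 2, [[1, 2], [0, 1]])

    def test_pairs_round_trip(self, rng):
        marks = [(0, 1), (2, 3), (2, 0)]
        r = Relation.from_pairs(3, 4, marks)
        assert r.pairs() == set(marks)

    @pytest.mark.parametrize("n_args,n_levels", [(0, 2), (2, 0), (-1, 3)])
    def test_positive_geometry_required(self, n_args, n_levels):
        with pytest.raises(ValueError):
            Relation(n_args, n_levels)


class TestDiscreteFunction:
    def test_at_most_one_level_per_argument(self):
        f = DiscreteFunction(2, 4)
        f[0] = 1
        f[0] = 3  # reassignment replaces, never accumulates
        assert f[0] == 3 and f[1] is None

    def test_level_out_of_range_rejected(self):
        f = DiscreteFunction(2, 4)
        with pytest.raises(ValueError):
            f[0] = 4

    def test_function_relation_conversion_examples(self):
        assert function_to_relation(DiscreteFunction(2, 2)).pairs() == set()
        f = DiscreteFunction(2, 2, {0: 1, 1: 0})
        assert function_to_relation(f).pairs() == {(0, 1), (1, 0)}

    @given(st.integers(1, 6), st.integers(1, 8), st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity_for_assigned_functions(self, n_args, n_levels, seed):
        rng = np.random.default_rng(seed)
        f = random_function(rng, n_args, n_levels, p_assigned=1.0)
        assert relation_to_function(function_to_relation(f)) == f


# --- abstraction -----------------------------------------------------------------

class TestAbstraction:
    def test_empty_relation_is_identity(self, rng):
        r = random_relation(rng, 4, 4)
        assert abstraction(r, Relation(4, 4)) == r

    def test_idempotent(self, rng):
        r = random_relation(rng, 4, 4)
        assert abstraction(r, r) == r

    def test_hand_enumerated_union(self):
        r_f = Relation.from_pairs(2, 2, [(0, 0)])
        r_a = Relation.from_pairs(2, 2, [(0, 1), (1, 0)])
        assert abstraction(r_f, r_a).pairs() == {(0, 0), (0, 1), (1, 0)}

    def test_inputs_unmodified(self, rng):
        r_f, r_a = random_relation(rng, 3, 3), random_relation(rng, 3, 3)
        before_f, before_a = r_f.pairs(), r_a.pairs()
        abstraction(r_f, r_a)
        assert r_f.pairs() == before_f and r_a.pairs() == before_a

    def test_geometry_mismatch(self):
        with pytest.raises(GeometryError):
            abstraction(Relation(2, 2), Relation(2, 3))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_commutative_associative(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (random_relation(rng, 4, 4) for _ in range(3))
        assert abstraction(a, b) == abstraction(b, a)
        assert abstraction(abstraction(a, b), c) == abstraction(a, abstraction(b, c))


# --- containment -----------------------------------------------------------------

class TestContainment:
    def test_union_contains_its_parts(self, rng):
        f = function_to_relation(random_function(rng, 5, 6))
        r = random_relation(rng, 5, 6)
        accept, failed = containment(f, abstraction(r, f))
        assert accept and failed == 0

    def test_full_relation_accepts_anything(self, rng):
        full = Relation(4, 4, np.ones((4, 4), bool))
        accept, failed = containment(random_relation(rng, 4, 4), full)
        assert accept and failed == 0

    def test_single_failing_column_and_relax(self):
        # r_f covers columns 0 and 2 fully, column 1 only at level 0
        r_f = Relation.from_pairs(3, 2, [(0, 0), (0, 1), (1, 0), (2, 0), (2, 1)])
        cue = function_to_relation(DiscreteFunction(3, 2, {0: 0, 1: 1, 2: 1}))
        assert containment(cue, r_f, relax=0) == (False, 1)
        assert containment(cue, r_f, relax=1) == (True, 1)

    def test_monotone_under_abstraction(self, rng):
        """An accepted cue stays accepted after the memory learns more."""
        for _ in range(25):
            r_a = function_to_relation(random_function(rng, 4, 4))
            r_f = abstraction(random_relation(rng, 4, 4), r_a)
            r_x = random_relation(rng, 4, 4)
            assert containment(r_a, abstraction(r_f, r_x))[0]

    def test_relax_percent_arithmetic(self):
        assert relax_to_percent(1, 64) == 1.6
        assert relax_to_percent(2, 64) == 3.1
        assert relax_to_percent(3, 64) == 4.7
        assert relax_from_percent(4.7, 64) == 3
        assert relax_from_percent(1.5, 64) == 0  # floored


# --- reduction -------------------------------------------------------------------

class TestReduction:
    def test_identity_when_contained(self, rng):
        f = random_function(rng, 5, 6, p_assigned=1.0)
        r = abstraction(random_relation(rng, 5, 6), function_to_relation(f))
        assert reduction(f, r, ReductionPolicy("identity")) == f

    def test_undefined_when_not_contained(self):
        f = DiscreteFunction(2, 2, {0: 1})
        r = Relation.from_pairs(2, 2, [(0, 0), (1, 0)])
        assert reduction(f, r) is None

    def test_singleton_column_forced_under_either_mode(self):
        r = Relation.from_pairs(1, 8, [(0, 5)])
        f = DiscreteFunction(1, 8, {0: 5})
        for mode in ("identity", "triangular"):
            out = reduction(f, r, ReductionPolicy(mode, seed=0))
            assert out[0] == 5

    def test_triangular_mode_peaks_at_cue(self):
        """10,000 seeded samples over marks {2,3,4}, cue 3: mode 3, support in the marks."""
        r = Relation.from_pairs(1, 8, [(0, 2), (0, 3), (0, 4)])
        f = DiscreteFunction(1, 8, {0: 3})
        policy = ReductionPolicy("triangular", seed=7)
        draws = np.array([reduction(f, r, policy)[0] for _ in range(10_000)])
        values, counts = np.unique(draws, return_counts=True)
        assert set(values) <= {2, 3, 4}
        assert values[np.argmax(counts)] == 3

    def test_output_contained_in_source(self, rng):
        for _ in range(25):
            f = random_function(rng, 5, 6)
            r = abstraction(random_relation(rng, 5, 6), function_to_relation(f))
            out = reduction(f, r, ReductionPolicy("triangular", seed=1))
            accept, failed = containment(function_to_relation(out), r)
            assert accept and failed == 0


# --- entropy ---------------------------------------------------------------------

class TestEntropy:
    def test_zero_for_functions_and_partial_functions(self, rng):
        assert entropy(function_to_relation(random_function(rng, 6, 8))) == 0.0
        assert entropy(Relation(6, 8)) == 0.0

    def test_hand_evaluated_examples(self):
        r = Relation(2, 4, np.array([[1, 1], [1, 1], [0, 1], [0, 1]], bool))
        assert entropy(r) == pytest.approx(1.5)  # (log2 2 + log2 4) / 2
        full = Relation(64, 32, np.ones((32, 64), bool))
        assert entropy(full) == pytest.approx(5.0)

    def test_bounds_and_monotone_under_abstraction(self, rng):
        for _ in range(25):
            a, b = random_relation(rng, 5, 8), random_relation(rng, 5, 8)
            e_a, e_ab = entropy(a), entropy(abstraction(a, b))
            assert 0.0 <= e_a <= e_ab <= np.log2(8) + 1e-12

    @given(st.integers(1, 6), st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_bounded_by_log2_min_n_functions_levels(self, n_funcs, seed):
        rng = np.random.default_rng(seed)
        r = Relation(4, 8)
        for _ in range(n_funcs):
            r = abstraction(r, function_to_relation(
                random_function(rng, 4, 8, p_assigned=1.0)))
        assert entropy(r) <= np.log2(min(n_funcs, 8)) + 1e-12


# --- oracle equivalence ----------------------------------------------------------

def test_oracle_equivalence(rng):
    """Table kernel vs. an explicit set-of-pairs implementation, 1,000 cases."""
    for _ in range(1_000):
        n_args = int(rng.integers(1, 7))
        n_levels = int(rng.integers(1, 9))
        r_f = random_relation(rng, n_args, n_levels, density=rng.uniform(0.1, 0.7))
        r_a = random_relation(rng, n_args, n_levels, density=rng.uniform(0.1, 0.7))
        pf, pa = r_f.pairs(), r_a.pairs()

        assert abstraction(r_f, r_a).pairs() == o_abstraction(pf, pa)

        relax = int(rng.integers(0, n_args + 1))
        assert containment(r_a, r_f, relax) == o_containment(pa, pf, n_args, relax)

        assert entropy(r_f) == pytest.approx(o_entropy(pf, n_args))

        f = random_function(rng, n_args, n_levels, p_assigned=0.7)
        assignment = dict(f.items())
        cue_rel = function_to_relation(f)
        accept, _ = containment(cue_rel, r_f)
        got = reduction(f, r_f, ReductionPolicy("identity"))
        if not accept:
            assert got is None
        else:
            expected = o_identity_reduction(assignment, pf, n_args)
            assert dict(got.items()) == expected
            tri = reduction(f, r_f, ReductionPolicy("triangular",
                                                    seed=int(rng.integers(2**31))))
            support = o_triangular_support(assignment, pf, n_args)
            assert set(dict(tri.items())) == set(support)
            for i, v in tri.items():
                assert v in support[i]
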