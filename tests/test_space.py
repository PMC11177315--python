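import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from upbo import synthetic as syn
from upbo.space import (
    BOOLEAN,
    NUMERIC,
    SOLVENT,
    Condition,
    EmptySpaceError,
    SearchSpace,
    SolventRecord,
    SolventResolutionError,
    SpaceError,
    VariableSpec,
    acid_base_axis,
    apply_constraint,
    define_space,
    flag_out_of_space,
    grid,
    split_acid_base,
)

from conftest import make_tiny_space


def small_solvents(n=3, seed=0):
    return syn.solvent_records(syn.generate_solvent_table(n, seed))


class TestVariableSpec:
    def test_rejects_empty_and_duplicate_and_unordered_levels(self):
        with pytest.raises(EmptySpaceError):
            VariableSpec("x", NUMERIC, ())
        with pytest.raises(SpaceError):
            VariableSpec("x", NUMERIC, (1.0, 1.0))
        with pytest.raises(SpaceError):
            VariableSpec("x", NUMERIC, (2.0, 1.0))

    def test_boolean_levels_restricted(self):
        with pytest.raises(SpaceError):
            VariableSpec("b", BOOLEAN, (0, 2))


class TestSolventRecord:
    def test_requires_exactly_four_finite_descriptors(self):
        with pytest.raises(SpaceError):
            SolventRecord("s", (1.0, 2.0, 3.0))
        with pytest.raises(SpaceError):
            SolventRecord("s", (1.0, 2.0, 3.0, float("nan")))


class TestDefineSpace:
    def test_temperature_grid_from_bounds_and_step(self):
        assert grid(0.0, 50.0, 12.5) == (0.0, 12.5, 25.0, 37.5, 50.0)

    def test_degenerate_single_combination_space(self):
        records = small_solvents(1)
        cfg = {
            "variables": [
                {"name": "dsi2", "kind": BOOLEAN, "levels": [1]},
                {"name": "temp_c", "kind": NUMERIC, "levels": [25.0]},
                {"name": "solvent", "kind": SOLVENT},
            ]
        }
        assert define_space(cfg, records).cardinality == 1

    def test_cardinality_is_product_of_level_counts(self):
        records = small_solvents(4)
        cfg = {
            "variables": [
                {"name": "a", "kind": NUMERIC, "levels": [1.0, 2.0]},
                {"name": "b", "kind": NUMERIC, "levels": [1.0, 2.0, 3.0]},
                {"name": "solvent", "kind": SOLVENT},
            ]
        }
        assert define_space(cfg, records).cardinality == 24

    def test_unknown_solvent_is_a_resolution_error(self):
        records = small_solvents(2)
        cfg = {
            "variables": [
                {"name": "solvent", "kind": SOLVENT, "levels": ["no-such-solvent"]},
            ]
        }
        with pytest.raises(SolventResolutionError):
            define_space(cfg, records)

    def test_default_space_meets_documented_scale(self):
        space = syn.default_space(0)
        assert space.cardinality > 1_000_000
        counts = [v.n_levels for v in space.variables]
        prod = 1
        for c in counts:
            prod *= c
        assert space.cardinality == prod


class TestAcidBaseAxis:
    @pytest.mark.parametrize(
        "acid,base,expected", [(5, 0, 5.0), (0, 5, -5.0), (0, 0, 0.0), (0, 2.8, -2.8)]
    )
    def test_signed_axis_values(self, acid, base, expected):
        assert acid_base_axis(acid, base) == expected

    def test_both_positive_rejected(self):
        with pytest.raises(SpaceError):
            acid_base_axis(1.0, 1.0)

    @given(
        equiv=st.floats(min_value=0.0, max_value=50.0, allow_nan=False),
        is_acid=st.booleans(),
    )
    @settings(deadline=None, derandomize=True)
    def test_bijection_with_pairs(self, equiv, is_acid):
        pair = (equiv, 0.0) if is_acid else (0.0, equiv)
        axis = acid_base_axis(*pair)
        recovered = split_acid_base(axis)
        if equiv == 0.0:
            assert axis == 0.0 and recovered == (0.0, 0.0)
        else:
            assert recovered == pair


class TestCardinalityProperty:
    def test_fifty_randomized_small_configs(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            records = small_solvents(int(rng.integers(1, 6)), seed=trial)
            n_num = int(rng.integers(1, 4))
            variables = []
            expected = len(records)
            for j in range(n_num):
                k = int(rng.integers(1, 5))
                levels = tuple(sorted(rng.choice(100, size=k, replace=False).astype(float)))
                variables.append(VariableSpec(f"v{j}", NUMERIC, levels))
                expected *= k
            if rng.random() < 0.5:
                variables.append(VariableSpec("flag", BOOLEAN, (0, 1)))
                expected *= 2
            variables.append(VariableSpec("solvent", SOLVENT, tuple(records)))
            space = SearchSpace(tuple(variables), records)
            assert space.cardinality == expected


class TestEnumeration:
    def test_exhaustive_enumeration_matches_nested_loops(self, tiny_space):
        conds = list(tiny_space.enumerate_candidates())
        assert len(conds) == tiny_space.cardinality == len(set(conds))
        # independent nested-loop oracle
        oracle = {
            Condition(tuple(zip([v.name for v in tiny_space.variables], combo)))
            for combo in itertools.product(*(v.levels for v in tiny_space.variables))
        }
        assert set(conds) == oracle

    def test_subsample_is_deterministic_and_distinct(self, tiny_space):
        a = list(tiny_space.enumerate_candidates(subsample=10, seed=3))
        b = list(tiny_space.enumerate_candidates(subsample=10, seed=3))
        assert a == b
        assert len(set(a)) == 10

    def test_subsample_larger_than_cardinality_rejected(self, tiny_space):
        with pytest.raises(SpaceError):
            list(tiny_space.enumerate_candidates(subsample=tiny_space.cardinality + 1))

    def test_unrank_covers_space_without_duplicates(self, tiny_space):
        seen = {tiny_space.unrank(i) for i in range(tiny_space.cardinality)}
        assert len(seen) == tiny_space.cardinality


class TestEncoding:
    def test_feature_vector_layout(self, tiny_space):
        cond = tiny_space.unrank(0)
        x = tiny_space.encode(cond)
        assert x.shape == (tiny_space.n_features,)
        assert tiny_space.n_features == 7 + 4
        # boolean components are exactly 0/1
        names = tiny_space.feature_names()
        for bname in ("dsi2", "ptc", "ms"):
            assert x[names.index(bname)] in (0.0, 1.0)

    def test_solvent_descriptors_enter_scaled(self, tiny_space):
        cond = tiny_space.unrank(5)
        x = tiny_space.encode(cond)
        assert np.all((x >= -1e-9) & (x <= 1 + 1e-9))

    def test_round_trip_on_1000_random_conditions(self, tiny_space):
        for cond in tiny_space.enumerate_candidates(subsample=1000, seed=1):
            assert tiny_space.decode(tiny_space.encode(cond)) == cond


class TestApplyConstraint:
    def test_hydrazine_cap_relaxation(self, tiny_space):
        relaxed = apply_constraint(
            tiny_space, "menhnh2_equiv", (1.0, 5.0, 10.0, 16.0, 20.0)
        )
        assert set(relaxed.variable("menhnh2_equiv").levels) & {16.0, 20.0}
        assert relaxed.cardinality > tiny_space.cardinality

    def test_identity_constraint_preserves_space(self, tiny_space):
        var = tiny_space.variable("menhnh2_equiv")
        same = apply_constraint(tiny_space, "menhnh2_equiv", var.levels)
        assert same.cardinality == tiny_space.cardinality
        assert same.variable("menhnh2_equiv").levels == var.levels

    def test_disjoint_constraint_flags_all_observations(self, tiny_space):
        observed = list(tiny_space.enumerate_candidates(subsample=20, seed=2))
        constrained = apply_constraint(tiny_space, "menhnh2_equiv", (3.0,))
        flags = flag_out_of_space(constrained, observed)
        # none of the observed values (1 or 5 equiv) survive the new levels
        assert all(flags)
        assert sum(flags) == 20

    def test_empty_constraint_rejected(self, tiny_space):
        with pytest.raises(EmptySpaceError):
            apply_constraint(tiny_space, "menhnh2_equiv", ())
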