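import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srmpt import (
    CategoryCounts,
    apply_constraints,
    build_constrained,
    category_probabilities,
    check_identifiability,
    df_account,
    parse_eqn,
    storage_retrieval_model,
    write_eqn,
)
from srmpt.errors import (
    ConstraintError,
    DomainError,
    EqnParseError,
    StructuralError,
)
from srmpt.model import DEFAULT_CONDITIONS, Equal, Fix, Substitution

TWO_BRANCH = "1 A p\n1 B (1-p)\n"


class TestParseEqn:
    def test_builtin_model_structure(self, spec):
        assert spec.parameters == ("s", "r1", "r2", "g", "d")
        assert spec.tree_names == ("target", "distractor")
        assert spec.tree("target").categories == ("Rn+Rc+", "Rn+Rc-", "Rn-Rc+", "Rn-Rc-")
        assert spec.tree("distractor").categories == ("D+", "D-")
        assert len(spec.tree("target").branches) == 8
        assert spec.base_parameters == ("s", "r1", "r2", "g")

    def test_two_branch_model(self):
        spec = parse_eqn(TWO_BRANCH)
        assert spec.parameters == ("p",)
        probs = category_probabilities(spec, {"p": 0.3})
        assert probs["1"]["A"] + probs["1"]["B"] == pytest.approx(1.0)

    def test_header_line_optional(self):
        with_header = parse_eqn("2\n" + TWO_BRANCH)
        without = parse_eqn(TWO_BRANCH)
        assert with_header.parameters == without.parameters

    def test_incomplete_tree_is_structural_error(self):
        # omitting the (1-s)*(1-g) branch leaves sums = s + (1-s)*g != 1
        text = "t A s\nt B (1-s)*g\n"
        with pytest.raises(StructuralError):
            parse_eqn(text)

    def test_bad_line_reports_line_number(self):
        with pytest.raises(EqnParseError, match="line 2"):
            parse_eqn("1 A p\n1 B p+q\n")

    def test_undeclared_general_arithmetic_rejected(self):
        with pytest.raises(EqnParseError):
            parse_eqn("1 A 0.5*p\n1 B (1-p)\n")

    def test_write_round_trip(self, spec):
        text = write_eqn(spec)
        again = parse_eqn(text, constraints=("d:=s*r1",))
        for tree in spec.trees:
            assert again.tree(tree.name).branches == tree.branches

    def test_duplicate_category_across_trees_rejected(self):
        with pytest.raises(StructuralError):
            parse_eqn("1 A p\n1 B (1-p)\n2 A q\n2 C (1-q)\n")


class TestCategoryProbabilities:
    def test_deterministic_success_branch(self, spec):
        probs = category_probabilities(spec, {"s": 1, "r1": 1, "g": 0.37, "r2": 1})
        target = probs["target"]
        assert target["Rn+Rc+"] == pytest.approx(1.0)
        assert target["Rn+Rc-"] == target["Rn-Rc+"] == target["Rn-Rc-"] == 0.0

    def test_false_alarm_probability(self, spec, waking_rest_params):
        probs = category_probabilities(spec, waking_rest_params)
        # (1 - 0.91*0.98) * 0.46
        assert probs["distractor"]["D-"] == pytest.approx(0.049772, abs=1e-12)

    def test_recall_marginal_identity(self, spec, waking_rest_params):
        probs = category_probabilities(spec, waking_rest_params)
        marginal = probs["target"]["Rn+Rc+"] + probs["target"]["Rn-Rc+"]
        assert marginal == pytest.approx(0.91 * 0.73, abs=1e-12)

    def test_out_of_domain_rejected(self, spec):
        with pytest.raises(DomainError):
            category_probabilities(spec, {"s": 1.2, "r1": 1, "g": 0.5, "r2": 1})

    def test_sums_and_range_under_fuzzing(self, spec):
        rng = np.random.default_rng(42)
        params = {p: rng.uniform(0, 1, size=1000) for p in spec.base_parameters}
        probs = category_probabilities(spec, params)
        for tree in spec.trees:
            stacked = np.stack([probs[tree.name][c] for c in tree.categories])
            assert np.all(stacked >= 0) and np.all(stacked <= 1)
            np.testing.assert_allclose(stacked.sum(axis=0), 1.0, atol=1e-12)

    @given(
        s=st.floats(0, 1),
        r1=st.floats(0, 1),
        g=st.floats(0, 1),
        r2=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_branch_sums_property(self, s, r1, g, r2):
        spec = storage_retrieval_model()
        probs = category_probabilities(spec, {"s": s, "r1": r1, "g": g, "r2": r2})
        for tree in spec.trees:
            total = sum(probs[tree.name][c] for c in tree.categories)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_symbolic_route_matches_branch_enumeration(self, spec):
        """The sympy-compiled path must agree with direct branch products."""
        model = build_constrained(spec)
        rng = np.random.default_rng(7)
        for _ in range(50):
            theta = rng.uniform(0, 1, size=model.n_free)
            values = dict(zip([p for p, _ in model.free_names], theta))
            direct = category_probabilities(spec, values)
            flat = []
            for tree in spec.trees:
                flat.extend(direct[tree.name][c] for c in tree.categories)
            np.testing.assert_allclose(model.prob_vector(theta), flat, atol=1e-14)


class TestConstraints:
    def test_df_saturated_single_group(self, spec):
        assert df_account(spec).df == 0

    def test_df_r1_equality_three_groups(self, spec):
        da = df_account(
            spec,
            groups=DEFAULT_CONDITIONS,
            constraints=["r1[waking_rest]=r1[social_media]"],
        )
        assert (da.free_categories, da.free_parameters, da.df) == (12, 11, 1)

    def test_df_g_equality_all_groups(self, spec):
        da = df_account(spec, groups=DEFAULT_CONDITIONS, constraints=["g=g"])
        assert (da.free_parameters, da.df) == (10, 2)

    def test_apply_constraints_idempotent(self, spec):
        c = ["r1[waking_rest]=r1[social_media]"]
        once = apply_constraints(spec, c)
        twice = apply_constraints(once, c)
        assert once == twice
        assert df_account(once, DEFAULT_CONDITIONS).df == df_account(twice, DEFAULT_CONDITIONS).df

    def test_df_matches_independent_recount(self, spec):
        # df = sum over groups/trees of (categories - 1) minus free parameters
        constraints = ["g=g", "r2[waking_rest]=r2[vocabulary]"]
        model = build_constrained(spec, DEFAULT_CONDITIONS, constraints)
        n_groups = len(DEFAULT_CONDITIONS)
        free_cats = n_groups * sum(len(t.categories) - 1 for t in spec.trees)
        # independent count: 4 base params x 3 groups, minus 2 for g-equality,
        # minus 1 for the r2 equality
        assert model.df_account().df == free_cats - (12 - 2 - 1)

    def test_contradictory_fixations_rejected(self, spec):
        with pytest.raises(ConstraintError):
            build_constrained(spec, constraints=[Fix("g", 0.3), Fix("g", 0.5)])

    def test_cyclic_substitution_rejected(self):
        with pytest.raises(ConstraintError):
            parse_eqn(TWO_BRANCH, constraints=[Substitution("p", ("p",))])

    def test_fixation_resolves_in_probabilities(self, spec):
        model = build_constrained(spec, constraints=[Fix("g", 0.5)])
        assert model.n_free == 3
        values = model.parameter_values(np.array([0.9, 0.95, 0.7]))
        assert values[None]["g"] == 0.5

    def test_equality_across_all_groups_string(self, spec):
        model = build_constrained(spec, DEFAULT_CONDITIONS, [Equal((("g", None),))])
        assert model.n_free == 10


class TestIdentifiability:
    def test_saturated_model_identifiable(self, spec):
        report = check_identifiability(spec, n_probe=10, seed=1)
        assert report.n_free_parameters == 4
        assert report.locally_identifiable
        assert report.min_rank == 4

    def test_free_d_not_identifiable(self):
        spec = storage_retrieval_model(with_substitution=False)
        report = check_identifiability(spec, n_probe=10, seed=1)
        assert report.n_free_parameters == 5
        assert report.max_rank < 5

    def test_one_parameter_model(self):
        report = check_identifiability(parse_eqn(TWO_BRANCH), n_probe=5)
        assert report.min_rank == report.max_rank == 1

    def test_zero_probes_rejected(self, spec):
        with pytest.raises(DomainError):
            check_identifiability(spec, n_probe=0)


class TestCategoryCounts:
    def test_vector_round_trip(self, spec):
        vec = np.array([10.0, 4, 3, 3, 18, 2])
        counts = CategoryCounts.from_vector(spec, vec)
        np.testing.assert_array_equal(counts.vector(spec), vec)
        assert counts.totals == {"target": 20.0, "distractor": 20.0}

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            CategoryCounts({"t": {"A": -1.0}})

    def test_real_valued_allowed(self, spec, waking_rest_counts):
        totals = waking_rest_counts.totals
        assert totals["target"] == pytest.approx(1020.0)
        assert totals["distractor"] == pytest.approx(1020.0)
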