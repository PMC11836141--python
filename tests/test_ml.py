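import dataclasses

import numpy as np
import pytest
from scipy import stats

from srmpt import (
    CategoryCounts,
    category_probabilities,
    compare_nested,
    expected_frequencies,
    fit_ml,
    goodness_of_fit,
    invert_saturated,
    storage_retrieval_model,
    wald_ci,
)
from srmpt.errors import DataError, InversionError, SrmptError
from srmpt.ml import g_squared
from srmpt.model import DEFAULT_CONDITIONS

from conftest import AGGREGATED_ESTIMATES, random_interior_counts


def _expected(spec, params, n=1000):
    return expected_frequencies(spec, params, {"target": n, "distractor": n})


class TestFitMl:
    def test_saturated_self_consistency(self, spec):
        theta0 = {"s": 0.85, "r1": 0.9, "g": 0.35, "r2": 0.65}
        fit = fit_ml(spec, _expected(spec, theta0), restarts=5, seed=0)
        assert fit.g2 == pytest.approx(0.0, abs=1e-6)
        for p, v in theta0.items():
            assert fit.estimates[None][p] == pytest.approx(v, abs=1e-6)

    @pytest.mark.parametrize("column", list(AGGREGATED_ESTIMATES))
    def test_printed_estimates_round_trip(self, spec, column):
        printed, n = AGGREGATED_ESTIMATES[column]
        counts = _expected(spec, printed, n)
        fit = fit_ml(spec, counts, restarts=5, seed=1)
        for p, v in printed.items():
            assert round(fit.estimates[None][p], 2) == v

    def test_boundary_data_flagged(self, spec):
        counts = CategoryCounts.from_vector(spec, [20, 0, 0, 0, 20, 0])
        fit = fit_ml(spec, counts, restarts=5, seed=0)
        assert fit.boundary
        assert fit.estimates[None]["s"] == pytest.approx(1.0, abs=1e-4)
        assert fit.estimates[None]["r1"] == pytest.approx(1.0, abs=1e-4)
        assert fit.estimates[None]["r2"] == pytest.approx(1.0, abs=1e-4)
        # g is unidentified here; its interval must be flagged missing
        assert all(ci.missing for ci in wald_ci(fit))

    def test_all_zero_tree_rejected(self, spec):
        with pytest.raises(DataError):
            fit_ml(spec, CategoryCounts.from_vector(spec, [10, 5, 3, 2, 0, 0]))

    def test_optimum_beats_random_vectors(self, spec):
        rng = np.random.default_rng(3)
        counts, _ = random_interior_counts(spec, rng, n_per_tree=400)
        fit = fit_ml(spec, counts, restarts=5, seed=0)
        n = counts.vector(spec)
        for _ in range(100):
            params = {p: rng.uniform(0.01, 0.99) for p in spec.base_parameters}
            probs = category_probabilities(spec, params)
            flat = np.array(
                [probs[t.name][c] for t in spec.trees for c in t.categories]
            )
            ll = float(np.sum(n * np.log(flat)))
            assert fit.loglik >= ll - 1e-9


class TestGoodnessOfFit:
    def test_saturated_p_not_applicable(self, spec, waking_rest_counts):
        fit = fit_ml(spec, waking_rest_counts, restarts=3, seed=0)
        g2, df, p = goodness_of_fit(fit)
        assert df == 0
        assert g2 == pytest.approx(0.0, abs=1e-6)
        assert p is None

    def test_df2_p_value_from_chi_square_tail(self, spec):
        # the df=2 statistic's p comes from the chi-square survival function;
        # G^2 = 11.34 with df = 2 corresponds to p = 0.003
        assert round(float(stats.chi2.sf(11.34, 2)), 3) == 0.003
        counts = {
            c: _expected(spec, AGGREGATED_ESTIMATES[f"exp1_{c}"][0], 1000)
            for c in DEFAULT_CONDITIONS
        }
        fit = fit_ml(spec, counts, constraints=["g=g"], restarts=3, seed=0)
        g2, df, p = goodness_of_fit(fit)
        assert df == 2
        assert g2 > 0
        assert p == pytest.approx(float(stats.chi2.sf(g2, 2)), abs=1e-12)

    def test_restricted_g2_dominates_general(self, spec):
        rng = np.random.default_rng(11)
        for _ in range(20):
            counts = {
                "a": random_interior_counts(spec, rng, 300)[0],
                "b": random_interior_counts(spec, rng, 300)[0],
            }
            general = fit_ml(spec, counts, restarts=3, seed=0)
            restricted = fit_ml(spec, counts, constraints=["s[a]=s[b]"], restarts=3, seed=0)
            assert restricted.g2 >= general.g2 - 1e-6


class TestCompareNested:
    def _two_group_fits(self, spec, seed=5, extra=("s[a]=s[b]",)):
        rng = np.random.default_rng(seed)
        counts = {
            "a": random_interior_counts(spec, rng, 500)[0],
            "b": random_interior_counts(spec, rng, 500)[0],
        }
        general = fit_ml(spec, counts, restarts=3, seed=0)
        restricted = fit_ml(spec, counts, constraints=list(extra), restarts=3, seed=0)
        return general, restricted

    def test_identical_constraint_sets(self, spec):
        general, _ = self._two_group_fits(spec)
        comparison = compare_nested(general, general)
        assert comparison.delta_g2 == 0.0
        assert comparison.p_two_tailed == 1.0

    def test_delta_df_one_gives_z(self, spec):
        general, restricted = self._two_group_fits(spec)
        comparison = compare_nested(general, restricted)
        assert comparison.delta_df == 1
        assert comparison.z == pytest.approx(np.sqrt(comparison.delta_g2))
        # Delta G^2 = 13.40 with df = 1 corresponds to p < 0.001
        assert float(stats.chi2.sf(13.40, 1)) < 0.001

    def test_one_tailed_direction_mismatch(self, spec):
        general, restricted = self._two_group_fits(spec)
        sa = general.estimates["a"]["s"]
        sb = general.estimates["b"]["s"]
        smaller, larger = ("a", "b") if sa < sb else ("b", "a")
        wrong = compare_nested(
            general, restricted, tail="one", direction=("s", smaller, larger)
        )
        right = compare_nested(
            general, restricted, tail="one", direction=("s", larger, smaller)
        )
        assert wrong.p_one_tailed > 0.5
        assert right.p_one_tailed == pytest.approx(right.p_two_tailed / 2)

    def test_non_nested_rejected(self, spec):
        general, _ = self._two_group_fits(spec, extra=("g[a]=g[b]",))
        other, _ = self._two_group_fits(spec, seed=6)
        with pytest.raises(SrmptError):
            compare_nested(other, general)


class TestWaldCi:
    def test_zero_se_degenerates_to_point(self, spec, waking_rest_counts):
        fit = fit_ml(spec, waking_rest_counts, restarts=3, seed=0)
        degenerate = dataclasses.replace(fit, covariance=np.zeros((4, 4)))
        for ci in wald_ci(degenerate):
            assert ci.lower == ci.upper == pytest.approx(ci.estimate)

    def test_width_scales_as_inverse_sqrt_n(self, spec, waking_rest_params):
        widths = []
        for n in (1000, 4000):
            fit = fit_ml(spec, _expected(spec, waking_rest_params, n), restarts=3, seed=0)
            ci = wald_ci(fit)[0]
            widths.append(ci.upper - ci.lower)
        assert widths[1] == pytest.approx(widths[0] / 2, rel=0.05)

    def test_bounds_contain_estimate_and_clip(self, spec):
        rng = np.random.default_rng(19)
        counts, _ = random_interior_counts(spec, rng, 200)
        fit = fit_ml(spec, counts, restarts=3, seed=0)
        for ci in wald_ci(fit):
            assert 0.0 <= ci.lower <= ci.estimate <= ci.upper <= 1.0

    def test_coverage_simulation(self, spec):
        """95% Wald CI covers the generating s at ~0.95 over 300 replicates."""
        theta0 = {"s": 0.8, "r1": 0.9, "g": 0.4, "r2": 0.7}
        probs = category_probabilities(spec, theta0)
        p_t = np.array([probs["target"][c] for c in spec.tree("target").categories])
        p_d = np.array([probs["distractor"][c] for c in spec.tree("distractor").categories])
        rng = np.random.default_rng(23)
        hits, total = 0, 300
        for _ in range(total):
            vec = np.concatenate([rng.multinomial(1000, p_t), rng.multinomial(1000, p_d)])
            counts = CategoryCounts.from_vector(spec, vec)
            start = {None: invert_saturated(counts)}
            fit = fit_ml(spec, counts, restarts=1, seed=0, start=start)
            ci = next(c for c in wald_ci(fit) if c.parameter == "s")
            if not ci.missing and ci.lower <= theta0["s"] <= ci.upper:
                hits += 1
        rate = hits / total
        assert abs(rate - 0.95) <= 3 * np.sqrt(0.95 * 0.05 / total)


class TestInvertSaturated:
    def test_algebraic_round_trip(self, spec):
        theta0 = {"s": 0.9, "r1": 0.95, "g": 0.4, "r2": 0.7}
        est = invert_saturated(_expected(spec, theta0))
        for p, v in theta0.items():
            assert est[p] == pytest.approx(v, abs=1e-12)

    def test_matches_optimizer_on_random_data(self, spec):
        rng = np.random.default_rng(31)
        for _ in range(20):
            counts, _ = random_interior_counts(spec, rng, 500)
            closed = invert_saturated(counts)
            fit = fit_ml(spec, counts, restarts=5, seed=2)
            for p in spec.base_parameters:
                assert fit.estimates[None][p] == pytest.approx(closed[p], abs=1e-5)

    def test_chance_performance_rejected(self, spec):
        counts = CategoryCounts.from_vector(spec, [5, 5, 5, 5, 10, 10])
        with pytest.raises(InversionError):
            invert_saturated(counts)  # hit rate == false-alarm rate


class TestGSquared:
    def test_zero_cells_contribute_nothing(self):
        assert g_squared(np.array([10.0, 0.0]), np.array([10.0, 1e-9])) == pytest.approx(0.0)

    def test_matches_direct_formula(self):
        n = np.array([30.0, 20.0, 50.0])
        e = np.array([25.0, 25.0, 50.0])
        manual = 2 * (30 * np.log(30 / 25) + 20 * np.log(20 / 25))
        assert g_squared(n, e) == pytest.approx(manual)


class TestProfileCi:
    def test_contains_estimate_and_brackets_wald(self, spec):
        from srmpt import profile_ci

        rng = np.random.default_rng(41)
        counts, _ = random_interior_counts(spec, rng, 800)
        fit = fit_ml(spec, counts, restarts=3, seed=0)
        profile = profile_ci(spec, fit, "s")
        wald = next(c for c in wald_ci(fit) if c.parameter == "s")
        assert profile.lower <= profile.estimate <= profile.upper
        # at large N the profile interval agrees closely with the Wald one
        assert profile.lower == pytest.approx(wald.lower, abs=0.01)
        assert profile.upper == pytest.approx(wald.upper, abs=0.01)

    def test_unknown_parameter_rejected(self, spec, waking_rest_counts):
        from srmpt import profile_ci

        fit = fit_ml(spec, waking_rest_counts, restarts=3, seed=0)
        with pytest.raises(SrmptError):
            profile_ci(spec, fit, "zeta")
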