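import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliapipe import (
    ecdf,
    kruskal_wallis,
    ks_test,
    mann_whitney_u,
    pearson_r,
    per_animal_summary,
    two_way_anova,
)
from gliapipe.errors import (
    ManifestError,
    ParameterError,
    UnbalancedDesignError,
    UndefinedCorrelationError,
)
from gliapipe.types import ImageGRSummary


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        assert mann_whitney_u([1, 2], [3, 4]).statistic == 0.0

    def test_identical_samples_u_half_n_squared(self):
        # midrank convention: U = n^2/2 for x = y
        res = mann_whitney_u([1, 2], [1, 2])
        assert res.statistic == 2.0
        res = mann_whitney_u([3, 1, 4], [3, 1, 4])
        assert res.statistic == 4.5

    def test_interleaved_matches_pair_counting(self):
        x, y = [1, 3], [2, 4]
        # brute-force count of pairs (x_i > y_j); U reported is the
        # smaller of the two orientations
        u_x = sum(xi > yj for xi in x for yj in y)
        u_y = sum(yj > xi for xi in x for yj in y)
        assert mann_whitney_u(x, y).statistic == min(u_x, u_y) == 1.0

    def test_exact_p_small_samples(self):
        # most extreme arrangement for n=3 each: exact two-sided p = 0.1
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.note == "exact"
        assert res.pvalue == pytest.approx(0.1)

    def test_empty_sample_raises(self):
        with pytest.raises(ParameterError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_singletons_closed_form(self):
        # groups {1},{2},{3}: H = 12/(N(N+1)) * sum n_i (rbar_i - (N+1)/2)^2 = 2
        res = kruskal_wallis([[1], [2], [3]])
        assert res.statistic == pytest.approx(2.0)

    def test_identical_samples_h_zero(self):
        assert kruskal_wallis([[1, 2], [1, 2]]).statistic == pytest.approx(0.0)

    def test_all_ties_h_zero(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_two_groups_needs_two(self):
        with pytest.raises(ParameterError):
            kruskal_wallis([[1, 2]])


class TestKS:
    def test_identical_samples_d_zero(self):
        assert ks_test([1, 2, 3], [1, 2, 3]).statistic == 0.0

    def test_disjoint_supports_d_one(self):
        assert ks_test([0, 0], [1, 1]).statistic == 1.0

    def test_matches_breakpoint_enumeration(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=5) + 0.5
        breaks = np.concatenate([x, y])
        d = max(
            abs((x <= b).mean() - (y <= b).mean()) for b in breaks
        )
        assert ks_test(x, y).statistic == pytest.approx(d)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        # x={1,2,3}, y={1,3,2}: cov/(sx sy) = 0.5 by direct arithmetic
        assert pearson_r([1, 2, 3], [1, 3, 2]).statistic == pytest.approx(0.5)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_nan_pairs_dropped(self):
        res = pearson_r([1, 2, 3, np.nan], [2, 4, 6, 8])
        assert res.statistic == pytest.approx(1.0)
        assert res.n == (3,)


class TestEcdf:
    def test_single_value(self):
        assert ecdf([5]) == [(5.0, 1.0)]

    def test_counting_example(self):
        assert ecdf([1, 2, 2, 4]) == [(1.0, 0.25), (2.0, 0.75), (4.0, 1.0)]

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_nondecreasing_and_ends_at_one(self, values):
        pts = ecdf(values)
        fracs = [f for _, f in pts]
        assert fracs == sorted(fracs)
        assert fracs[-1] == pytest.approx(1.0)


class TestTwoWayAnova:
    def test_constant_data_all_f_zero(self):
        values = [5.0] * 12
        ages = ["young", "aged"] * 6
        stress = ["control"] * 6 + ["stress"] * 6
        res = two_way_anova(values, ages, stress)
        for term in ("age", "stress", "interaction"):
            assert res.terms[term]["F"] == 0.0

    def test_additive_noiseless_design_degenerate(self):
        # cell means young/aged x control/stress = 0/2 + 0/3, two obs per
        # cell, zero within-cell variance: interaction F = 0, main
        # effects unbounded, flagged degenerate
        rows = []
        for age, a in (("young", 0.0), ("aged", 2.0)):
            for stress, b in (("control", 0.0), ("stress", 3.0)):
                rows += [(a + b, age, stress)] * 2
        values, ages, stress = zip(*rows)
        res = two_way_anova(values, ages, stress)
        assert res.degenerate
        assert res.terms["interaction"]["F"] == 0.0
        assert res.terms["age"]["F"] == float("inf")
        assert res.terms["stress"]["F"] == float("inf")

    def test_balanced_2x3_matches_hand_computed_sums_of_squares(self):
        # balanced design: Type II equals the classical factorial SS
        data = {
            ("young", "control"): [3.0, 5.0],
            ("young", "stress"): [6.0, 8.0],
            ("young", "recovery"): [4.0, 6.0],
            ("aged", "control"): [7.0, 9.0],
            ("aged", "stress"): [8.0, 12.0],
            ("aged", "recovery"): [9.0, 11.0],
        }
        values, ages, stress = [], [], []
        for (a, s), vals in data.items():
            for v in vals:
                values.append(v)
                ages.append(a)
                stress.append(s)
        res = two_way_anova(values, ages, stress)

        # explicit group-mean arithmetic oracle
        arr = {k: np.array(v) for k, v in data.items()}
        grand = np.mean(values)
        n_per_cell = 2
        a_levels = ["young", "aged"]
        s_levels = ["control", "stress", "recovery"]
        a_means = {a: np.mean([v for k, vs in arr.items() if k[0] == a for v in vs]) for a in a_levels}
        s_means = {s: np.mean([v for k, vs in arr.items() if k[1] == s for v in vs]) for s in s_levels}
        ss_a = sum(6 * (a_means[a] - grand) ** 2 for a in a_levels)
        ss_s = sum(4 * (s_means[s] - grand) ** 2 for s in s_levels)
        cell_means = {k: v.mean() for k, v in arr.items()}
        ss_cells = sum(
            n_per_cell * (cell_means[(a, s)] - grand) ** 2
            for a in a_levels
            for s in s_levels
        )
        ss_int = ss_cells - ss_a - ss_s
        ss_err = sum(((v - v.mean()) ** 2).sum() for v in arr.values())
        df_a, df_s, df_int, df_err = 1, 2, 2, 6
        f_a = (ss_a / df_a) / (ss_err / df_err)
        f_s = (ss_s / df_s) / (ss_err / df_err)
        f_int = (ss_int / df_int) / (ss_err / df_err)
        assert res.terms["age"]["F"] == pytest.approx(f_a)
        assert res.terms["stress"]["F"] == pytest.approx(f_s)
        assert res.terms["interaction"]["F"] == pytest.approx(f_int)

    def test_empty_cell_raises_naming_the_cell(self):
        with pytest.raises(UnbalancedDesignError, match="aged.*stress"):
            two_way_anova(
                [1, 2, 3, 4],
                ["young", "young", "young", "aged"],
                ["control", "stress", "control", "control"],
            )


class TestRankTestInvariances:
    @settings(derandomize=True, max_examples=20)
    @given(
        x=st.lists(st.integers(0, 50), min_size=3, max_size=10),
        y=st.lists(st.integers(0, 50), min_size=3, max_size=10),
    )
    def test_monotone_transform_leaves_rank_tests_unchanged(self, x, y):
        def warp(v):
            return np.exp(np.asarray(v, dtype=float) / 10.0)

        assert mann_whitney_u(x, y).statistic == mann_whitney_u(warp(x), warp(y)).statistic
        assert kruskal_wallis([x, y]).statistic == pytest.approx(
            kruskal_wallis([warp(x), warp(y)]).statistic
        )
        assert ks_test(x, y).statistic == pytest.approx(
            ks_test(warp(x), warp(y)).statistic
        )

    def test_group_order_invariance(self):
        x = [1.0, 5.0, 2.0]
        y = [4.0, 3.0, 9.0]
        assert mann_whitney_u(x, y).statistic == mann_whitney_u(y, x).statistic
        assert ks_test(x, y).statistic == ks_test(y, x).statistic
        assert kruskal_wallis([x, y]).statistic == pytest.approx(
            kruskal_wallis([y, x]).statistic
        )


class TestPerAnimalSummary:
    def _summary(self, image_id, animal_id, soma, volume=100.0, n_mg=2):
        return ImageGRSummary(
            image_id=image_id,
            animal_id=animal_id,
            microglial_volume=volume,
            n_microglia=n_mg,
            mean_soma_volume=soma,
        )

    def _manifest(self, pairs):
        return pd.DataFrame(
            [
                {"image_id": i, "animal_id": a, "age": "young", "stress": "control"}
                for i, a in pairs
            ]
        )

    def test_single_image_passthrough(self):
        out = per_animal_summary(
            [], [self._summary("i1", "a1", soma=120.0)], self._manifest([("i1", "a1")])
        )
        assert len(out) == 1
        assert out.loc[0, "mean_soma_volume"] == 120.0
        assert out.loc[0, "microglial_volume"] == 100.0

    def test_two_images_averaged(self):
        out = per_animal_summary(
            [],
            [self._summary("i1", "a1", 100.0), self._summary("i2", "a1", 200.0)],
            self._manifest([("i1", "a1"), ("i2", "a1")]),
        )
        assert out.loc[0, "mean_soma_volume"] == 150.0
        assert out.loc[0, "n_images"] == 2

    def test_zero_microglia_yields_missing_not_zero(self):
        s = self._summary("i1", "a1", soma=float("nan"), n_mg=0)
        out = per_animal_summary([], [s], self._manifest([("i1", "a1")]))
        assert np.isnan(out.loc[0, "mean_soma_volume"])
        assert out.loc[0, "n_microglia"] == 0

    def test_unknown_image_raises(self):
        with pytest.raises(ManifestError):
            per_animal_summary(
                [], [self._summary("i9", "a1", 1.0)], self._manifest([("i1", "a1")])
            )

    def test_mixed_cohort_matches_brute_force_group_means(self, rng):
        summaries, rows = [], []
        for a in range(4):
            animal = f"a{a}"
            for i in range(3):
                image = f"{animal}_i{i}"
                summaries.append(
                    self._summary(image, animal, soma=float(rng.integers(50, 150)))
                )
                rows.append((image, animal))
        out = per_animal_summary([], summaries, self._manifest(rows)).set_index("animal_id")
        by_animal = {}
        for s in summaries:
            by_animal.setdefault(s.animal_id, []).append(s.mean_soma_volume)
        for animal, vals in by_animal.items():
            assert out.loc[animal, "mean_soma_volume"] == pytest.approx(
                sum(vals) / len(vals)
            )
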