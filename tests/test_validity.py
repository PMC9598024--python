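"""Convergent-variable derivation, test selection, effect sizes, battery."""

import math

import numpy as np
import pytest
from scipy import stats

from pbi_ark import (
    SimulationConfig,
    derive_convergent,
    effect_label,
    score_cohort,
    simulate_cohort,
    validity_battery,
)
from pbi_ark.validity import (
    LEVENE_SCREEN_P,
    VariableKind,
    levene_equal_variance,
    one_way_anova,
    pearson_assoc,
    two_group_compare,
)

from conftest import make_respondent


def _by_name(variables):
    return {v.name: v for v in variables}


class TestDeriveConvergent:
    def _cohort(self, cohort_factory, convergent, age=9.0):
        return cohort_factory([make_respondent(age=age, convergent=convergent)])

    def test_strict_ordinal_improvement_counts_as_decrease(self, cohort_factory):
        cohort = self._cohort(
            cohort_factory, {"v1_rhinitis_severity": "strong", "v2_rhinitis_severity": "mild"}
        )
        v = _by_name(derive_convergent(cohort))["rhinitis_severity_change"]
        assert v.values[0] == "decreased"
        assert v.kind is VariableKind.DICHOTOMOUS

    @pytest.mark.parametrize("v2", ["mild", "moderate"])
    def test_tie_or_worsening_counts_as_no_decrease(self, cohort_factory, v2):
        cohort = self._cohort(
            cohort_factory, {"v1_rhinitis_severity": "mild", "v2_rhinitis_severity": v2}
        )
        v = _by_name(derive_convergent(cohort))["rhinitis_severity_change"]
        assert v.values[0] == "no_decrease"

    def test_normal_at_visit1_excluded_from_normalisation(self, cohort_factory):
        cohort = self._cohort(
            cohort_factory, {"v1_sleep": "normal", "v2_sleep": "normal"}
        )
        assert _by_name(derive_convergent(cohort))["sleep_normalised"].values[0] is None

    def test_impaired_then_normal_is_normalised(self, cohort_factory):
        cohort = self._cohort(
            cohort_factory, {"v1_sleep": "impaired", "v2_sleep": "normal"}
        )
        assert _by_name(derive_convergent(cohort))["sleep_normalised"].values[0] == "normalised"

    def test_vas_change_is_plain_difference(self, cohort_factory):
        cohort = self._cohort(cohort_factory, {"v1_vas_avg": 8, "v2_vas_avg": 3})
        assert _by_name(derive_convergent(cohort))["vas_avg_change"].values[0] == -5.0

    def test_missing_visit_value_propagates(self, cohort_factory):
        cohort = self._cohort(cohort_factory, {"v1_vas_avg": 8})
        assert _by_name(derive_convergent(cohort))["vas_avg_change"].values[0] is None

    def test_children_judgement_keeps_three_levels(self, cohort_factory):
        cohort = cohort_factory(
            [
                make_respondent(str(i), convergent={"v2_global_judgement_physician": lvl})
                for i, lvl in enumerate(["much_better", "somewhat_better", "unchanged", "worse"])
            ]
        )
        v = _by_name(derive_convergent(cohort))["global_judgement_physician"]
        assert v.kind is VariableKind.CATEGORICAL
        assert v.values == ("much_better", "somewhat_better", "unchanged", None)

    def test_adolescent_judgement_keeps_two_levels(self, cohort_factory):
        cohort = cohort_factory(
            [
                make_respondent(str(i), age=15.0,
                                convergent={"v2_global_judgement_patient": lvl})
                for i, lvl in enumerate(["much_better", "somewhat_better", "unchanged", "worse"])
            ]
        )
        v = _by_name(derive_convergent(cohort))["global_judgement_patient"]
        assert v.kind is VariableKind.DICHOTOMOUS
        assert v.values == ("much_better", "somewhat_better", None, None)

    def test_eleven_variables_derived(self, small_children_cohort):
        assert len(derive_convergent(small_children_cohort)) == 11


class TestLevene:
    def test_identical_samples_give_statistic_zero_region(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert levene_equal_variance(g, g) > 0.99

    def test_detects_fourfold_sd_difference(self):
        """SD 1 vs SD 4 at n=50: the 0.1 screen should flag inequality in
        at least 95% of 500 replicates."""
        rng = np.random.default_rng(12)
        hits = sum(
            levene_equal_variance(rng.normal(0, 1, 50), rng.normal(0, 4, 50)) < LEVENE_SCREEN_P
            for _ in range(500)
        )
        assert hits >= 475

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            levene_equal_variance([], [1.0, 2.0])


def _levene_boundary_samples():
    """Two fixed samples plus scale factors placing Levene's p just below
    and just above the 0.1 screen."""
    rng = np.random.default_rng(42)
    g1 = rng.normal(0, 1, 60)
    g2 = rng.normal(0, 1, 60)
    lo = hi = None
    for c in np.linspace(1.0, 2.0, 4001):
        p = levene_equal_variance(g1, g2 * c)
        if 0.09 < p < 0.0999 and lo is None:
            lo = c
        if 0.1001 < p < 0.11 and hi is None:
            hi = c
        if lo is not None and hi is not None:
            break
    assert lo is not None and hi is not None
    return g1, g2, lo, hi


class TestSelectionWiring:
    def test_levene_p_below_screen_routes_to_welch_above_to_pooled(self):
        g1, g2, lo, hi = _levene_boundary_samples()
        scores = np.concatenate([g1, g2 * lo])
        labels = ["a"] * 60 + ["b"] * 60
        res = two_group_compare(scores, labels, ("a", "b"))
        assert res.test == "welch_t"
        scores = np.concatenate([g1, g2 * hi])
        res = two_group_compare(scores, labels, ("a", "b"))
        assert res.test == "t_test"


class TestTwoGroupCompare:
    def test_equal_groups_null_case(self):
        scores = np.array([1.0, 2, 3, 1, 2, 3])
        labels = ["a", "a", "a", "b", "b", "b"]
        res = two_group_compare(scores, labels, ("a", "b"))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_cohens_d_sign_and_bias(self):
        """Group means 0 vs 1, SD 1, n=100 each: mean estimated d is -1.0
        (group 1 = the worse-outcome group) within 0.05 over 500 replicates."""
        rng = np.random.default_rng(8)
        ds = []
        labels = ["worse"] * 100 + ["better"] * 100
        for _ in range(500):
            scores = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
            ds.append(two_group_compare(scores, labels, ("worse", "better")).effect_size)
        assert np.mean(ds) == pytest.approx(-1.0, abs=0.05)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(21)
        labels = ["a"] * 50 + ["b"] * 50
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            scores = rng.standard_normal(100)
            if two_group_compare(scores, labels, ("a", "b")).significant:
                hits += 1
        assert hits / n_rep == pytest.approx(0.05, abs=0.02)

    def test_power_at_large_effect(self):
        """True difference 0.8 pooled SD, n=80 per group: significant in at
        least 90% of 500 replicates."""
        rng = np.random.default_rng(30)
        labels = ["a"] * 80 + ["b"] * 80
        hits = sum(
            two_group_compare(
                np.concatenate([rng.normal(0, 1, 80), rng.normal(0.8, 1, 80)]),
                labels,
                ("a", "b"),
            ).significant
            for _ in range(500)
        )
        assert hits >= 450

    def test_emptied_group_not_estimable(self):
        res = two_group_compare([1.0, 2.0, np.nan], ["a", "a", "b"], ("a", "b"))
        assert not res.estimable and res.p is None


class TestAnova:
    def test_equal_means_null_case(self):
        scores = np.tile([1.0, 2.0, 3.0], 3)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = one_way_anova(scores, labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_eta_squared_recovers_population_value(self):
        """Three groups with means (0, 0, 1), SD 1, n=50: population
        eta^2 = (2/9) / (2/9 + 1) ~ 0.1818; the mean estimate over seeded
        replicates lands within 0.05."""
        rng = np.random.default_rng(13)
        labels = ["a"] * 50 + ["b"] * 50 + ["c"] * 50
        estimates = []
        for _ in range(300):
            scores = np.concatenate(
                [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
            )
            estimates.append(one_way_anova(scores, labels).effect_size)
        pop = (2 / 9) / (2 / 9 + 1)
        assert np.mean(estimates) == pytest.approx(pop, abs=0.05)

    def test_two_level_anova_equals_squared_pooled_t(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(40)
        labels = ["a"] * 22 + ["b"] * 18
        f_res = one_way_anova(scores, labels)
        t, p = stats.ttest_ind(scores[:22], scores[22:], equal_var=True)
        assert f_res.statistic == pytest.approx(t ** 2, abs=1e-8)
        assert f_res.p == pytest.approx(p, abs=1e-10)

    def test_single_level_not_estimable(self):
        res = one_way_anova([1.0, 2.0], ["a", "a"])
        assert not res.estimable


class TestPearson:
    def test_perfect_decreasing_relation(self):
        res = pearson_assoc([1.0, 2, 3, 4], [4.0, 3, 2, 1])
        assert res.effect_size == pytest.approx(-1.0)

    def test_recovers_negative_correlation(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(160)
        y = -0.4 * x + math.sqrt(1 - 0.4 ** 2) * rng.standard_normal(160)
        res = pearson_assoc(x, y)
        assert res.effect_size == pytest.approx(-0.4, abs=0.15)

    def test_null_correlations_stay_small(self):
        rng = np.random.default_rng(19)
        hits = sum(
            abs(pearson_assoc(rng.standard_normal(150), rng.standard_normal(150)).effect_size) < 0.2
            for _ in range(400)
        )
        assert hits >= 380

    def test_zero_variance_not_estimable(self):
        assert not pearson_assoc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]).estimable


class TestEffectLabels:
    @pytest.mark.parametrize(
        "value,kind,expected",
        [
            (0.19, "d", "NEGLIGIBLE"), (0.2, "d", "SMALL"), (0.5, "d", "MEDIUM"),
            (0.8, "d", "STRONG"), (-0.82, "d", "STRONG"), (-0.5, "d", "MEDIUM"),
            (0.009, "eta2", "NEGLIGIBLE"), (0.01, "eta2", "SMALL"),
            (0.06, "eta2", "MEDIUM"), (0.14, "eta2", "STRONG"),
            (0.05, "r", "NEGLIGIBLE"), (0.1, "r", "SMALL"), (0.3, "r", "MEDIUM"),
            (0.5, "r", "STRONG"), (-0.5, "r", "STRONG"),
        ],
    )
    def test_thresholds_inclusive_on_absolute_value(self, value, kind, expected):
        assert effect_label(value, kind) == expected

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            effect_label(0.5, "g")


class TestEffectSizeFormulas:
    def test_d_eta2_r_match_brute_force_on_random_small_data(self):
        """d, eta^2 and r agree with independent textbook arithmetic on 100
        random datasets of n <= 12, to 1e-10."""
        rng = np.random.default_rng(55)
        for _ in range(100):
            n1, n2 = rng.integers(2, 7, 2)
            g1, g2 = rng.normal(0, 1, n1), rng.normal(0.5, 1.5, n2)
            scores = np.concatenate([g1, g2])
            labels = ["a"] * n1 + ["b"] * n2
            res = two_group_compare(scores, labels, ("a", "b"))
            sp = math.sqrt(
                ((n1 - 1) * np.var(g1, ddof=1) + (n2 - 1) * np.var(g2, ddof=1)) / (n1 + n2 - 2)
            )
            assert res.effect_size == pytest.approx((g1.mean() - g2.mean()) / sp, abs=1e-10)
            a_res = one_way_anova(scores, labels)
            grand = scores.mean()
            ssb = n1 * (g1.mean() - grand) ** 2 + n2 * (g2.mean() - grand) ** 2
            sst = ((scores - grand) ** 2).sum()
            assert a_res.effect_size == pytest.approx(ssb / sst, abs=1e-10)
            x, y = rng.normal(size=12), rng.normal(size=12)
            r_res = pearson_assoc(x, y)
            r_manual = (
                ((x - x.mean()) * (y - y.mean())).sum()
                / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            assert r_res.effect_size == pytest.approx(r_manual, abs=1e-10)


class TestBattery:
    def test_children_battery_is_five_by_eleven(self, small_children_cohort):
        scores = score_cohort(small_children_cohort)
        frame = validity_battery(small_children_cohort, scores)
        assert len(frame) == 55
        assert frame["scale"].nunique() == 5
        assert frame["variable"].nunique() == 11

    def test_adolescent_battery_is_four_by_eleven(self):
        cohort = simulate_cohort(SimulationConfig(n_children=0, n_adolescents=250, seed=31))
        scores = score_cohort(cohort)
        frame = validity_battery(cohort, scores)
        assert len(frame) == 44
        assert frame["scale"].nunique() == 4

    def test_cell_n_never_exceeds_pairwise_available(self, small_children_cohort):
        scores = score_cohort(small_children_cohort)
        frame = validity_battery(small_children_cohort, scores)
        variables = {v.name: v for v in derive_convergent(small_children_cohort)}
        defined = ~scores.set_index("id").reindex(
            [r.id for r in small_children_cohort.respondents]
        ).isna()
        for _, row in frame.iterrows():
            have_value = np.array([v is not None for v in variables[row["variable"]].values])
            cap = int((have_value & defined[row["scale"]].to_numpy()).sum())
            assert row["N"] <= cap

    def test_decoupled_benefit_gives_null_calibrated_battery(self):
        """Scores generated independently of the clinical course: about 5%
        of estimable cells significant (80 seeded replicates here; the
        acceptance suite runs the full 1000)."""
        sig = tot = 0
        for rep in range(80):
            cohort = simulate_cohort(
                SimulationConfig(n_children=200, n_adolescents=0, benefit_loading=0.0,
                                 seed=5000 + rep)
            )
            scores = score_cohort(cohort)
            frame = validity_battery(cohort, scores)
            est = frame["estimable"]
            sig += int(frame.loc[est, "significant"].sum())
            tot += int(est.sum())
        assert 0.02 <= sig / tot <= 0.09
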