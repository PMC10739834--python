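"""Permutation tests, Holm correction and effect sizes against independent
oracles (full enumeration, sequential rejection, statsmodels, pingouin)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from veristyle.stats import (AnalysisConfig, cles, cohens_d, compare_groups,
                             holm_adjust, perm_test_independent,
                             perm_test_paired, subject_average)
from veristyle.stylometry import FEATURE_NAMES

FAST = AnalysisConfig(n_permutations=10_000, n_bootstrap=0, seed=1)


class TestPermutationTests:
    def test_identical_groups_give_p_one(self):
        assert perm_test_independent([5, 5, 5], [5, 5, 5], FAST) == 1.0
        assert perm_test_paired([1, 2, 3], [1, 2, 3], FAST) == 1.0

    def test_complete_separation_matches_enumeration(self):
        # exact two-sided p = 2 / C(10,5) ~ 0.0079
        exact = 2 / 252
        p = perm_test_independent([0] * 5, [10] * 5, FAST)
        se = math.sqrt(exact * (1 - exact) / FAST.n_permutations)
        assert abs(p - exact) <= 3 * se + 2 / FAST.n_permutations

    def test_independent_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(2, 3), (3, 3), (4, 4), (2, 8), (5, 5)]:
            x = list(rng.normal(0, 1, n1))
            y = list(rng.normal(0.8, 1, n2))
            p_exact = oracles.enum_p_independent(x, y)
            p_mc = perm_test_independent(x, y, FAST)
            se = math.sqrt(p_exact * (1 - p_exact) / FAST.n_permutations)
            assert abs(p_mc - p_exact) <= 3 * se + 2 / FAST.n_permutations

    def test_paired_matches_sign_flip_oracle(self):
        rng = np.random.default_rng(1)
        for n in [4, 6, 8, 10, 12]:
            x = list(rng.normal(0.5, 1, n))
            y = list(rng.normal(0.0, 1, n))
            p_exact = oracles.enum_p_paired(x, y)
            p_mc = perm_test_paired(x, y, FAST)
            se = math.sqrt(p_exact * (1 - p_exact) / FAST.n_permutations)
            assert abs(p_mc - p_exact) <= 3 * se + 2 / FAST.n_permutations

    def test_constant_difference_pairs(self):
        # exact sign-flip p = 2 / 2^8
        p = perm_test_paired([3] * 8, [0] * 8, FAST)
        assert p == pytest.approx(2 / 256, abs=3 * math.sqrt(0.008 / 10_000) + 2e-4)

    def test_insufficient_group_sizes_raise(self):
        with pytest.raises(ValueError):
            perm_test_independent([1], [2, 3], FAST)
        with pytest.raises(ValueError):
            perm_test_paired([1, 2], [3], FAST)

    def test_type_one_error_calibration(self):
        """Rejection rate on identically distributed groups stays near alpha."""
        cfg = AnalysisConfig(n_permutations=199, n_bootstrap=0, seed=0)
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            rejections += perm_test_independent(x, y, cfg, rng=rng) < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestHolm:
    def test_hand_worked_step_down(self):
        assert holm_adjust([0.001, 0.2, 0.03]) == pytest.approx([0.003, 0.2, 0.06])

    def test_cap_at_one_and_empty(self):
        assert holm_adjust([1.0, 1.0]) == [1.0, 1.0]
        assert holm_adjust([]) == []

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_dominates_raw_and_matches_sequential_rejection(self, p):
        adjusted = holm_adjust(p)
        assert all(a >= r for a, r in zip(adjusted, p))
        alpha = 0.05
        assert {i for i, a in enumerate(adjusted) if a < alpha} == \
            oracles.holm_rejections(p, alpha)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(max_examples=100, derandomize=True)
    def test_rejects_everything_bonferroni_rejects(self, p):
        alpha = 0.05
        m = len(p)
        bonf = {i for i in range(m) if p[i] * m < alpha}
        holm = {i for i, a in enumerate(holm_adjust(p)) if a < alpha}
        assert bonf <= holm

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(1e-4, 1, 26)
        _, adj, _, _ = multipletests(p, method="holm")
        assert holm_adjust(list(p)) == pytest.approx(list(adj))


class TestEffectSizes:
    def test_cles_null_value_with_identical_groups(self):
        point, _ = cles([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], FAST)
        assert point == 0.5

    def test_cles_complete_separation_and_tie_weighting(self):
        assert cles([2, 3], [0, 1], FAST)[0] == 1.0
        assert cles([1, 2, 3], [1, 2, 3], FAST)[0] == (3 + 1.5) / 9

    def test_cles_complementarity(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        assert cles(x, y, FAST)[0] + cles(y, x, FAST)[0] == pytest.approx(1.0)
        xt = np.round(x)  # heavy ties
        yt = np.round(y)
        assert cles(xt, yt, FAST)[0] + cles(yt, xt, FAST)[0] == pytest.approx(1.0)

    def test_cles_ci_brackets_the_point(self):
        cfg = AnalysisConfig(n_bootstrap=500, seed=2)
        rng = np.random.default_rng(2)
        point, (lo, hi) = cles(rng.normal(0.5, 1, 30), rng.normal(0, 1, 30), cfg)
        assert lo <= point <= hi

    def test_cles_agrees_with_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(9)
        x, y = rng.normal(0.4, 1, 25), rng.normal(0, 1, 30)
        expected = pg.compute_effsize(x, y, eftype="CLES")
        assert cles(x, y, FAST)[0] == pytest.approx(float(expected))

    def test_cohens_d_hand_arithmetic_and_antisymmetry(self):
        d, _ = cohens_d([2, 4], [0, 2])
        assert d == pytest.approx(2 / math.sqrt(2))
        d1, (lo1, hi1) = cohens_d([1, 2, 5], [0, 1, 2])
        d2, (lo2, hi2) = cohens_d([0, 1, 2], [1, 2, 5])
        assert d2 == pytest.approx(-d1)
        assert (lo2, hi2) == pytest.approx((-hi1, -lo1))

    def test_cohens_d_zero_and_degenerate(self):
        assert cohens_d([1, 2, 3], [1, 2, 3])[0] == 0.0
        d, ci = cohens_d([1, 1], [1, 1])
        assert math.isnan(d) and all(math.isnan(v) for v in ci)

    def test_cohens_d_agrees_with_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(11)
        x, y = rng.normal(0.6, 1, 40), rng.normal(0, 1, 35)
        expected = pg.compute_effsize(x, y, eftype="cohen")
        assert cohens_d(x, y)[0] == pytest.approx(float(expected))


class TestSubjectAverage:
    def _frame(self, rows):
        return pd.DataFrame(rows)

    def test_arithmetic_means_per_subject(self):
        frame = self._frame([
            {"subject_id": "a", "veracity": "truthful", "f": 2.0},
            {"subject_id": "a", "veracity": "truthful", "f": 4.0},
            {"subject_id": "a", "veracity": "deceptive", "f": 1.0},
        ])
        truthful, deceptive, excluded = subject_average(frame, ["f"])
        assert truthful.loc["a", "f"] == 3.0
        assert deceptive.loc["a", "f"] == 1.0
        assert excluded == []

    def test_subject_missing_a_group_is_excluded(self):
        frame = self._frame([
            {"subject_id": "a", "veracity": "truthful", "f": 2.0},
            {"subject_id": "a", "veracity": "deceptive", "f": 1.0},
            {"subject_id": "b", "veracity": "truthful", "f": 9.0},
        ])
        truthful, _, excluded = subject_average(frame, ["f"])
        assert list(truthful.index) == ["a"]
        assert excluded == ["b"]

    def test_nan_cells_drop_pairs_per_feature_only(self):
        frame = self._frame([
            {"subject_id": "a", "veracity": "truthful", "f": np.nan, "g": 1.0},
            {"subject_id": "a", "veracity": "deceptive", "f": 2.0, "g": 2.0},
        ])
        truthful, deceptive, _ = subject_average(frame, ["f", "g"])
        assert math.isnan(truthful.loc["a", "f"])
        assert truthful.loc["a", "g"] == 1.0


class TestCompareGroups:
    def _matrix(self, rng, n_per_class, shift_feature=None, delta=0.0):
        data = rng.normal(size=(2 * n_per_class, len(FEATURE_NAMES)))
        frame = pd.DataFrame(data, columns=FEATURE_NAMES)
        frame["veracity"] = (["truthful"] * n_per_class
                             + ["deceptive"] * n_per_class)
        if shift_feature:
            frame.loc[frame["veracity"] == "truthful", shift_feature] += delta
        return frame

    def test_planted_shift_survives_holm_null_features_mostly_do_not(self):
        rng = np.random.default_rng(0)
        frame = self._matrix(rng, 100, "Self_reference", 1.5)
        cfg = AnalysisConfig(n_permutations=999, n_bootstrap=0, seed=4)
        results = {r.feature: r for r in compare_groups(frame, "independent", cfg)}
        assert results["Self_reference"].significant
        assert results["Self_reference"].direction == "higher_in_truthful"
        null_hits = sum(r.significant for f, r in results.items()
                        if f != "Self_reference")
        assert null_hits <= 2

    def test_constant_feature_contract(self):
        rng = np.random.default_rng(1)
        frame = self._matrix(rng, 10)
        frame["Tone"] = 50.0
        cfg = AnalysisConfig(n_permutations=199, n_bootstrap=0, seed=0)
        res = {r.feature: r for r in compare_groups(frame, "independent", cfg)}
        tone = res["Tone"]
        assert tone.p_raw == 1.0 and tone.effect.cles == 0.5
        assert tone.effect.d == 0.0 and tone.direction == "none"

    def test_adjusted_dominates_raw_and_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        frame = self._matrix(rng, 15)
        cfg = AnalysisConfig(n_permutations=199, n_bootstrap=50, seed=9)
        res1 = compare_groups(frame, "independent", cfg)
        res2 = compare_groups(frame, "independent", cfg)
        assert res1 == res2
        assert all(r.p_adjusted >= r.p_raw for r in res1)
        assert all(r.significant == (r.p_adjusted < cfg.alpha) for r in res1)

    def test_paired_design_detects_within_subject_shift(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(40):
            base = rng.normal(size=len(FEATURE_NAMES))
            for veracity, offset in (("truthful", 1.0), ("deceptive", 0.0)):
                vec = base + rng.normal(scale=0.5, size=len(FEATURE_NAMES))
                row = dict(zip(FEATURE_NAMES, vec))
                row["Self_reference"] += offset
                row.update(subject_id=f"s{s}", veracity=veracity)
                rows.append(row)
        frame = pd.DataFrame(rows)
        cfg = AnalysisConfig(n_permutations=999, n_bootstrap=0, seed=5)
        res = {r.feature: r for r in compare_groups(frame, "paired_by_subject", cfg)}
        assert res["Self_reference"].significant
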