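"""SAM statistics, rank tests, correlation matrices, lesion and overlap scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

from msub.stats import (
    bh_adjust,
    fraction_percent,
    lesion_overlap_association,
    lesion_score,
    load_tcell_signature,
    overlap_index,
    patient_correlation_matrix,
    random_overlap_index,
    sam_test,
    tcell_score,
    wilcoxon_rank_sum,
    TCELL_SIGNATURE,
)


class TestSam:
    def _matrix(self, rng, n_features=200, n_per=15, shift_features=0, shift=0.0):
        X = rng.normal(0, 1, size=(n_features, 2 * n_per))
        X[:shift_features, n_per:] += shift
        labels = ["g1"] * n_per + ["g2"] * n_per
        return pd.DataFrame(X), labels

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        df, labels = self._matrix(rng)
        res1 = sam_test(df, labels, n_permutations=60, seed=1)
        swapped = ["g2" if l == "g1" else "g1" for l in labels]
        res2 = sam_test(df, swapped, n_permutations=60, seed=1)
        np.testing.assert_allclose(res1.table["d"], -res2.table["d"], atol=1e-12)

    def test_null_features_have_high_q(self):
        rng = np.random.default_rng(1)
        df, labels = self._matrix(rng, n_features=300, n_per=30)
        res = sam_test(df, labels, n_permutations=100, seed=0)
        assert (res.table["q"] > 0.5).mean() >= 0.95

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(2)
        df, labels = self._matrix(
            rng, n_features=1000, n_per=30, shift_features=50, shift=2.0
        )
        res = sam_test(df, labels, n_permutations=100, seed=0)
        planted_q = res.table["q"].iloc[:50]
        assert (planted_q < 0.1).mean() >= 0.8

    def test_matches_pooled_t_when_s0_zero(self):
        rng = np.random.default_rng(3)
        df, labels = self._matrix(rng, n_features=50, n_per=10)
        res = sam_test(df, labels, n_permutations=50, seed=0, s0=0.0)
        t_oracle = ttest_ind(
            df.iloc[:, :10], df.iloc[:, 10:], axis=1, equal_var=True
        ).statistic
        np.testing.assert_allclose(res.table["d"], t_oracle, atol=1e-10)

    def test_few_permutations_warn(self):
        rng = np.random.default_rng(4)
        df, labels = self._matrix(rng, n_features=20, n_per=5)
        with pytest.warns(UserWarning, match="unstable"):
            sam_test(df, labels, n_permutations=10, seed=0)


class TestWilcoxon:
    def test_extreme_split_matches_enumeration(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        # enumeration oracle over all 20 rank splits
        ranks = range(1, 7)
        observed = 1 + 2 + 3
        more_extreme = 0
        total = 0
        for combo in itertools.combinations(ranks, 3):
            total += 1
            s = sum(combo)
            if abs(s - 10.5) >= abs(observed - 10.5):  # 10.5 = null mean rank sum
                more_extreme += 1
        assert p == pytest.approx(more_extreme / total, abs=1e-12)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_large_planted_shift(self):
        rng = np.random.default_rng(0)
        _, p = wilcoxon_rank_sum(rng.normal(0, 1, 100), rng.normal(3, 1, 100))
        assert p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestPatientCorrelation:
    def test_identical_and_negated_profiles(self):
        rng = np.random.default_rng(1)
        prof = rng.random(10)
        a = pd.DataFrame({"s1": prof})
        b = pd.DataFrame({"v1": prof, "v2": 1 - prof})  # negation after centering
        R = patient_correlation_matrix(a, b)
        assert R.loc["v1", "s1"] == pytest.approx(1.0)
        assert R.loc["v2", "s1"] == pytest.approx(-1.0)

    def test_independent_profiles_uncorrelated(self):
        rng = np.random.default_rng(2)
        feats = [f"cg{i}" for i in range(621)]
        a = pd.DataFrame(rng.random((621, 10)), index=feats)
        b = pd.DataFrame(rng.random((621, 10)), index=feats)
        R = patient_correlation_matrix(a, b)
        assert np.abs(R.to_numpy()).mean() < 0.1

    def test_zero_variance_profile_is_nan(self):
        feats = ["f1", "f2", "f3"]
        a = pd.DataFrame({"s1": [0.5, 0.5, 0.5]}, index=feats)
        b = pd.DataFrame({"v1": [0.1, 0.5, 0.9]}, index=feats)
        with pytest.warns(UserWarning, match="zero-variance"):
            R = patient_correlation_matrix(a, b)
        assert np.isnan(R.loc["v1", "s1"])

    def test_too_few_shared_features_rejected(self):
        a = pd.DataFrame({"s1": [0.5, 0.6]}, index=["f1", "f2"])
        with pytest.raises(ValueError, match="shared"):
            patient_correlation_matrix(a, a)


class TestLesionScore:
    @pytest.mark.parametrize("n_mut,gistic,expected", [(1, -1, 2), (0, 0, 0), (2, -2, 4)])
    def test_literal_formula(self, n_mut, gistic, expected):
        assert lesion_score(n_mut, gistic) == expected

    def test_amplification_warns(self):
        with pytest.warns(UserWarning, match="negatively"):
            assert lesion_score(0, 2) == -2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lesion_score(1, 3)
        with pytest.raises(ValueError):
            lesion_score(-1, 0)


class TestOverlapIndex:
    def test_set_arithmetic(self):
        assert overlap_index({"a", "b", "c", "d"}, {"b", "d", "z"}) == pytest.approx(0.5)
        assert overlap_index({"a"}, {"z"}) == 0.0
        assert overlap_index({"a", "b"}, {"a", "b", "c"}) == 1.0

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        universe = [f"cg{i}" for i in range(50)]
        hypo = set(rng.choice(universe, 12, replace=False))
        sig = set(rng.choice(universe, 20, replace=False))
        brute = sum(1 for c in hypo if c in sig) / len(hypo)
        assert overlap_index(hypo, sig) == pytest.approx(brute, abs=1e-15)

    def test_ordering_invariance(self):
        hypo = ["c", "a", "b"]
        sig = ["b", "c"]
        assert overlap_index(hypo, sig) == overlap_index(sorted(hypo), reversed(sig))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_index(set(), {"a"})


class TestRandomOverlapIndex:
    def test_degenerate_sizes(self):
        universe = [f"cg{i}" for i in range(30)]
        hypo = set(universe[:5])
        assert random_overlap_index(hypo, universe, m=30, seed=0) == 1.0
        assert random_overlap_index(hypo, universe, m=0, seed=0) == 0.0

    def test_expectation_matches_hypergeometric(self):
        universe = [f"cg{i}" for i in range(100)]
        hypo = set(universe[:10])
        vals = [
            random_overlap_index(hypo, universe, m=20, n_draws=10, seed=s)
            for s in range(200)
        ]
        # E[index] = m/N; SE of the mean over 200x10 draws
        expectation = 20 / 100
        per_draw_sd = np.sqrt(expectation * (1 - expectation) / 10)
        se = per_draw_sd / np.sqrt(200 * 10)
        assert abs(np.mean(vals) - expectation) <= 3 * per_draw_sd / np.sqrt(200)

    def test_oversized_signature_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            random_overlap_index({"a"}, ["a", "b"], m=3)


class TestLesionOverlapAssociation:
    def test_exact_linear_relationship(self):
        scores = np.array([0, 1, 2, 3, 4] * 4)
        slope, p = lesion_overlap_association(scores, 0.1 * scores)
        assert slope == pytest.approx(0.1, abs=1e-12)
        assert p < 1e-10

    def test_null_calibration(self):
        rejections = 0
        n_seeds = 500
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            x = rng.integers(0, 4, 100).astype(float)
            y = rng.random(100)
            _, p = lesion_overlap_association(x, y)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.08

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lesion_overlap_association([1, 1, 1], [0.1, 0.2, 0.3])


class TestTcellScore:
    def test_constant_signature(self):
        expr = pd.DataFrame(5.0, index=list(TCELL_SIGNATURE), columns=["s1", "s2"])
        assert (tcell_score(expr) == 5.0).all()

    def test_single_present_gene(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 9.9], "s2": [2.0, 9.9]}, index=["CD8A", "OTHER"]
        ).astype(float)
        out = tcell_score(expr)
        assert out["s1"] == 1.0 and out["s2"] == 2.0

    def test_no_genes_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["NOT_A_GENE"])
        with pytest.raises(ValueError, match="signature"):
            tcell_score(expr)

    def test_packaged_list_matches_constant(self):
        assert load_tcell_signature() == list(TCELL_SIGNATURE)


class TestFractionPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(24, 42, 57), (21, 33, 64), (0, 10, 0), (99, 269, 37), (1, 8, 13)],
    )
    def test_half_up_rounding(self, num, den, expected):
        assert fraction_percent(num, den) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fraction_percent(1, 0)
        with pytest.raises(ValueError):
            fraction_percent(5, 4)


def test_bh_adjust_monotone():
    p = np.array([0.001, 0.02, 0.5, 0.9])
    q = bh_adjust(p)
    assert (np.diff(q[np.argsort(p)]) >= 0).all()
    assert (q >= p).all()
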