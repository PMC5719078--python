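"""Beta-mixture fitting, DM values, expression coupling and state calling."""

import numpy as np
import pandas as pd
import pytest

from msub.mixture import (
    BetaMixtureFit,
    _em,
    _quantile_init,
    EPS_CLAMP,
    call_states,
    compute_dm,
    count_hypo_per_patient,
    expression_coupling,
    fit_beta_mixture,
)
from msub.stats import wilcoxon_rank_sum


class TestFitBetaMixture:
    def test_unimodal_selects_one_component(self):
        rng = np.random.default_rng(0)
        x = rng.beta(0.5 * 60, 0.5 * 60, 100)  # tight around 0.5
        fit = fit_beta_mixture(x, seed=0)
        assert fit.K == 1
        assert fit.means[0] == pytest.approx(x.mean(), abs=0.03)

    def test_bimodal_recovers_component_means(self):
        rng = np.random.default_rng(1)
        lo = rng.beta(0.1 * 40, 0.9 * 40, 100)
        hi = rng.beta(0.8 * 40, 0.2 * 40, 100)
        fit = fit_beta_mixture(np.concatenate([lo, hi]), seed=0)
        assert fit.K == 2
        # oracle: sample means under the true component labels
        assert fit.means[0] == pytest.approx(lo.mean(), abs=0.05)
        assert fit.means[1] == pytest.approx(hi.mean(), abs=0.05)
        assert fit.pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_beta_mixture(np.full(5, 0.5))

    def test_shapes_positive_and_means_interior(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            x = rng.beta(2, 5, 60)
            fit = fit_beta_mixture(x, seed=seed)
            assert (fit.alpha > 0).all() and (fit.beta > 0).all()
            assert ((fit.means > 0) & (fit.means < 1)).all()
            assert fit.pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_loglik_nondecreasing_over_em_iterations(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.beta(4, 16, 80), rng.beta(16, 4, 80)])
        x = np.clip(x, EPS_CLAMP, 1 - EPS_CLAMP)
        lx, l1x = np.log(x), np.log1p(-x)
        for K in (1, 2, 3):
            alpha, beta, pi = _quantile_init(x, K)
            trace = []
            _em(x, lx, l1x, alpha, beta, pi, trace=trace)
            diffs = np.diff(trace)
            assert (diffs >= -1e-8).all()

    def test_component_relabelling_does_not_change_assignment_means(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.beta(4, 16, 60), rng.beta(16, 4, 60)])
        fit = fit_beta_mixture(x, seed=0)
        flipped = BetaMixtureFit(
            fit.alpha[::-1].copy(), fit.beta[::-1].copy(), fit.pi[::-1].copy(),
            fit.loglik, fit.n,
        )
        np.testing.assert_allclose(
            fit.means[fit.assign(x)], flipped.means[flipped.assign(x)], atol=1e-12
        )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.beta(3, 12, 50), rng.beta(12, 3, 50)])
        f1 = fit_beta_mixture(x, seed=9)
        f2 = fit_beta_mixture(x, seed=9)
        np.testing.assert_array_equal(f1.alpha, f2.alpha)
        np.testing.assert_array_equal(f1.pi, f2.pi)


class TestComputeDm:
    def test_arithmetic(self):
        fit = BetaMixtureFit(np.array([3.0]), np.array([7.0]), np.array([1.0]), 0.0, 10)
        assert compute_dm(fit, [0.7, 0.7])[0] == pytest.approx(-0.4)

    def test_zero_when_equal(self):
        fit = BetaMixtureFit(np.array([7.0]), np.array([3.0]), np.array([1.0]), 0.0, 10)
        assert compute_dm(fit, [0.7])[0] == pytest.approx(0.0)

    def test_two_components_symmetric(self):
        fit = BetaMixtureFit(
            np.array([2.0, 8.0]), np.array([8.0, 2.0]), np.array([0.5, 0.5]), 0.0, 10
        )
        np.testing.assert_allclose(compute_dm(fit, [0.5]), [-0.3, 0.3], atol=1e-12)

    def test_empty_normal_vector_rejected(self):
        fit = BetaMixtureFit(np.array([3.0]), np.array([7.0]), np.array([1.0]), 0.0, 10)
        with pytest.raises(ValueError, match="empty"):
            compute_dm(fit, [])


class TestExpressionCoupling:
    def test_exact_inverse_passes(self):
        meth = np.linspace(0.1, 0.9, 20)
        r, p, passes = expression_coupling(meth, -meth)
        assert r == pytest.approx(-1.0)
        assert passes

    def test_independent_expression_rarely_passes(self):
        # planted null: coupling should fail in nearly every replicate
        fails = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            meth = rng.beta(5, 5, 200)
            expr = rng.normal(6, 1, 200)
            _, _, passes = expression_coupling(meth, expr)
            fails += not passes
        assert fails / n_seeds >= 0.95

    def test_constant_expression_warns(self):
        meth = np.linspace(0.1, 0.9, 20)
        with pytest.warns(UserWarning, match="zero variance"):
            r, p, passes = expression_coupling(meth, np.full(20, 5.0))
        assert not passes and np.isnan(r)

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            expression_coupling([0.1] * 5, [1.0] * 5)


class TestCallStates:
    def test_planted_hypo_gene_called_for_carriers(self, small_states):
        cohort, truth, cmap, cluster_beta, states, calls = small_states
        planted = set(truth.planted_hypo_genes(0))
        abnormal_genes = set(calls.loc[calls["is_abnormal"], "gene"])
        # most planted genes are recovered as abnormal hypomethylated
        assert len(planted & abnormal_genes) / len(planted) >= 0.8
        # carriers of the planted subtype are predominantly in the hypo state
        subtype0 = truth.samples.index[truth.samples["subtype"] == 0]
        planted_clusters = [
            cid for cid in states.states.index if cmap.gene_of[cid] in planted
        ]
        frac_hypo = (
            (states.states.loc[planted_clusters, subtype0] == "hypo").to_numpy().mean()
        )
        assert frac_hypo >= 0.7

    def test_flat_gene_not_abnormal(self):
        rng = np.random.default_rng(0)
        samples = [f"t{i}" for i in range(60)] + [f"n{i}" for i in range(20)]
        beta = pd.DataFrame(
            {s: [rng.beta(12, 12)] for s in samples}, index=["G1--cluster--1"]
        )
        group = pd.Series(["tumor"] * 60 + ["normal"] * 20, index=samples)
        expr = pd.DataFrame(
            rng.normal(5, 1, (1, 60)), index=["G1"], columns=samples[:60]
        )
        states, calls = call_states(beta, group, expr, {"G1--cluster--1": "G1"})
        assert not calls["is_abnormal"].any()

    def test_uncoupled_expression_blocks_abnormal_call(self):
        rng = np.random.default_rng(1)
        tumor = [f"t{i}" for i in range(80)]
        normal = [f"n{i}" for i in range(20)]
        # half the tumors hypomethylated, but expression independent
        tvals = np.concatenate([rng.beta(6, 24, 40), rng.beta(21, 9, 40)])
        nvals = rng.beta(21, 9, 20)
        beta = pd.DataFrame(
            [np.concatenate([tvals, nvals])], index=["G1--cluster--1"],
            columns=tumor + normal,
        )
        group = pd.Series(["tumor"] * 80 + ["normal"] * 20, index=tumor + normal)
        expr = pd.DataFrame([rng.normal(5, 1, 80)], index=["G1"], columns=tumor)
        states, calls = call_states(beta, group, expr, {"G1--cluster--1": "G1"})
        assert not calls["is_abnormal"].any()
        assert len(states.states) == 0


class TestHypoCounts:
    def test_trivial_counts(self):
        df = pd.DataFrame(
            [["normal", "hypo"], ["normal", "hypo"], ["normal", "hypo"]],
            columns=["s1", "s2"],
        )
        counts = count_hypo_per_patient(df)
        assert counts["s1"] == 0 and counts["s2"] == 3

    def test_planted_subtype_has_elevated_counts(self, small_states):
        cohort, truth, cmap, cluster_beta, states, calls = small_states
        counts = count_hypo_per_patient(states)
        subtype = truth.subtype_of().reindex(counts.index)
        in0 = counts[subtype == 0]
        out0 = counts[subtype != 0]
        assert in0.mean() > out0.mean()
        _, p = wilcoxon_rank_sum(in0, out0)
        assert p < 0.01
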