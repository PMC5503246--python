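import numpy as np
import pytest
from scipy import stats

from cumimpact import (
    Factor,
    FactorGroup,
    FactorSpace,
    SobolPlan,
    beta_from_mode_confidence,
    build_factor_space,
    compute_ci,
    make_known_truth_case,
    run_model_batch,
    saltelli_sample,
    sobol_indices,
    ua_summaries,
)


def uniform_space(k):
    return FactorSpace([
        FactorGroup(f"x{i+1}", (Factor.uniform(f"x{i+1}", 0, 1),)) for i in range(k)
    ])


class TestBetaFromModeConfidence:
    def test_zero_confidence_uniform(self):
        assert beta_from_mode_confidence(0.3, 0.0) == (1.0, 1.0)

    @pytest.mark.parametrize("m", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("c", [0.2, 0.6, 1.0])
    def test_mode_identity(self, m, c):
        a, b = beta_from_mode_confidence(m, c)
        assert (a - 1) / (a + b - 2) == pytest.approx(m)

    def test_symmetric_at_central_mode(self):
        a, b = beta_from_mode_confidence(0.5, 1.0, K=18.0)
        assert a == b == pytest.approx(1 + 9.0)

    def test_variance_decreasing_in_confidence(self):
        variances = [stats.beta(*beta_from_mode_confidence(0.4, c)).var()
                     for c in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(np.diff(variances) < 0)

    def test_empirical_mode_matches(self):
        a, b = beta_from_mode_confidence(0.7, 0.8)
        rng = np.random.default_rng(0)
        draws = rng.beta(a, b, 1_000_000)
        hist, edges = np.histogram(draws, bins=100, range=(0, 1))
        empirical_mode = (edges[hist.argmax()] + edges[hist.argmax() + 1]) / 2
        assert abs(empirical_mode - 0.7) < 0.02


class TestSampling:
    def test_run_count_matches_design_cost(self):
        space = uniform_space(4)
        sample = saltelli_sample(space, SobolPlan(1500, k=4, seed=0))
        assert sample.values.shape == (15_000, 4)

    def test_values_within_declared_ranges(self):
        space = FactorSpace([
            FactorGroup("SC", (Factor.beta("s", 0.6, 0.5),)),
            FactorGroup("D", (Factor.beta("d", 0.2, 0.5, scale=50.0),)),
            FactorGroup("MSCF", (Factor.uniform("mscf", 0, 1),)),
            FactorGroup("RF", (Factor.uniform("nr", 0, 1), Factor.uniform("sr", 0.3, 0.7))),
        ])
        sample = saltelli_sample(space, SobolPlan(256, k=4, seed=1))
        v = sample.values
        assert v[:, 0].min() >= 0 and v[:, 0].max() <= 1
        assert v[:, 1].min() >= 0 and v[:, 1].max() <= 50
        assert v[:, 3].min() >= 0 and v[:, 3].max() <= 1
        assert v[:, 4].min() >= 0.3 and v[:, 4].max() <= 0.7

    def test_same_seed_identical(self):
        space = uniform_space(3)
        plan = SobolPlan(128, k=3, seed=42)
        a = saltelli_sample(space, plan).values
        b = saltelli_sample(space, plan).values
        np.testing.assert_array_equal(a, b)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            saltelli_sample(FactorSpace([]), SobolPlan(16, k=1, seed=0))


class TestEstimators:
    def test_single_active_factor(self):
        space = uniform_space(4)
        plan = SobolPlan(2048, k=4, seed=2)
        X = saltelli_sample(space, plan).values
        Y = X[:, [0]]  # f = x1
        res = sobol_indices(Y, plan, group_names=["x1", "x2", "x3", "x4"])
        assert res.s1["x1"][0] == pytest.approx(1.0, abs=0.02)
        for other in ("x2", "x3", "x4"):
            assert abs(res.st[other][0]) < 0.02

    def test_additive_four_factor_decomposition(self):
        space = uniform_space(4)
        plan = SobolPlan(2048, k=4, seed=3)
        X = saltelli_sample(space, plan).values
        Y = X.sum(axis=1, keepdims=True)
        res = sobol_indices(Y, plan, group_names=["a", "b", "c", "d"])
        for g in ("a", "b", "c", "d"):
            assert res.s1[g][0] == pytest.approx(0.25, abs=0.02)
        assert (res.s2_pairs.s2_mean_pct.abs() <= 2.0).all()

    def test_matches_closed_form_with_interaction(self):
        # f = x1 + 2*x2 + x3*x4: V1=1/12, V2=4/12, V3=V4=1/48, V34=1/144
        space = uniform_space(4)
        plan = SobolPlan(2**13, k=4, seed=4)
        X = saltelli_sample(space, plan).values
        Y = (X[:, 0] + 2 * X[:, 1] + X[:, 2] * X[:, 3])[:, None]
        res = sobol_indices(Y, plan, group_names=["x1", "x2", "x3", "x4"])
        V = 1 / 12 + 4 / 12 + 1 / 48 + 1 / 48 + 1 / 144
        assert res.s1["x1"][0] == pytest.approx((1 / 12) / V, abs=0.02)
        assert res.s1["x2"][0] == pytest.approx((4 / 12) / V, abs=0.02)
        assert res.s1["x3"][0] == pytest.approx((1 / 48) / V, abs=0.02)
        assert res.st["x3"][0] == pytest.approx((1 / 48 + 1 / 144) / V, abs=0.02)
        s2_34 = res.s2_pairs.query("group_i == 'x3' and group_j == 'x4'").s2_mean_pct.iloc[0]
        assert s2_34 / 100 == pytest.approx((1 / 144) / V, abs=0.02)

    def test_agrees_with_double_loop_oracle(self):
        """Saltelli estimates vs brute-force conditional-variance decomposition."""
        def f(x):
            return x[..., 0] + 2 * x[..., 1] + x[..., 2] * x[..., 3]

        rng = np.random.default_rng(5)
        M_outer, M_inner = 400, 400
        V = f(rng.random((200_000, 4))).var()
        brute_s1 = []
        for g in range(4):
            outer = rng.random(M_outer)
            cond = np.empty(M_outer)
            for i, xg in enumerate(outer):
                pts = rng.random((M_inner, 4))
                pts[:, g] = xg
                cond[i] = f(pts).mean()
            brute_s1.append((cond.var() - V / M_inner) / V)

        space = uniform_space(4)
        plan = SobolPlan(2**12, k=4, seed=6)
        X = saltelli_sample(space, plan).values
        res = sobol_indices(f(X)[:, None], plan, group_names=["a", "b", "c", "d"])
        for g, name in enumerate(["a", "b", "c", "d"]):
            assert res.s1[name][0] == pytest.approx(brute_s1[g], abs=0.03)

    def test_st_geq_s1(self):
        space = uniform_space(4)
        plan = SobolPlan(2**13, k=4, seed=7)
        X = saltelli_sample(space, plan).values
        a = np.array([0.0, 0.5, 3.0, 9.0])
        Y = np.prod((np.abs(4 * X - 2) + a) / (1 + a), axis=1)[:, None]
        res = sobol_indices(Y, plan, group_names=list("wxyz"))
        for g in "wxyz":
            assert res.st[g][0] >= res.s1[g][0] - 0.02

    def test_mismatched_run_count_rejected(self):
        plan = SobolPlan(64, k=4, seed=0)
        with pytest.raises(ValueError):
            sobol_indices(np.zeros((100, 3)), plan)


class TestModelBatch:
    def test_degenerate_distributions_reproduce_baseline(self):
        ds, _ = make_known_truth_case("single_driver")
        baseline = compute_ci(ds)
        space = build_factor_space(ds, baseline, sample_groups=())
        plan = SobolPlan(4, k=4, seed=0)
        Y = run_model_batch(ds, saltelli_sample(space, plan))
        base_vals = baseline.ci_map.values[ds.grid.valid_mask]
        base_vals = base_vals / base_vals.max()
        for row in Y:
            np.testing.assert_allclose(row, base_vals, atol=1e-12)

    def test_outputs_in_unit_interval(self):
        ds, exp = make_known_truth_case("mscf_sensitive")
        baseline = compute_ci(ds)
        space = build_factor_space(ds, baseline, sample_groups=exp["sampled_groups"])
        Y = run_model_batch(ds, saltelli_sample(space, SobolPlan(8, k=4, seed=1)))
        assert Y.min() >= 0 and Y.max() <= 1 + 1e-12

    def test_statelessness_row_order(self):
        ds, _ = make_known_truth_case("single_driver")
        baseline = compute_ci(ds)
        space = build_factor_space(ds, baseline, sample_groups=("MSCF", "RF"))
        sample = saltelli_sample(space, SobolPlan(4, k=4, seed=2))
        Y_full = run_model_batch(ds, sample)
        # re-evaluate a permuted copy: same rows give same outputs
        import copy
        perm = np.arange(sample.values.shape[0])[::-1]
        shuffled = copy.copy(sample)
        shuffled.values = sample.values[perm]
        Y_perm = run_model_batch(ds, shuffled)
        np.testing.assert_allclose(Y_perm, Y_full[perm], atol=1e-12)

    def test_factor_space_defaults(self):
        ds, _ = make_known_truth_case("single_driver")
        baseline = compute_ci(ds)
        space = build_factor_space(ds, baseline, top_m=60)
        by_name = {g.name: g for g in space.groups}
        assert set(by_name) == {"SC", "D", "MSCF", "RF"}
        assert by_name["SC"].dim == len(ds.sensitivities)  # clamped to triple count
        assert by_name["MSCF"].dim == 1 and by_name["RF"].dim == 2


class TestUASummaries:
    def test_identical_runs_degenerate(self):
        runs = np.tile(np.array([[0.1, 0.5, 0.9, 0.3]]), (10, 1))
        ua = ua_summaries(runs)
        np.testing.assert_allclose(ua.cv, 0.0, atol=1e-12)
        for t in (25, 10):
            assert set(np.unique(ua.freq_most[t])) <= {0.0, 1.0}
            assert set(np.unique(ua.freq_least[t])) <= {0.0, 1.0}

    def test_cv_hand_computation(self):
        # per-cell runs {1, 3}: population std 1, mean 2 -> CV 0.5
        runs = np.array([[1.0, 1.0, 2.0], [3.0, 3.0, 2.0]])
        ua = ua_summaries(runs)
        assert ua.cv[0] == pytest.approx(0.5)
        assert ua.cv[2] == pytest.approx(0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        runs = rng.random((40, 50))
        ua1 = ua_summaries(runs)
        ua2 = ua_summaries(runs * 13.7)
        np.testing.assert_allclose(ua1.cv, ua2.cv, atol=1e-12)
        for t in (25, 10):
            np.testing.assert_array_equal(ua1.freq_most[t], ua2.freq_most[t])
            np.testing.assert_array_equal(ua1.freq_least[t], ua2.freq_least[t])

    def test_frequencies_are_fractions(self):
        rng = np.random.default_rng(9)
        runs = rng.random((30, 64))
        ua = ua_summaries(runs)
        for t in (25, 10):
            assert ua.freq_most[t].min() >= 0 and ua.freq_most[t].max() <= 1

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            ua_summaries(np.ones((1, 5)))
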