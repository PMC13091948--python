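import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tinntraj as tj
from tinntraj.lcgmm_core import ModelData, SplineBasisSpec


def make_model_data(y_by_subject, days_by_subject, basis_df=3):
    """Assemble a ModelData directly from per-subject (days, values) arrays."""
    rows = []
    for sid, (days, ys) in enumerate(zip(days_by_subject, y_by_subject)):
        rows.append(
            pd.DataFrame(
                {"subject_id": f"s{sid:03d}", "item": "y", "day": days, "value": ys}
            )
        )
    sm = pd.concat(rows, ignore_index=True)
    return tj.build_model_data(sm, "y", basis=SplineBasisSpec(df=basis_df))


class TestNcsBasis:
    def test_df1_is_linear(self):
        spec = SplineBasisSpec(df=1).resolve(np.linspace(0, 1, 50))
        B = tj.ncs_basis(np.linspace(0, 1, 50), spec)
        assert B.shape == (50, 1)
        np.testing.assert_allclose(np.diff(B[:, 0], 2), 0, atol=1e-12)

    def test_linear_beyond_boundary_knots(self):
        """Second differences vanish outside the boundary (natural condition)."""
        spec = SplineBasisSpec(df=3, boundary_knots=(0.3, 0.7)).resolve(
            np.linspace(0.3, 0.7, 10)
        )
        x_out = np.linspace(0.7, 0.71, 20)
        B = tj.ncs_basis(x_out, spec)
        for j in range(B.shape[1]):
            np.testing.assert_allclose(np.diff(B[:, j], 2), 0, atol=1e-9)

    def test_continuity_at_knots(self):
        spec = SplineBasisSpec(df=3).resolve(np.linspace(0, 1, 100))
        x = np.linspace(0, 1, 2001)
        B = tj.ncs_basis(x, spec)
        assert np.all(np.abs(np.diff(B, axis=0)) < 0.01)

    def test_spans_same_space_as_reference_cr_basis(self):
        """Independent construction: patsy's natural cubic regression basis
        on the same knots spans the same function space."""
        patsy = pytest.importorskip("patsy")
        x = np.linspace(0, 1, 200)
        spec = SplineBasisSpec(df=3).resolve(x)
        ours = np.column_stack([np.ones_like(x), tj.ncs_basis(x, spec)])
        knots = spec.all_knots
        theirs = patsy.dmatrix(
            "cr(x, knots=k[1:-1], lower_bound=k[0], upper_bound=k[-1])",
            {"x": x, "k": knots},
            return_type="matrix",
        )
        theirs = np.asarray(theirs)
        # projection of each reference column onto our column space is exact
        proj, *_ = np.linalg.lstsq(ours, theirs, rcond=None)
        np.testing.assert_allclose(ours @ proj, theirs, atol=1e-8)

    def test_day_outside_tolerance_rejected(self):
        spec = SplineBasisSpec(df=3).resolve(np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            tj.ncs_basis(np.array([2.0]), spec)

    def test_wrong_knot_count_rejected(self):
        with pytest.raises(ValueError):
            SplineBasisSpec(df=3, interior_knots=[0.2, 0.4, 0.6])

    def test_df0_rejected(self):
        with pytest.raises(ValueError):
            SplineBasisSpec(df=0)


class TestCsLoglik:
    def test_standard_normal_point(self):
        assert tj.cs_loglik([0.0], [0.0], 0.0, 1.0) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_diagonal_limit_matches_independent_normals(self, rng):
        y = rng.normal(50, 10, 8)
        mu = rng.normal(50, 5, 8)
        expected = stats.norm.logpdf(y, mu, 3.0).sum()
        assert tj.cs_loglik(y, mu, 0.0, 3.0) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_multivariate_normal(self, seed):
        """Oracle: explicit compound-symmetry covariance matrix."""
        r = np.random.default_rng(seed)
        n = r.integers(1, 11)
        y = r.normal(40, 15, n)
        mu = r.normal(40, 10, n)
        sb, se = r.uniform(0.1, 10), r.uniform(0.5, 10)
        cov = sb**2 * np.ones((n, n)) + se**2 * np.eye(n)
        expected = stats.multivariate_normal.logpdf(y, mean=mu, cov=cov)
        assert abs(tj.cs_loglik(y, mu, sb, se) - expected) < 1e-8

    def test_nonpositive_residual_variance_rejected(self):
        with pytest.raises(ValueError):
            tj.cs_loglik([1.0], [0.0], 1.0, 0.0)


@pytest.fixture(scope="module")
def tiny_data():
    r = np.random.default_rng(3)
    days = [np.arange(0, 84, 3)] * 12
    ys = [50 + r.normal(0, 5) + r.normal(0, 4, len(d)) for d in days]
    return make_model_data(ys, days)


class TestMixtureLoglik:
    def test_single_class_equals_lmm_loglik(self, tiny_data):
        params = tj.LCGMMParams(
            beta=np.array([[50.0, 1.0, 0.5, -0.5]]), sigma_b=5.0, sigma_eps=4.0,
            pi=np.array([1.0]),
        )
        direct = 0.0
        for i in range(tiny_data.n_subjects):
            m = tiny_data.subj_idx == i
            direct += tj.cs_loglik(
                tiny_data.y[m], tiny_data.X[m] @ params.beta[0], 5.0, 4.0
            )
        assert tj.mixture_loglik(tiny_data, params) == pytest.approx(direct)

    def test_duplicate_class_collapses(self, tiny_data):
        beta = np.array([50.0, 1.0, 0.5, -0.5])
        one = tj.LCGMMParams(beta[None], 5.0, 4.0, np.array([1.0]))
        two = tj.LCGMMParams(np.vstack([beta, beta]), 5.0, 4.0, np.array([0.5, 0.5]))
        assert tj.mixture_loglik(tiny_data, two) == pytest.approx(
            tj.mixture_loglik(tiny_data, one)
        )

    def test_label_permutation_invariance(self, tiny_data, rng):
        beta = rng.normal(50, 10, size=(3, 4))
        pi = np.array([0.2, 0.3, 0.5])
        perm = [2, 0, 1]
        a = tj.LCGMMParams(beta, 5.0, 4.0, pi)
        b = tj.LCGMMParams(beta[perm], 5.0, 4.0, pi[perm])
        assert tj.mixture_loglik(tiny_data, a) == pytest.approx(
            tj.mixture_loglik(tiny_data, b)
        )


class TestPosteriorProbs:
    def test_single_class_all_ones(self, tiny_data):
        params = tj.LCGMMParams(
            np.array([[50.0, 0, 0, 0]]), 5.0, 4.0, np.array([1.0])
        )
        np.testing.assert_allclose(tj.posterior_probs(tiny_data, params), 1.0)

    def test_rows_sum_to_one(self, tiny_data, rng):
        params = tj.LCGMMParams(
            rng.normal(50, 10, (4, 4)), 5.0, 4.0, np.full(4, 0.25)
        )
        P = tj.posterior_probs(tiny_data, params)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_symmetric_setup_gives_half(self):
        days = [np.arange(10)] * 4
        ys = [np.full(10, 45.0)] * 4
        data = make_model_data(ys, days, basis_df=1)
        beta = np.array([[40.0, 0.0], [50.0, 0.0]])
        params = tj.LCGMMParams(beta, 2.0, 3.0, np.array([0.5, 0.5]))
        P = tj.posterior_probs(data, params)
        np.testing.assert_allclose(P, 0.5, atol=1e-12)


class TestFitEm:
    def test_loglik_nondecreasing(self, small_study):
        *_, data = small_study
        spec = tj.LCGMMSpec(2, data.basis, data.time_scale)
        one = tj.fit_one_class(data)
        r = np.random.default_rng(0)
        start = tj.LCGMMParams(
            one.params.beta + r.normal(0, 3, size=(2, one.params.beta.shape[1])),
            one.params.sigma_b,
            one.params.sigma_eps,
            np.array([0.5, 0.5]),
        )
        fit = tj.fit_em(data, spec, start, max_iter=100)
        diffs = np.diff(fit.history)
        assert (diffs >= -1e-6 * np.abs(fit.history[:-1])).all()

    def test_stationary_start_converges_immediately(self, small_study):
        *_, data = small_study
        spec = tj.LCGMMSpec(2, data.basis, data.time_scale)
        fit = tj.grid_search_fit(data, spec, n_starts=5, burn_iters=20, seed=0)
        refit = tj.fit_em(data, spec, fit.params, max_iter=50)
        assert refit.converged and refit.n_iterations <= 3
        np.testing.assert_allclose(refit.params.beta, fit.params.beta, atol=1e-4)

    def test_well_separated_two_class_recovery(self, small_study):
        cfg, _, truth, _, data = small_study
        spec = tj.LCGMMSpec(2, data.basis, data.time_scale)
        fit = tj.grid_search_fit(data, spec, n_starts=5, burn_iters=20, seed=1)
        assert fit.converged
        mapping, acc = tj.align_to_truth(fit.assignment, truth.class_label, 2)
        assert acc >= 0.95
        # intercepts near the generating baselines (20 and 70)
        intercepts = sorted(fit.params.beta[:, 0])
        assert intercepts[0] == pytest.approx(20, abs=2.5)
        assert intercepts[1] == pytest.approx(70, abs=2.5)


class TestFitOneClass:
    def test_matches_statsmodels_mixedlm(self, small_study):
        """Independent oracle: REML-off MixedLM on the same design."""
        import statsmodels.api as sm

        *_, data = small_study
        fit = tj.fit_one_class(data)
        groups = data.subject_ids[data.subj_idx]
        m = sm.MixedLM(data.y, data.X, groups=groups).fit(reml=False)
        np.testing.assert_allclose(fit.params.beta[0], m.fe_params, atol=0.05)
        assert fit.loglik == pytest.approx(m.llf, abs=0.5)
        sb_sm = np.sqrt(np.asarray(m.cov_re)[0, 0])
        assert fit.params.sigma_b == pytest.approx(sb_sm, rel=0.05)

    def test_noise_free_constant_data(self):
        days = [np.arange(20)] * 6
        ys = [np.full(20, 37.0)] * 6
        data = make_model_data(ys, days, basis_df=1)
        fit = tj.fit_one_class(data)
        assert fit.params.beta[0, 0] == pytest.approx(37.0, abs=1e-3)
        assert fit.params.sigma_eps <= 0.01

    def test_loglik_consistent_with_mixture(self, small_study):
        *_, data = small_study
        fit = tj.fit_one_class(data)
        assert tj.mixture_loglik(data, fit.params) == pytest.approx(fit.loglik)


class TestCountParameters:
    @pytest.mark.parametrize("G,df,expected", [(1, 3, 6), (4, 3, 21), (2, 1, 7)])
    def test_parameter_count(self, G, df, expected):
        spec = tj.LCGMMSpec(G, SplineBasisSpec(df=df))
        assert tj.count_parameters(spec) == expected

    def test_invalid_class_count(self):
        with pytest.raises(ValueError):
            tj.LCGMMSpec(0)


class TestGridSearchFit:
    def test_g1_delegates_to_one_class(self, small_study):
        *_, data = small_study
        spec = tj.LCGMMSpec(1, data.basis, data.time_scale)
        a = tj.grid_search_fit(data, spec, seed=3)
        b = tj.fit_one_class(data)
        assert a.loglik == pytest.approx(b.loglik)

    def test_same_seed_identical_fit(self, small_study):
        *_, data = small_study
        spec = tj.LCGMMSpec(2, data.basis, data.time_scale)
        a = tj.grid_search_fit(data, spec, n_starts=4, burn_iters=10, seed=5)
        b = tj.grid_search_fit(data, spec, n_starts=4, burn_iters=10, seed=5)
        np.testing.assert_array_equal(a.params.beta, b.params.beta)
        assert a.loglik == b.loglik and a.best_start_index == b.best_start_index


class TestPrediction:
    def test_zero_spline_coefficients_give_flat_line(self, small_study):
        *_, data = small_study
        fit = tj.fit_one_class(data)
        fit.params.beta[0, 1:] = 0.0
        traj = tj.predict_class_trajectory(fit, np.arange(84))
        np.testing.assert_allclose(traj["mean"], fit.params.beta[0, 0])

    def test_ci_width_shrinks_with_sample_size(self):
        def mean_width(n, seed):
            cfg = tj.SimConfig(
                n_subjects=n, n_days=84,
                class_proportions=(1.0,),
                class_anchor_curves=(((0, 40.0), (83, 50.0)),),
                sigma_b=6.0, sigma_eps=5.0, missing_raw_fraction=0.0, seed=seed,
            )
            panel, _ = tj.simulate_panel(cfg)
            sm = tj.smooth_panel(panel, 84, items=[tj.PRIMARY_ITEM])
            data = tj.build_model_data(sm, tj.PRIMARY_ITEM)
            fit = tj.fit_one_class(data)
            traj = tj.predict_class_trajectory(fit, np.arange(84))
            return (traj["ci_high"] - traj["ci_low"]).mean()

        assert mean_width(200, 17) < 0.7 * mean_width(50, 17)

    def test_nonconverged_fit_rejected(self, small_study):
        *_, data = small_study
        fit = tj.fit_one_class(data)
        fit.converged = False
        with pytest.raises(RuntimeError):
            tj.predict_class_trajectory(fit, np.arange(10))


class TestLabeling:
    def test_relabel_orders_by_baseline_descending(self, small_study):
        *_, data = small_study
        spec = tj.LCGMMSpec(2, data.basis, data.time_scale)
        fit = tj.grid_search_fit(data, spec, n_starts=5, burn_iters=20, seed=2)
        rel = tj.relabel_by_baseline(fit)
        assert rel.params.beta[0, 0] >= rel.params.beta[1, 0]
        assert rel.loglik == fit.loglik
        np.testing.assert_allclose(rel.posterior.sum(axis=1), 1.0)
        # assignments stay consistent with the posterior argmax
        np.testing.assert_array_equal(rel.assignment, rel.posterior.argmax(1) + 1)

    def test_align_recovers_permutation(self, rng):
        truth = rng.integers(1, 5, size=200)
        perm = np.array([3, 1, 4, 2])
        shuffled = perm[truth - 1]
        mapping, acc = tj.align_to_truth(shuffled, truth, 4)
        assert acc == 1.0
        np.testing.assert_array_equal(mapping[perm - 1], np.arange(1, 5))
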