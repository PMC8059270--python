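"""Growth mixture core: designs, covariance, likelihood, EM, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from conftest import simulate_centered, true_params, two_class_config
from trajmix import data_model as dm
from trajmix import gmm_core as gc

RNG = np.random.default_rng(12345)


def random_class_params(rng, S=5, q=2, rho=0.3, pi=1.0):
    psi = None
    if q:
        a = rng.uniform(0.5, 2.0, size=q)
        psi = np.diag(a)
        if q == 2:
            psi[0, 1] = psi[1, 0] = 0.3 * np.sqrt(a[0] * a[1])
    return gc.ClassParams(
        pi=pi,
        beta=np.array([22.0, 0.2, -0.01, 0.001])[: 4],
        psi=psi,
        sigma=rng.uniform(1.0, 2.0, S),
        rho=rho,
    )


class TestBuildDesign:
    def test_center_point(self):
        X, Z = gc.build_design([0.0], degree=3)
        assert np.allclose(X, [[1, 0, 0, 0]])
        assert np.allclose(Z, [[1, 0]])

    def test_polynomial_powers(self):
        X, _ = gc.build_design([1.0, 2.0], degree=2)
        assert np.allclose(X, [[1, 1, 1], [1, 2, 4]])

    def test_matches_bruteforce_powers(self):
        ages = RNG.normal(size=8)
        X, Z = gc.build_design(ages, degree=3)
        for i, t in enumerate(ages):
            for d in range(4):
                assert X[i, d] == pytest.approx(t**d)
        assert np.allclose(Z, X[:, :2])

    def test_bad_degree(self):
        with pytest.raises(ValueError):
            gc.build_design([0.0], degree=4)


class TestClassCovariance:
    def test_single_point_reduction(self):
        pk = random_class_params(RNG)
        V = gc.class_covariance(pk, [0.0], [1])
        assert V[0, 0] == pytest.approx(pk.psi[0, 0] + pk.sigma[0] ** 2)

    def test_rho_zero_offdiag_is_re_part_only(self):
        rng = np.random.default_rng(5)
        pk = random_class_params(rng, rho=0.0)
        t = np.array([-1.0, 2.0])
        V = gc.class_covariance(pk, t, [1, 2])
        z1, z2 = np.array([1, t[0]]), np.array([1, t[1]])
        assert V[0, 1] == pytest.approx(z1 @ pk.psi @ z2)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(9)
        pk = random_class_params(rng, rho=0.45)
        t = rng.normal(size=5)
        j = np.array([1, 2, 3, 4, 5])
        V = gc.class_covariance(pk, t, j)
        for a in range(5):
            for b in range(5):
                za = np.array([1.0, t[a]])
                zb = np.array([1.0, t[b]])
                expect = pk.sigma[j[a] - 1] * pk.sigma[j[b] - 1] * pk.rho ** abs(j[a] - j[b])
                expect += za @ pk.psi @ zb
                assert V[a, b] == pytest.approx(expect, abs=1e-12)

    def test_non_psd_psi_rejected(self):
        pk = gc.ClassParams(
            pi=1.0, beta=np.zeros(4), psi=np.array([[1.0, 2.0], [2.0, 1.0]]),
            sigma=np.ones(5), rho=0.2,
        )
        with pytest.raises(gc.ParameterError):
            gc.class_covariance(pk, [0.0, 1.0], [1, 2])


def _brute_force_loglik(ds, params, degree=3):
    total = 0.0
    for s in ds.subjects:
        t, y, j = s.ages(), s.bmis(), s.sweeps()
        X = np.stack([t**d for d in range(degree + 1)], -1)
        Z = np.stack([np.ones_like(t), t], -1)
        dens = 0.0
        for pk in params:
            R = np.array(
                [[pk.sigma[a - 1] * pk.sigma[b - 1] * pk.rho ** abs(a - b) for b in j] for a in j]
            )
            V = Z @ pk.psi @ Z.T + R
            dens += pk.pi * multivariate_normal.pdf(y, X @ pk.beta, V)
        total += np.log(dens)
    return total


class TestMarginalLoglik:
    def test_single_obs_univariate_normal(self):
        s = dm.Subject(id="a", sex="male", cohort="C", observations=(dm.Observation(age=0.0, bmi=22.5, sweep_index=1),))
        ds = dm.LongitudinalDataset(subjects=(s,), centering_age=23.64)
        pk = random_class_params(np.random.default_rng(2), pi=1.0)
        spec = gc.ModelSpec(K=1, n_sweeps=5, ar1=True)
        var = pk.psi[0, 0] + pk.sigma[0] ** 2
        expected = -0.5 * (np.log(2 * np.pi * var) + (22.5 - pk.beta[0]) ** 2 / var)
        assert gc.marginal_loglik(ds, [pk], spec) == pytest.approx(expected)

    def test_duplication_doubles_loglik(self, small_dataset):
        _, ds, _ = small_dataset
        sub = ds.subjects[:15]
        ds1 = dm.LongitudinalDataset(subjects=sub, centering_age=ds.centering_age)
        dup = tuple(
            dm.Subject(id=s.id + "_b", sex=s.sex, cohort=s.cohort, observations=s.observations)
            for s in sub
        )
        ds2 = dm.LongitudinalDataset(subjects=sub + dup, centering_age=ds.centering_age)
        rng = np.random.default_rng(3)
        params = [random_class_params(rng, pi=0.6), random_class_params(rng, pi=0.4, rho=0.1)]
        spec = gc.ModelSpec(K=2, n_sweeps=5, ar1=True)
        assert gc.marginal_loglik(ds2, params, spec) == pytest.approx(2 * gc.marginal_loglik(ds1, params, spec))

    def test_matches_bruteforce_on_10x3(self, small_dataset):
        _, ds, _ = small_dataset
        ds10 = dm.LongitudinalDataset(subjects=ds.subjects[:10], centering_age=ds.centering_age)
        rng = np.random.default_rng(4)
        params = [
            random_class_params(rng, pi=0.5, rho=0.4),
            random_class_params(rng, pi=0.3, rho=0.2),
            random_class_params(rng, pi=0.2, rho=0.0),
        ]
        spec = gc.ModelSpec(K=3, n_sweeps=5, ar1=True)
        assert gc.marginal_loglik(ds10, params, spec) == pytest.approx(
            _brute_force_loglik(ds10, params), abs=1e-10
        )


class TestEStep:
    def test_k1_posteriors_all_one(self, small_dataset):
        _, ds, _ = small_dataset
        pk = random_class_params(np.random.default_rng(1))
        post = gc.e_step(ds, [pk], gc.ModelSpec(K=1, n_sweeps=5, ar1=True))
        assert np.allclose(post, 1.0)

    def test_identical_classes_symmetric(self, small_dataset):
        _, ds, _ = small_dataset
        pk = random_class_params(np.random.default_rng(1), pi=0.5)
        post = gc.e_step(ds, [pk, pk], gc.ModelSpec(K=2, n_sweeps=5, ar1=True))
        assert np.allclose(post, 0.5)

    def test_matches_direct_normalization(self, small_dataset):
        _, ds, _ = small_dataset
        ds5 = dm.LongitudinalDataset(subjects=ds.subjects[:5], centering_age=ds.centering_age)
        rng = np.random.default_rng(8)
        params = [random_class_params(rng, pi=0.7), random_class_params(rng, pi=0.3, rho=0.1)]
        spec = gc.ModelSpec(K=2, n_sweeps=5, ar1=True)
        post = gc.e_step(ds5, params, spec)
        for i, s in enumerate(ds5.subjects):
            one = dm.LongitudinalDataset(subjects=(s,), centering_age=ds.centering_age)
            raw = np.array(
                [
                    pk.pi * np.exp(gc.marginal_loglik(one, [gc.ClassParams(pi=1.0, beta=pk.beta, psi=pk.psi, sigma=pk.sigma, rho=pk.rho)], gc.ModelSpec(K=1, n_sweeps=5, ar1=True)))
                    for pk in params
                ]
            )
            assert np.allclose(post[i], raw / raw.sum(), atol=1e-12)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_pi_update_from_hard_posteriors(self, small_dataset):
        _, ds, _ = small_dataset
        n = ds.n_subjects
        post = np.zeros((n, 2))
        post[: n // 2, 0] = 1
        post[n // 2 :, 1] = 1
        spec = gc.ModelSpec(K=2, n_sweeps=5, degree=1, random_effects=(), heteroskedastic_over_sweeps=False, ar1=False)
        params = [
            gc.ClassParams(pi=0.5, beta=[20.0, 0.0], psi=None, sigma=np.full(5, 1.5), rho=None)
            for _ in range(2)
        ]
        new = gc.m_step(ds, post, spec, params)
        assert new[0].pi == pytest.approx((n // 2) / n)

    def test_reduces_to_wls_per_class(self, small_dataset):
        _, ds, _ = small_dataset
        half = ds.n_subjects // 2
        post = np.zeros((ds.n_subjects, 2))
        post[:half, 0] = 1
        post[half:, 1] = 1
        spec = gc.ModelSpec(K=2, n_sweeps=5, degree=1, random_effects=(), heteroskedastic_over_sweeps=False, ar1=False)
        params = [
            gc.ClassParams(pi=0.5, beta=[20.0, 0.0], psi=None, sigma=np.full(5, 1.5), rho=None)
            for _ in range(2)
        ]
        new = gc.m_step(ds, post, spec, params)
        T = np.concatenate([s.ages() for s in ds.subjects[:half]])
        Y = np.concatenate([s.bmis() for s in ds.subjects[:half]])
        X = np.stack([np.ones_like(T), T], -1)
        ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.allclose(new[0].beta, ols, atol=1e-8)

    def test_never_decreases_em_objective(self, small_dataset):
        _, ds, _ = small_dataset
        rng = np.random.default_rng(6)
        params = [random_class_params(rng, pi=0.5), random_class_params(rng, pi=0.5, rho=0.1)]
        spec = gc.ModelSpec(K=2, n_sweeps=5, ar1=True, class_specific_residuals=True)
        ll0 = gc.marginal_loglik(ds, params, spec)
        post = gc.e_step(ds, params, spec)
        new = gc.m_step(ds, post, spec, params)
        ll1 = gc.marginal_loglik(ds, list(new), spec)
        assert ll1 >= ll0 - 1e-8


class TestEntropyBicCounts:
    def test_entropy_hard_assignment_is_one(self):
        post = np.eye(4)[RNG.integers(0, 4, size=30)]
        assert gc.entropy(post) == pytest.approx(1.0)

    def test_entropy_uniform_is_zero(self):
        assert gc.entropy(np.full((12, 3), 1 / 3)) == pytest.approx(0.0)

    def test_entropy_hand_computed(self):
        p = np.array([[0.9, 0.1], [0.6, 0.4], [0.5, 0.5]])
        shannon = -(p * np.log(p)).sum()
        assert gc.entropy(p) == pytest.approx(1 - shannon / (3 * np.log(2)))

    def test_entropy_k1_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(gc.entropy(np.ones((5, 1))))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_entropy_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(3), size=10)
        e = gc.entropy(p)
        assert -1e-12 <= e <= 1 + 1e-12

    def test_bic_arithmetic(self):
        assert gc.bic(-100.0, 10, 100) == pytest.approx(200 + 10 * np.log(100))
        assert gc.bic(-100.0, 0, 50) == pytest.approx(200.0)

    def test_final_model_parameter_count_is_49(self):
        spec = gc.ModelSpec(
            K=4, n_sweeps=5, degree=3,
            class_specific_intercept_var=True, class_specific_residuals=True, ar1=True,
        )
        assert gc.n_parameters(spec) == 49

    def test_minimal_model_count(self):
        spec = gc.ModelSpec(K=1, n_sweeps=5, degree=1, random_effects=(), heteroskedastic_over_sweeps=False)
        assert gc.n_parameters(spec) == 3

    def test_ar1_toggle_changes_count_by_K(self):
        kw = dict(K=3, n_sweeps=5, class_specific_residuals=True)
        with_ar = gc.n_parameters(gc.ModelSpec(ar1=True, **kw))
        without = gc.n_parameters(gc.ModelSpec(ar1=False, **kw))
        assert with_ar - without == 3


class TestModalAndOrdering:
    def test_argmax_and_tie_rule(self):
        assert gc.assign_modal(np.array([[0.1, 0.9]]))[0] == 2
        assert gc.assign_modal(np.array([[0.5, 0.5]]))[0] == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(4), size=25)
        labels = gc.assign_modal(p)
        for i in range(25):
            assert p[i, labels[i] - 1] == p[i].max()

    def test_order_classes_restores_and_preserves_loglik(self, small_dataset):
        _, ds, _ = small_dataset
        rng = np.random.default_rng(11)
        lo = random_class_params(rng, pi=0.6)
        hi = gc.ClassParams(pi=0.4, beta=lo.beta + np.array([5.0, 0, 0, 0]), psi=lo.psi, sigma=lo.sigma, rho=lo.rho)
        spec = gc.ModelSpec(K=2, n_sweeps=5, ar1=True)
        post = gc.e_step(ds, [hi, lo], spec)
        swapped = gc.FitResult(
            spec=spec, params=(hi, lo), loglik=-1.0, n_params=5, bic=0.0, entropy=0.5,
            posteriors=post, converged=True, n_starts_used=1, best_start_seed=0,
        )
        ordered = gc.order_classes(swapped)
        assert ordered.params[0].beta[0] < ordered.params[1].beta[0]
        assert np.allclose(ordered.posteriors, post[:, [1, 0]])
        assert ordered.loglik == swapped.loglik
        assert gc.order_classes(ordered).params == ordered.params


class TestFit:
    def test_k1_matches_ols_closed_form(self, small_dataset):
        _, ds, _ = small_dataset
        spec = gc.ModelSpec(K=1, n_sweeps=5, degree=1, random_effects=(), heteroskedastic_over_sweeps=False, ar1=False)
        res = gc.fit(ds, spec, n_starts=1, seed=0, max_iter=200)
        T = np.concatenate([s.ages() for s in ds.subjects])
        Y = np.concatenate([s.bmis() for s in ds.subjects])
        X = np.stack([np.ones_like(T), T], -1)
        b = np.linalg.lstsq(X, Y, rcond=None)[0]
        rss = np.sum((Y - X @ b) ** 2)
        N = len(Y)
        sig2 = rss / N
        ll = -0.5 * N * (np.log(2 * np.pi * sig2) + 1)
        assert res.loglik == pytest.approx(ll, rel=1e-6)

    def test_well_separated_two_class_recovery(self):
        cfg = two_class_config(delta=6.0, n=500)
        ds, truth = simulate_centered(cfg, seed=1)
        spec = gc.ModelSpec(K=2, n_sweeps=5, ar1=True)
        res = gc.fit(ds, spec, n_starts=3, seed=2, n_full=1, short_iter=8, max_iter=80, tol=1e-6)
        labels = gc.assign_modal(res.posteriors)
        true_labels = np.array([t.true_class for t in truth])
        acc = np.mean(labels == true_labels)
        assert acc >= 0.95

    def test_seeded_determinism(self, small_dataset):
        _, ds, _ = small_dataset
        spec = gc.ModelSpec(K=2, n_sweeps=5, ar1=True)
        kw = dict(n_starts=2, seed=42, n_full=1, short_iter=5, max_iter=30)
        r1 = gc.fit(ds, spec, **kw)
        r2 = gc.fit(ds, spec, **kw)
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-8)

    def test_refuses_mixed_sex(self, small_dataset):
        _, ds, _ = small_dataset
        flipped = dm.Subject(id="x_f", sex="female", cohort="COH", observations=ds.subjects[0].observations)
        mixed = dm.LongitudinalDataset(subjects=ds.subjects + (flipped,), centering_age=ds.centering_age)
        with pytest.raises(ValueError, match="sex"):
            gc.fit(mixed, gc.ModelSpec(K=2, n_sweeps=5), n_starts=1, seed=0)

    def test_refuses_uncentered(self, tiny_raw_dataset):
        with pytest.raises(dm.StateError):
            gc.fit(tiny_raw_dataset, gc.ModelSpec(K=1, n_sweeps=5), n_starts=1, seed=0)

    def test_fit_result_roundtrip_json(self, small_dataset, tmp_path):
        _, ds, _ = small_dataset
        spec = gc.ModelSpec(K=2, n_sweeps=5, ar1=True)
        res = gc.fit(ds, spec, n_starts=1, seed=3, n_full=1, short_iter=5, max_iter=20)
        path = tmp_path / "fit.json"
        res.to_json(path)
        back = gc.FitResult.from_json(path)
        assert back.loglik == pytest.approx(res.loglik)
        assert np.allclose(back.params[0].beta, res.params[0].beta)
        assert back.spec == res.spec


class TestEntropySeparationMonotonicity:
    def test_entropy_increases_with_separation(self):
        values = []
        for delta in (1.0, 3.0, 6.0):
            cfg = two_class_config(delta=delta, n=300)
            ds, _ = simulate_centered(cfg, seed=5)
            params = true_params(cfg)
            post = gc.e_step(ds, params, gc.ModelSpec(K=2, n_sweeps=5, ar1=True))
            values.append(gc.entropy(post))
        assert values[0] < values[1] < values[2]
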