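import numpy as np
import pytest
import statsmodels.api as sm

from tcrnp import (
    FitConfig,
    GroupSpec,
    fit,
    fit_path,
    lambda_max,
    objective,
    penalty_weights,
)
from conftest import make_logistic_instance

TIGHT = FitConfig(tol=1e-12, max_iter=200000)


def fista_oracle(X, y, spec, weights, lam, iters=30000):
    """Independent proximal-gradient (FISTA with function restart) minimizer
    of the same penalized logistic objective, intercept unpenalized."""
    n, P = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    L = 0.25 * np.linalg.norm(Xa, 2) ** 2
    starts = spec.starts + 1
    sizes = spec.sizes

    def prox(u):
        out = u.copy()
        for g in range(spec.G):
            s = slice(starts[g], starts[g] + sizes[g])
            nrm = np.linalg.norm(u[s])
            thr = lam * weights[g] / L
            out[s] = 0.0 if nrm <= thr else (1 - thr / nrm) * u[s]
        return out

    def obj(b):
        eta = Xa @ b
        nll = -(y @ eta - np.logaddexp(0, eta).sum())
        pen = sum(
            weights[g] * np.linalg.norm(b[starts[g] : starts[g] + sizes[g]])
            for g in range(spec.G)
        )
        return nll + lam * pen

    beta = np.zeros(P + 1)
    z, t, prev = beta.copy(), 1.0, np.inf
    for _ in range(iters):
        p = 1 / (1 + np.exp(-(Xa @ z)))
        new = prox(z - Xa.T @ (p - y) / L)
        cur = obj(new)
        if cur > prev:  # function restart
            z, t = beta.copy(), 1.0
            prev = obj(beta)
            continue
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = new + ((t - 1) / t_new) * (new - beta)
        beta, t, prev = new, t_new, cur
    return beta[0], beta[1:]


class TestPenaltyWeights:
    def test_conventions(self):
        spec = GroupSpec(names=["a", "b"], sizes=[6, 7])
        assert penalty_weights(spec, "sqrt_size") == pytest.approx(
            [np.sqrt(6), np.sqrt(7)]
        )
        assert penalty_weights(spec, "linear_size") == pytest.approx([6, 7])

    def test_singletons_reduce_to_lasso(self):
        spec = GroupSpec(names=list("abc"), sizes=[1, 1, 1])
        for conv in ("sqrt_size", "linear_size"):
            assert penalty_weights(spec, conv) == pytest.approx([1, 1, 1])


class TestLambdaMax:
    def test_boundary_behaviour(self, rng):
        X, y, spec = make_logistic_instance(rng, n=50, sizes=(3, 3), signal=(1.0, 0.0))
        w = penalty_weights(spec)
        lmax = lambda_max(X, y, spec, w)
        _, b_hi, _ = fit(X, y, spec, 1.001 * lmax, w, TIGHT)
        assert np.all(b_hi == 0.0)
        _, b_lo, _ = fit(X, y, spec, 0.9 * lmax, w, TIGHT)
        assert np.any(b_lo != 0.0)

    def test_weight_homogeneity(self, rng):
        X, y, spec = make_logistic_instance(rng)
        w = penalty_weights(spec)
        assert lambda_max(X, y, spec, 3.0 * w) == pytest.approx(
            lambda_max(X, y, spec, w) / 3.0
        )

    def test_lasso_reduction_single_columns(self, rng):
        n = 32
        Q, _ = np.linalg.qr(rng.standard_normal((n, 4)))
        X = Q * np.sqrt(n)
        y = (rng.random(n) < 0.5).astype(float)
        y[:2] = [0, 1]
        spec = GroupSpec(names=list("abcd"), sizes=[1, 1, 1, 1])
        w = np.ones(4)
        expected = np.abs(X.T @ (y - y.mean())).max()
        assert lambda_max(X, y, spec, w) == pytest.approx(expected)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        spec = GroupSpec(names=["a"], sizes=[2])
        with pytest.raises(ValueError):
            lambda_max(X, np.ones(10), spec)


class TestFit:
    def test_zero_lambda_matches_logistic_mle(self, rng):
        X, y, spec = make_logistic_instance(rng, n=40, sizes=(2, 2), signal=(0.8, -0.5))
        b0, b, ok = fit(X, y, spec, 0.0, config=TIGHT)
        assert ok
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.abs(np.r_[b0, b] - mle.params).max() < 1e-5

    def test_at_lambda_max_returns_null_model(self, rng):
        X, y, spec = make_logistic_instance(rng)
        w = penalty_weights(spec)
        lmax = lambda_max(X, y, spec, w)
        b0, b, _ = fit(X, y, spec, lmax, w)
        assert np.all(b == 0.0)
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_matches_convex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, y, spec = make_logistic_instance(rng, n=30, sizes=(3, 3), signal=(1.0, 0.0))
        w = penalty_weights(spec)
        lam = 0.3 * lambda_max(X, y, spec, w)
        b0, b, _ = fit(X, y, spec, lam, w, TIGHT)
        ob0, ob = fista_oracle(X, y, spec, w, lam)
        mine = objective(X, y, b0, b, lam, spec, w)
        oracle = objective(X, y, ob0, ob, lam, spec, w)
        assert abs(mine - oracle) < 1e-6

    def test_descent_vs_zero_vector(self, rng):
        X, y, spec = make_logistic_instance(rng)
        w = penalty_weights(spec)
        for lam in (0.0, 0.1, 1.0, 10.0):
            b0, b, _ = fit(X, y, spec, lam, w)
            assert objective(X, y, b0, b, lam, spec, w) <= objective(
                X, y, 0.0, np.zeros(spec.P), lam, spec, w
            ) + 1e-9

    def test_weight_doubling_never_adds_group(self, rng):
        for _ in range(5):
            X, y, spec = make_logistic_instance(
                rng, n=50, sizes=(3, 3, 2), signal=(0.8, 0.3, 0.0)
            )
            w = penalty_weights(spec)
            lam = 0.3 * lambda_max(X, y, spec, w)
            _, b, _ = fit(X, y, spec, lam, w, TIGHT)
            for g in range(spec.G):
                w2 = w.copy()
                w2[g] *= 2.0
                _, b2, _ = fit(X, y, spec, lam, w2, TIGHT)
                cols = spec.columns_of(g)
                if not np.any(b[cols]):
                    assert not np.any(b2[cols])

    def test_within_group_column_reorder(self, rng):
        X, y, spec = make_logistic_instance(rng, n=50, sizes=(3, 3), signal=(0.9, 0.4))
        w = penalty_weights(spec)
        lam = 0.2 * lambda_max(X, y, spec, w)
        b0, b, _ = fit(X, y, spec, lam, w, TIGHT)
        perm = np.r_[[2, 0, 1], [3, 4, 5]]  # shuffle inside group 0 only
        b0p, bp, _ = fit(X[:, perm], y, spec, lam, w, TIGHT)
        assert b0p == pytest.approx(b0, abs=1e-6)
        assert np.allclose(bp, b[perm], atol=1e-6)

    def test_negative_lambda_rejected(self, rng):
        X, y, spec = make_logistic_instance(rng)
        with pytest.raises(ValueError):
            fit(X, y, spec, -1.0)


class TestFitPath:
    def test_first_grid_point_empty_support(self, rng):
        X, y, spec = make_logistic_instance(rng)
        path = fit_path(X, y, spec)
        assert np.all(path.coefs[0] == 0.0)
        assert not path.group_support()[0].any()
        assert np.all(np.diff(path.lambdas) < 0)

    def test_warm_vs_cold_same_objective(self, rng):
        X, y, spec = make_logistic_instance(rng, n=50, sizes=(3, 3), signal=(1.0, 0.2))
        w = penalty_weights(spec)
        path = fit_path(X, y, spec, w, config=FitConfig(grid_length=20, grid_ratio=0.05))
        for k in (5, 12, 19):
            lam = path.lambdas[k]
            warm_obj = objective(X, y, path.intercepts[k], path.coefs[k], lam, spec, w)
            b0, b, _ = fit(X, y, spec, lam, w, TIGHT)  # cold start
            cold_obj = objective(X, y, b0, b, lam, spec, w)
            assert warm_obj == pytest.approx(cold_obj, abs=1e-4)

    def test_singleton_supports_match_sklearn_lasso(self, rng):
        from sklearn.linear_model import LogisticRegression

        X, y, spec = make_logistic_instance(
            rng, n=60, sizes=(1,) * 8, signal=(1.0, 0.8, 0, 0, -0.6, 0, 0, 0)
        )
        cfg = FitConfig(grid_length=12, grid_ratio=0.05, tol=1e-10, max_iter=50000)
        path = fit_path(X, y, spec, config=cfg)
        for k, lam in enumerate(path.lambdas):
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / lam, solver="saga",
                tol=1e-10, max_iter=20000, fit_intercept=True,
            ).fit(X, y)
            ref = np.abs(clf.coef_.ravel()) > 1e-6
            mine = np.abs(path.coefs[k]) > 1e-6
            assert np.array_equal(mine, ref), f"grid point {k}"
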