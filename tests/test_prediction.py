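"""Mixed-effects fitting, nested LOSO prediction, metrics and importance."""

import numpy as np
import pandas as pd
import pytest

from oculoseason.prediction import (
    evaluate,
    feature_importance,
    fit_lme,
    loso_predict,
)


def _grouped_data(rng, n_subjects=8, per=5, sigma_u=1.2, sigma_e=0.7, p=3):
    subj = np.repeat(np.arange(n_subjects), per)
    X = rng.normal(size=(subj.size, p))
    beta = rng.normal(size=p)
    u = rng.normal(0, sigma_u, n_subjects)
    y = 0.5 + X @ beta + u[subj] + rng.normal(0, sigma_e, subj.size)
    return X, y, subj


class TestFitLME:
    def test_pure_subject_offsets_reproduced_exactly(self):
        """Intercept-only model on noise-free subject constants."""
        subj = np.repeat(np.arange(5), 4)
        y = np.array([1.0, 2.0, -1.0, 0.5, 3.0])[subj]
        fit = fit_lme(np.empty((20, 0)), y, subj, add_intercept=True)
        pred = fit.predict(np.ones((20, 1)), subj)
        assert np.allclose(pred, y, atol=1e-6)

    def test_zero_between_subject_variance_matches_ols(self, rng):
        """Antisymmetric within-subject residuals force sigma_u to zero."""
        n_subjects, p = 10, 2
        subj = np.repeat(np.arange(n_subjects), 2)
        X = rng.normal(size=(subj.size, p))
        e = rng.normal(0, 0.5, n_subjects)
        resid = np.stack([e, -e], axis=1).ravel()  # subject means exactly zero
        y = X @ np.array([1.0, -2.0]) + resid
        fit = fit_lme(X, y, subj, add_intercept=True)
        Xi = np.column_stack([np.ones(subj.size), X])
        beta_ols = np.linalg.lstsq(Xi, y, rcond=None)[0]
        assert fit.sigma2_u == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fit.beta, beta_ols, atol=1e-6)
        assert np.allclose(fit.predict(Xi, subj), Xi @ beta_ols, atol=1e-6)

    def test_matches_profile_likelihood_grid_oracle(self, rng):
        """12-row toy fit agrees with a brute-force likelihood grid."""
        from scipy.stats import multivariate_normal

        subj = np.repeat(np.arange(4), 3)
        X = rng.normal(size=(12, 1))
        y = (1.0 + 0.8 * X[:, 0] + np.array([0.9, -0.4, 0.1, -0.6])[subj]
             + rng.normal(0, 0.3, 12))
        fit = fit_lme(X, y, subj, add_intercept=True)
        Xi = np.column_stack([np.ones(12), X])
        Z = np.zeros((12, 4))
        Z[np.arange(12), subj] = 1.0
        best = (-np.inf, None, None)
        for su in np.linspace(0.01, 1.5, 60):
            for se in np.linspace(0.05, 1.0, 60):
                V = su**2 * Z @ Z.T + se**2 * np.eye(12)
                Vi = np.linalg.inv(V)
                beta = np.linalg.solve(Xi.T @ Vi @ Xi, Xi.T @ Vi @ y)
                ll = multivariate_normal.logpdf(y, mean=Xi @ beta, cov=V)
                if ll > best[0]:
                    best = (ll, su, se)
        ll_grid, su_grid, se_grid = best
        assert np.sqrt(fit.sigma2_u) == pytest.approx(su_grid, abs=0.05)
        assert np.sqrt(fit.sigma2_e) == pytest.approx(se_grid, abs=0.05)
        assert fit.loglik >= ll_grid - 1e-6  # ML is at least as good as the grid

    def test_matches_statsmodels_ml(self, rng):
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM

        X, y, subj = _grouped_data(rng)
        fit = fit_lme(X, y, subj, add_intercept=True)
        md = MixedLM(y, sm.add_constant(X), groups=subj).fit(reml=False)
        assert np.allclose(fit.beta, np.asarray(md.params)[:4], atol=1e-4)
        assert fit.sigma2_e == pytest.approx(md.scale, rel=1e-3)
        assert fit.sigma2_u == pytest.approx(float(np.asarray(md.cov_re)[0, 0]),
                                             rel=1e-3)
        assert fit.loglik == pytest.approx(md.llf, abs=1e-4)

    def test_unseen_subject_predicted_by_fixed_effects_only(self, rng):
        X, y, subj = _grouped_data(rng)
        fit = fit_lme(X, y, subj, add_intercept=True)
        xnew = np.concatenate([[1.0], rng.normal(size=3)])
        assert fit.predict(xnew[None, :], ["never-seen"])[0] == pytest.approx(
            float(xnew @ fit.beta))

    def test_errors(self, rng):
        X, y, subj = _grouped_data(rng)
        with pytest.raises(ValueError):
            fit_lme(np.column_stack([X, X[:, 0]]), y, subj)  # singular
        with pytest.raises(ValueError):
            fit_lme(X[:4], y[:4], np.zeros(4, dtype=int))  # one subject


class TestEvaluate:
    def test_identity(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["corr"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert m["bias"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self):
        m = evaluate([1.5, 2.5, 3.5], [1.0, 2.0, 3.0])
        assert m["corr"] == pytest.approx(1.0)
        assert m["bias"] == pytest.approx(0.5)
        assert m["rmse"] == pytest.approx(0.5)

    def test_anticorrelated_hand_arithmetic(self):
        m = evaluate([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert m["corr"] == pytest.approx(-1.0)
        assert m["bias"] == pytest.approx(0.0, abs=1e-12)
        assert m["rmse"] == pytest.approx(np.sqrt(8.0 / 3.0))
        assert m["r2"] == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            evaluate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _feature_frame(rng, n, p=8):
    return pd.DataFrame(rng.normal(size=(n, p)),
                        columns=[f"f{j}" for j in range(p)])


class TestLosoPredict:
    def test_realizable_model_near_perfect(self, rng):
        """Outcome = first feature PC + subject offsets, no noise."""
        n_subjects, per = 12, 4
        subj = np.repeat([f"s{i}" for i in range(n_subjects)], per)
        F = _feature_frame(rng, n_subjects * per)
        F["f0"] = F["f0"] * 5.0  # dominant variance direction
        z = (F - F.mean()) / F.std(ddof=1)
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        pc1 = u[:, 0] * s[0]
        offs = rng.normal(0, 2.0, n_subjects)
        y = 1.0 + 0.8 * pc1 + offs[np.repeat(np.arange(n_subjects), per)]
        res = loso_predict(F, y, subj, variant="raw", compute_baseline=False)
        assert res.metrics["corr"] >= 0.99

    def test_every_session_held_out_once(self, rng):
        subj = np.repeat([f"s{i}" for i in range(6)], 3)
        F = _feature_frame(rng, 18, p=4)
        y = rng.normal(size=18)
        res = loso_predict(F, y, subj, variant="raw", compute_baseline=False,
                           pc_grid_max=3)
        assert len(res.predictions) == 18
        assert res.predictions["predicted"].notna().all()
        assert (res.predictions["n_pcs"] >= 1).all()

    def test_row_order_invariance(self, rng):
        subj = np.repeat([f"s{i}" for i in range(8)], 3)
        F = _feature_frame(rng, 24, p=5)
        u = dict(zip(np.unique(subj), rng.normal(0, 1.5, 8)))
        y = F["f0"].to_numpy() + np.array([u[s] for s in subj]) + rng.normal(0, .2, 24)
        res = loso_predict(F, y, subj, variant="raw", compute_baseline=False,
                           pc_grid_max=3)
        perm = rng.permutation(24)
        res_p = loso_predict(F.iloc[perm].reset_index(drop=True), y[perm], subj[perm],
                             variant="raw", compute_baseline=False, pc_grid_max=3)
        back = np.empty(24)
        back[perm] = res_p.predictions["predicted"].to_numpy()
        assert np.allclose(back, res.predictions["predicted"].to_numpy(), atol=1e-8)

    def test_heldout_outcome_cannot_leak(self, rng):
        """Mutating a held-out session's outcome leaves its prediction alone."""
        subj = np.repeat([f"s{i}" for i in range(8)], 3)
        F = _feature_frame(rng, 24, p=5)
        y = F["f0"].to_numpy() + rng.normal(0, 0.5, 24)
        r = 7
        res1 = loso_predict(F, y, subj, variant="raw", compute_baseline=False,
                            pc_grid_max=3)
        y2 = y.copy()
        y2[r] += 50.0
        res2 = loso_predict(F, y2, subj, variant="raw", compute_baseline=False,
                            pc_grid_max=3)
        assert res2.predictions["predicted"].iloc[r] == pytest.approx(
            res1.predictions["predicted"].iloc[r], abs=1e-10)
        assert res2.predictions["n_pcs"].iloc[r] == res1.predictions["n_pcs"].iloc[r]

    def test_missing_features_imputed_from_training_fold(self, rng):
        subj = np.repeat([f"s{i}" for i in range(6)], 3)
        F = _feature_frame(rng, 18, p=4)
        F.iloc[2, 1] = np.nan
        F.iloc[5, 3] = np.nan
        res = loso_predict(F, rng.normal(size=18), subj, variant="raw",
                           compute_baseline=False, pc_grid_max=2)
        assert res.predictions["predicted"].notna().all()

    def test_sn_variant_has_no_intercept(self, rng):
        subj = np.repeat([f"s{i}" for i in range(6)], 3)
        F = _feature_frame(rng, 18, p=4)
        y = rng.normal(size=18)
        res = loso_predict(F, y, subj, variant="sn", compute_baseline=False,
                           pc_grid_max=2)
        for fold in res.folds:
            assert fold.beta_pcs.shape[0] == fold.n_pcs


class TestFeatureImportance:
    def test_single_dominant_loading(self):
        L = np.zeros((5, 1))
        L[0, 0] = 1.0
        table = feature_importance([(L, np.array([2.0]))],
                                   feature_names=list("abcde"))
        w = table.set_index("feature")["weight"]
        assert w["a"] == pytest.approx(1.0)
        assert (w.drop("a") == 0).all()

    def test_two_pc_two_fold_hand_computation(self):
        L1 = np.array([[0.8, 0.1], [0.6, 0.2], [0.0, 0.9]])
        b1 = np.array([1.0, 2.0])
        L2 = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        b2 = np.array([1.0, 1.0])
        table = feature_importance([(L1, b1), (L2, b2)],
                                   feature_names=["A", "B", "C"])
        w = table.set_index("feature")["weight"]
        # fold 1: A=0.8+0.2=1.0, B=0.6+0.4=1.0, C=1.8; fold 2: A=1, B=0, C=1
        # averages (1.0, 0.5, 1.4) normalized by 1.4
        assert w["C"] == pytest.approx(1.0)
        assert w["A"] == pytest.approx(1.0 / 1.4)
        assert w["B"] == pytest.approx(0.5 / 1.4)

    def test_top_k_truncation(self):
        L = np.array([[0.9], [0.5], [0.1]])
        table = feature_importance([(L, np.array([1.0]))],
                                   feature_names=["A", "B", "C"], top_k=2)
        w = table.set_index("feature")["weight"]
        assert w["C"] == 0.0  # outside the top 2

    def test_max_weight_exactly_one(self, rng):
        folds = [(rng.normal(size=(10, 3)), rng.normal(size=3)) for _ in range(4)]
        table = feature_importance(folds, feature_names=[f"f{i}" for i in range(10)])
        assert table["weight"].max() == pytest.approx(1.0)

    def test_empty_folds(self):
        table = feature_importance([], feature_names=["a"])
        assert table.empty
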