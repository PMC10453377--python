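"""PLS1 fit, LV cap, cross-validation against brute-force oracles."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from nirbran import (
    CVResult,
    PLSModel,
    PretreatmentSpec,
    cross_validate,
    evaluate,
    fit,
    lv_cap,
    select_lvs,
)
from nirbran.pls import _fit_predict_path


class TestFit:
    def test_univariate_equals_least_squares(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 20)
        y = 2.0 * x + 0.5 + rng.normal(0, 0.1, 20)
        model = fit(x[:, None], y, 1)
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(model.predict(x[:, None]),
                                   slope * x + intercept, atol=1e-10)

    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        beta = np.array([1.0, -2.0, 0.5])
        y = X @ beta + 4.0
        model = fit(X, y, 3)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse <= 1e-8

    @pytest.mark.parametrize("n_lvs", [1, 2, 3])
    def test_matches_independent_sklearn_pls(self, n_lvs):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        model = fit(X, y, n_lvs, enforce_cap=False)
        ref = PLSRegression(n_components=n_lvs, scale=False).fit(X, y)
        np.testing.assert_allclose(model.coef, ref.coef_.ravel(), atol=1e-8)
        np.testing.assert_allclose(
            model.predict(X), ref.predict(X).ravel(), atol=1e-8
        )

    def test_cap_enforced_with_message(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 10))
        with pytest.raises(ValueError, match="one tenth"):
            fit(X, rng.normal(size=25), 3)  # cap is floor(25/10) = 2

    def test_lv_cap_values(self):
        assert lv_cap(99) == 9
        assert lv_cap(141) == 14
        assert lv_cap(10) == 1

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = fit(X, y, 3, pretreatment=PretreatmentSpec(("snv",)),
                    pretreatment_state=[None])
        back = PLSModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.coef, model.coef)
        np.testing.assert_allclose(back.predict(X), model.predict(X), atol=1e-14)
        assert back.pretreatment.chain == ("snv",)


class TestCrossValidate:
    def _loo_oracle(self, X, y, max_lvs, chain=None):
        """Explicit refit-and-predict loop, the independent reference."""
        from nirbran.preprocess import apply_chain, msc

        n = len(y)
        press = np.zeros(max_lvs)
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            Xtr, Xte = X[mask], X[i : i + 1]
            if chain is not None:
                prefix = PretreatmentSpec(
                    tuple(op for op in chain.chain if op != "msc")
                )
                if prefix.chain:
                    Xtr, _ = apply_chain(Xtr, prefix)
                    Xte, _ = apply_chain(Xte, prefix)
                if "msc" in chain.chain:
                    Xtr, ref = msc(Xtr)
                    Xte, _ = msc(Xte, reference=ref)
            for a in range(1, max_lvs + 1):
                m = fit(Xtr, y[mask], a, enforce_cap=False)
                press[a - 1] += float((m.predict(Xte)[0] - y[i]) ** 2)
        return np.sqrt(press / n)

    def test_loo_equals_brute_force_loop(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 6))
        y = rng.normal(size=8) + X[:, 0]
        # small n: the one-tenth cap would forbid 3 LVs; bypass it for the toy
        res = cross_validate(X, y, max_lvs=3, chain=None, enforce_cap=False)
        np.testing.assert_allclose(res.rmsecv, self._loo_oracle(X, y, 3), atol=1e-8)

    def test_loo_with_msc_refit_matches_oracle(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(0.2, 1.0, 12)
        X = base[None, :] * rng.uniform(0.8, 1.2, (9, 1)) + rng.normal(0, 0.05, (9, 12))
        y = X @ rng.normal(size=12)
        chain = PretreatmentSpec(("msc",))
        res = cross_validate(X, y, max_lvs=3, chain=chain, enforce_cap=False)
        np.testing.assert_allclose(
            res.rmsecv, self._loo_oracle(X, y, 3, chain=chain), atol=1e-8
        )

    def test_kfold_matches_manual_folds(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 5))
        y = X[:, 1] + rng.normal(0, 0.1, 20)
        res = cross_validate(X, y, max_lvs=2, cv=4)
        press = np.zeros(2)
        for j in range(4):
            test = np.arange(20) % 4 == j
            preds = _fit_predict_path(X[~test], y[~test], X[test], 2)
            press += ((preds - y[test][:, None]) ** 2).sum(axis=0)
        np.testing.assert_allclose(res.rmsecv, np.sqrt(press / 20), atol=1e-10)

    def test_perfect_linear_data_reaches_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 4))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5])
        res = cross_validate(X, y, max_lvs=4)
        assert res.rmsecv[3] < 1e-8

    def test_cap_violation_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 10))
        with pytest.raises(ValueError, match="cap"):
            cross_validate(X, rng.normal(size=30), max_lvs=5)

    def test_constant_response_flagged(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(15, 4))
        with pytest.raises(ValueError, match="constant response"):
            cross_validate(X, np.full(15, 3.0), max_lvs=1)


class TestSelectLvs:
    @pytest.mark.parametrize(
        "table,expected",
        [([0.5, 0.3, 0.31], 2), ([0.3, 0.3], 1), ([0.5, 0.4, 0.3, 0.2], 4)],
    )
    def test_argmin_with_tie_to_fewer(self, table, expected):
        assert select_lvs(np.array(table)) == expected


class TestEvaluate:
    def _identity_model(self):
        # univariate pass-through: yhat = x
        return PLSModel(
            n_lvs=1, x_mean=np.zeros(1), y_mean=0.0,
            weights=np.ones((1, 1)), loadings=np.ones((1, 1)),
            y_loadings=np.ones(1), coef=np.ones(1),
        )

    def test_perfect_prediction(self):
        m = self._identity_model()
        y = np.array([4.0, 5.0, 6.0])
        r2, rmse = evaluate(m, y[:, None], y)
        assert r2 == pytest.approx(1.0) and rmse == pytest.approx(0.0)

    def test_constant_prediction_gives_zero_r2(self):
        y = np.array([4.0, 5.0, 6.0])
        m = PLSModel(
            n_lvs=1, x_mean=np.zeros(1), y_mean=float(y.mean()),
            weights=np.zeros((1, 1)), loadings=np.zeros((1, 1)),
            y_loadings=np.zeros(1), coef=np.zeros(1),
        )
        r2, _ = evaluate(m, y[:, None], y)
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_three_point_case(self):
        m = self._identity_model()
        yhat_src = np.array([4.0, 5.0, 7.0])  # model emits its input
        y = np.array([4.0, 5.0, 6.0])
        r2, rmse = evaluate(m, yhat_src[:, None], y)
        assert rmse == pytest.approx(np.sqrt(1.0 / 3.0))
        assert r2 == pytest.approx(0.5)

    def test_column_rescaling_invariance_at_full_rank(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 3))
        y = X @ np.array([1.0, -1.0, 2.0]) + rng.normal(0, 0.1, 30)
        X2 = X.copy()
        X2[:, 1] *= 37.0
        m1 = fit(X, y, 3)
        m2 = fit(X2, y, 3)
        np.testing.assert_allclose(m1.predict(X), m2.predict(X2), atol=1e-8)
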