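"""Logistic fit, ROC threshold selection, evaluation and cross-validation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from srqa.classifier import (
    TAU_GRID,
    evaluate,
    fit_logistic,
    kfold_cv,
    load_model,
    predict_proba,
    roc_threshold,
    save_model,
)
from srqa.features import AF, NON_AF


def make_df(X, y01, names=None):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["label"] = np.where(np.asarray(y01).astype(bool), AF, NON_AF)
    return df


def simulate_logistic(beta, n, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta) - 1))
    p = 1.0 / (1.0 + np.exp(-(beta[0] + X @ beta[1:])))
    return make_df(X, rng.uniform(size=n) < p)


class TestFit:
    def test_parameter_recovery(self):
        beta = np.array([0.4, 1.2, -0.8, 0.5])
        m = fit_logistic(simulate_logistic(beta, 5000, seed=123),
                         covariates=["x0", "x1", "x2"])
        assert m.converged
        z = np.abs((m.coefficients - beta) / m.standard_errors)
        assert (z < 3).all()

    def test_bias_shrinks_with_sample_size(self):
        beta = np.array([0.0, 1.0])
        errs = []
        for n in (500, 5000):
            reps = [
                fit_logistic(simulate_logistic(beta, n, seed=1000 * n + r),
                             covariates=["x0"]).coefficients[1]
                for r in range(8)
            ]
            errs.append(abs(np.mean(reps) - 1.0))
        assert errs[1] < errs[0] + 0.02

    def test_duplicating_rows_preserves_estimates(self):
        df = simulate_logistic(np.array([0.2, 0.7]), 300, seed=5)
        a = fit_logistic(df, covariates=["x0"])
        b = fit_logistic(pd.concat([df, df], ignore_index=True), covariates=["x0"])
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-6)

    def test_single_class_rejected(self):
        df = make_df(np.random.default_rng(0).normal(size=(20, 2)), np.ones(20))
        with pytest.raises(ValueError):
            fit_logistic(df, covariates=["x0", "x1"])

    def test_zero_variance_covariate_dropped_with_warning(self):
        df = simulate_logistic(np.array([0.0, 1.0]), 200, seed=9)
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            m = fit_logistic(df, covariates=["x0", "flat"])
        assert m.dropped_covariates == ["flat"]
        assert m.covariate_names == ["x0"]

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        df = make_df(x[:, None], x)
        with pytest.warns(UserWarning, match="separation"):
            m = fit_logistic(df, covariates=["x0"])
        assert not m.converged
        # last-iterate coefficients still separate the classes
        p = predict_proba(m, df)
        assert (p[x == 1] > 0.9).all() and (p[x == 0] < 0.1).all()

    def test_significance_stars(self):
        beta = np.array([0.0, 3.0, 0.0])
        m = fit_logistic(simulate_logistic(beta, 4000, seed=77),
                         covariates=["x0", "x1"])
        stars = m.significance_stars()
        assert stars[1] == "**"  # strong effect


class TestPredict:
    def test_zero_covariates_give_half(self):
        df = simulate_logistic(np.array([0.3, 1.0, -1.0]), 50, seed=2)
        m = fit_logistic(df, covariates=["x0", "x1"])
        m.coefficients = np.zeros(3)
        assert predict_proba(m, df) == pytest.approx(np.full(50, 0.5))

    def test_matches_hand_computed_linear_predictor(self):
        df = simulate_logistic(np.array([0.3, 1.0, -1.0]), 200, seed=3)
        m = fit_logistic(df, covariates=["x0", "x1"])
        rows = df.iloc[[0, 57, 123]]
        for _, row in rows.iterrows():
            eta = (
                m.coefficients[0]
                + m.coefficients[1] * row["x0"]
                + m.coefficients[2] * row["x1"]
            )
            expected = 1.0 / (1.0 + np.exp(-eta))
            assert predict_proba(m, rows.loc[[row.name]])[0] == pytest.approx(expected)

    def test_monotone_in_positive_coefficient(self):
        df = simulate_logistic(np.array([0.0, 2.0]), 500, seed=4)
        m = fit_logistic(df, covariates=["x0"])
        assert m.coefficients[1] > 0
        lo, hi = df.copy(), df.copy()
        hi["x0"] += 1.0
        assert (predict_proba(m, hi) > predict_proba(m, lo)).all()

    def test_name_mismatch_rejected(self):
        df = simulate_logistic(np.array([0.0, 1.0]), 100, seed=6)
        m = fit_logistic(df, covariates=["x0"])
        with pytest.raises(ValueError, match="missing"):
            predict_proba(m, df.rename(columns={"x0": "y0"}))


class TestRoc:
    def test_grid_shape_and_monotonicity(self):
        rng = np.random.default_rng(12)
        probs = rng.uniform(size=400)
        labels = np.where(rng.uniform(size=400) < probs, AF, NON_AF)
        roc = roc_threshold(probs, labels)
        assert len(roc.grid_tau) == 1001
        assert (np.diff(roc.grid_se) <= 1e-12).all()
        assert (np.diff(roc.grid_fpr) <= 1e-12).all()

    def test_perfectly_separated_probabilities(self):
        probs = np.r_[np.full(10, 0.9), np.full(10, 0.1)]
        labels = [AF] * 10 + [NON_AF] * 10
        roc = roc_threshold(probs, labels)
        i = np.searchsorted(roc.grid_tau, roc.chosen_tau)
        assert roc.grid_fpr[i] == 0.0 and roc.grid_se[i] == 1.0
        # smallest grid tau with distance zero: 0.1 itself (rule is strict >)
        assert roc.chosen_tau == pytest.approx(0.100)

    def test_tau_zero_flags_everything(self):
        probs = np.array([0.2, 0.7, 0.9, 0.4])
        roc = roc_threshold(probs, [AF, AF, NON_AF, NON_AF])
        assert roc.grid_se[0] == 1.0 and roc.grid_fpr[0] == 1.0

    def test_uninformative_probabilities(self):
        rng = np.random.default_rng(21)
        probs = rng.uniform(size=4000)
        labels = np.where(rng.uniform(size=4000) < 0.5, AF, NON_AF)
        roc = roc_threshold(probs, labels)
        i = np.searchsorted(roc.grid_tau, roc.chosen_tau)
        assert roc.grid_se[i] == pytest.approx(1 - roc.grid_fpr[i], abs=0.06)
        assert roc.grid_se[i] == pytest.approx(0.5, abs=0.06)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_threshold(np.array([0.1, 0.9]), [AF, AF])


class TestEvaluate:
    def test_printed_formulas(self):
        probs = np.r_[np.full(96, 0.9), np.full(4, 0.1), np.full(95, 0.1), np.full(5, 0.9)]
        labels = [AF] * 100 + [NON_AF] * 100
        rep = evaluate(probs, labels, 0.5)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (96, 4, 95, 5)
        assert rep.se == pytest.approx(0.96)
        assert rep.sp == pytest.approx(0.95)
        assert rep.acc == pytest.approx(0.955)

    def test_all_correct(self):
        rep = evaluate(np.array([0.9, 0.1]), [AF, NON_AF], 0.5)
        assert rep.se == rep.sp == rep.acc == 1.0

    def test_against_brute_force_counter(self):
        rng = np.random.default_rng(31)
        probs = rng.uniform(size=200)
        labels = np.where(rng.uniform(size=200) < 0.4, AF, NON_AF)
        tau = 0.37
        rep = evaluate(probs, labels, tau)
        tp = tn = fp = fn = 0
        for p, lab in zip(probs, labels):
            pred_af = p > tau
            if pred_af and lab == AF:
                tp += 1
            elif pred_af:
                fp += 1
            elif lab == AF:
                fn += 1
            else:
                tn += 1
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (tp, tn, fp, fn)
        P, N = tp + fn, tn + fp
        assert rep.acc == pytest.approx((rep.se * P + rep.sp * N) / (P + N))


class TestKFold:
    @staticmethod
    def separated_df(n_per_class=120, seed=0):
        rng = np.random.default_rng(seed)
        X = np.r_[rng.normal(-2.5, 1, n_per_class), rng.normal(2.5, 1, n_per_class)]
        return make_df(X[:, None], np.r_[np.zeros(n_per_class), np.ones(n_per_class)])

    def test_every_row_held_out_once(self):
        df = self.separated_df(100)
        res = kfold_cv(df, k=10, seed=1, covariates=["x0"])
        total = sum(r.tp + r.tn + r.fp + r.fn for r in res.per_fold)
        assert total == len(df)
        assert all(
            r.tp + r.tn + r.fp + r.fn == len(df) // 10 for r in res.per_fold
        )

    def test_strong_separation_gives_high_accuracy(self):
        res = kfold_cv(self.separated_df(150, seed=7), k=10, seed=2,
                       covariates=["x0"])
        assert res.median_acc >= 0.95

    def test_identical_seed_identical_summary(self):
        df = self.separated_df(100, seed=3)
        a = kfold_cv(df, k=5, seed=42, covariates=["x0"])
        b = kfold_cv(df, k=5, seed=42, covariates=["x0"])
        pd.testing.assert_frame_equal(a.quartiles, b.quartiles)

    def test_quartiles_ordered(self):
        res = kfold_cv(self.separated_df(100, seed=4), k=5, seed=0,
                       covariates=["x0"])
        q = res.quartiles
        assert (q["p25"] <= q["median"]).all() and (q["median"] <= q["p75"]).all()

    def test_small_class_rejected(self):
        df = self.separated_df(5)
        with pytest.raises(ValueError):
            kfold_cv(df, k=10, covariates=["x0"])


def test_model_json_round_trip(tmp_path):
    df = simulate_logistic(np.array([0.1, 1.0]), 300, seed=15)
    m = fit_logistic(df, covariates=["x0"])
    path = tmp_path / "model.json"
    save_model(m, tau=0.42, spec={"w": 60, "m": 3}, path=path)
    back, tau, spec = load_model(path)
    assert tau == 0.42 and spec == {"w": 60, "m": 3}
    assert back.covariate_names == m.covariate_names
    assert np.allclose(back.coefficients, m.coefficients)
    assert np.allclose(back.wald_p_values, m.wald_p_values, equal_nan=True)
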