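"""PLS1 day regression: fitting, grouped CV, model selection, metrics."""

import numpy as np
import pandas as pd
import pytest

import aquamon as am
from aquamon.pls import PLSCVResult


def simpls_1lv_oracle(X, y):
    """One-latent-variable PLS1 regression vector via SIMPLS (for a single
    response and one component, the weight is the normalized X'y, and the
    coefficient is w q / (p'w)).  Independent of the package's fit path."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    s = Xc.T @ yc
    w = s / np.linalg.norm(s)
    t = Xc @ w
    p = Xc.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    return w * q / (p @ w)


def planted_table(n_seeds=6, rows_per_seed=8, p=25, noise=0.0, seed=0):
    """Spectra with a linear day signal along a known direction."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=p)
    v /= np.linalg.norm(v)
    days = np.tile(np.arange(4, 4 + 2 * rows_per_seed, 2), n_seeds)
    seeds = np.repeat(np.arange(1, n_seeds + 1), rows_per_seed)
    X = np.outer(days, v) + noise * rng.normal(size=(days.size, p))
    meta = pd.DataFrame({"sample_type": "s", "seed_id": seeds, "day": days})
    return am.SpectraTable(700.0 + np.arange(p), X, meta), v


class TestFitPLS1:
    def test_rank_one_single_factor_fits_exactly(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=40)
        X = np.outer(t, rng.normal(size=12))
        y = 3.0 * t + 1.0
        model = am.fit_pls1(X, y, 1)
        m = am.regression_metrics(y, model.predict(X))
        assert m["R2"] == pytest.approx(1.0, abs=1e-10)

    def test_zero_latent_variables_predicts_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = am.fit_pls1(X, y, 0)
        np.testing.assert_allclose(model.predict(X), y.mean())

    def test_one_lv_matches_simpls_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        model = am.fit_pls1(X, y, 1)
        np.testing.assert_allclose(model.regression_vector,
                                   simpls_1lv_oracle(X, y), atol=1e-6)

    def test_prediction_identity_and_score_orthogonality(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 20))
        y = X @ rng.normal(size=20) + 0.1 * rng.normal(size=30)
        model = am.fit_pls1(X, y, 4)
        manual = (X - model.x_mean) @ model.regression_vector + model.intercept
        np.testing.assert_allclose(model.predict(X), manual, atol=1e-10)
        cross = model.scores.T @ model.scores
        np.testing.assert_allclose(cross - np.diag(np.diag(cross)), 0.0,
                                   atol=1e-8)

    def test_constant_shift_of_spectra_leaves_coefficients(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        b0 = am.fit_pls1(X, y, 3).regression_vector
        b1 = am.fit_pls1(X + 5.0, y, 3).regression_vector
        np.testing.assert_allclose(b0, b1, atol=1e-8)

    def test_planted_direction_recovered(self):
        table, v = planted_table(noise=1e-4, seed=5)
        model = am.fit_pls1(table.values, np.asarray(table.meta["day"], float), 1)
        b = model.regression_vector
        cos = abs(b @ v) / np.linalg.norm(b)
        assert cos >= 0.95

    def test_invalid_inputs_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 5))
        with pytest.raises(ValueError, match="variance"):
            am.fit_pls1(X, np.ones(8), 1)
        with pytest.raises(ValueError, match="n_lv"):
            am.fit_pls1(X, np.arange(8.0), 8)


class TestRegressionMetrics:
    def test_perfect_and_mean_predictions(self):
        y = np.array([4.0, 6.0, 8.0])
        assert am.regression_metrics(y, y) == {"R2": 1.0, "RMSE": 0.0}
        m = am.regression_metrics(y, np.full(3, y.mean()))
        assert m["R2"] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        m = am.regression_metrics([4.0, 6.0, 8.0], [5.0, 6.0, 7.0])
        assert m["RMSE"] == pytest.approx(np.sqrt(2 / 3))
        assert m["R2"] == pytest.approx(0.75)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            am.regression_metrics([1.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="length"):
            am.regression_metrics([1.0, 2.0], [1.0])


class TestOneSeedOutCV:
    def test_fold_count_equals_distinct_seeds(self):
        table, _ = planted_table(n_seeds=6, noise=0.05)
        cv = am.one_seed_out_cv(table, max_lv=4)
        assert len(cv.fold_seeds) == 6
        assert set(cv.predictions["seed_id"]) == set(range(1, 7))
        assert cv.predictions.notna().all().all()

    def test_held_out_seed_y_does_not_leak(self):
        table, _ = planted_table(n_seeds=5, noise=0.05, seed=6)
        cv = am.one_seed_out_cv(table, max_lv=3)
        tampered = am.SpectraTable(table.wavelengths, table.values,
                                   table.meta.copy(), table.provenance)
        sel = tampered.meta["seed_id"] == 3
        tampered.meta.loc[sel, "day"] = 999.0
        cv2 = am.one_seed_out_cv(tampered, max_lv=3)
        mask = (cv.predictions["seed_id"] == 3).to_numpy()
        np.testing.assert_allclose(
            cv.predictions.loc[mask, "pred_lv3"],
            cv2.predictions.loc[mask, "pred_lv3"], atol=1e-10)

    def test_duplicating_held_out_spectra_leaves_fold_predictions(self):
        table, _ = planted_table(n_seeds=5, noise=0.05, seed=7)
        cv = am.one_seed_out_cv(table, max_lv=3)
        dup_rows = (table.meta["seed_id"] == 2).to_numpy()
        values = np.vstack([table.values, table.values[dup_rows]])
        meta = pd.concat([table.meta, table.meta[dup_rows]], ignore_index=True)
        bigger = am.SpectraTable(table.wavelengths, values, meta)
        cv2 = am.one_seed_out_cv(bigger, max_lv=3)
        base = cv.predictions[cv.predictions["seed_id"] == 2]["pred_lv3"]
        new = cv2.predictions[cv2.predictions["seed_id"] == 2]["pred_lv3"]
        np.testing.assert_allclose(new.to_numpy()[: len(base)],
                                   base.to_numpy(), atol=1e-10)

    def test_metrics_table_shape_and_monotone_calibration(self):
        table, _ = planted_table(n_seeds=6, noise=0.2, seed=8)
        cv = am.one_seed_out_cv(table, max_lv=5)
        assert list(cv.metrics.columns) == ["n_lv", "R2tr", "RMSEC", "R2cv",
                                            "RMSECV"]
        assert len(cv.metrics) == 5
        rmsec = cv.metrics["RMSEC"].to_numpy()
        assert np.all(np.diff(rmsec) <= 1e-9)  # calibration error never grows

    def test_fewer_than_two_seeds_rejected(self):
        table, _ = planted_table(n_seeds=1)
        with pytest.raises(ValueError, match="2 distinct seeds"):
            am.one_seed_out_cv(table)


class TestSelectNLV:
    def _fake_cv(self, rmsecv):
        metrics = pd.DataFrame({
            "n_lv": np.arange(1, len(rmsecv) + 1), "R2tr": 0.9, "RMSEC": 1.0,
            "R2cv": 0.8, "RMSECV": rmsecv})
        return PLSCVResult(pd.DataFrame(), metrics,
                           int(metrics["n_lv"][np.argmin(rmsecv)]))

    def test_tie_broken_toward_fewer_lvs(self):
        assert am.select_n_lv(self._fake_cv([3.0, 2.1, 2.1, 2.5])) == 2

    def test_monotone_decreasing_takes_max(self):
        assert am.select_n_lv(self._fake_cv([3.0, 2.5, 2.0, 1.5])) == 4

    def test_noiseless_rank_two_signal_selects_two(self):
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n_seeds, rows = 6, 10
            seeds = np.repeat(np.arange(n_seeds), rows)
            t1 = rng.normal(size=seeds.size)
            t2 = rng.normal(size=seeds.size)
            v1, v2 = rng.normal(size=(2, 20))
            X = np.outer(t1, v1) + np.outer(t2, v2)
            y = t1 + 2.0 * t2
            meta = pd.DataFrame({"seed_id": seeds, "day": y})
            table = am.SpectraTable(700.0 + np.arange(20), X, meta)
            cv = am.one_seed_out_cv(table, max_lv=5)
            hits.append(am.select_n_lv(cv))
        assert all(abs(h - 2) <= 1 for h in hits)
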