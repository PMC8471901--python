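"""PLS1 regression of developmental day on spectra.

Fitting uses the NIPALS decomposition (single response, mean-centered X
and y).  Model selection and validation follow the grouped one-seed-out
scheme: every spectrum of one biological replicate (seed) is held out per
fold, centering constants are recomputed on each training set, and the
cross-validation metrics (R2cv, RMSECV) are computed over the pooled
held-out predictions.  Because NIPALS components nest, the regression
vector for every candidate number of latent variables is obtained from a
single maximal fit per fold via

    B_k = W_k (P_k^T W_k)^{-1} q_k .
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .spectra import SpectraTable

__all__ = ["PLSModel", "PLSCVResult", "fit_pls1", "one_seed_out_cv",
           "select_n_lv", "regression_metrics"]


@dataclass
class PLSModel:
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # (p, n_lv)
    x_loadings: np.ndarray    # (p, n_lv)
    y_loadings: np.ndarray    # (n_lv,)
    regression_vector: np.ndarray  # (p,)
    intercept: float
    n_lv: int
    scores: np.ndarray | None = None  # (n, n_lv) training scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return (X - self.x_mean) @ self.regression_vector + self.intercept


def _nipals_decomposition(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Centered NIPALS PLS1 via sklearn; returns (W, P, q, T) truncated to
    the effectively extracted components (deflation can exhaust y early)."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*residual is constant.*")
        pls = PLSRegression(n_components=n_lv, scale=False).fit(Xc, yc)
    W = pls.x_weights_
    P = pls.x_loadings_
    q = pls.y_loadings_.ravel()
    T = pls.x_scores_
    norms = np.linalg.norm(W, axis=0)
    a_eff = int(np.sum(norms > 0))
    return W[:, :a_eff], P[:, :a_eff], q[:a_eff], T[:, :a_eff]


def _coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray,
               ks: range | list[int]) -> dict[int, np.ndarray]:
    """Regression vectors for every k in ks (k <= number of components)."""
    out = {}
    for k in ks:
        Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
        out[k] = Wk @ np.linalg.solve(Pk.T @ Wk, qk)
    return out


def fit_pls1(X: np.ndarray | SpectraTable, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables (0 = predict the mean)."""
    if isinstance(X, SpectraTable):
        X = X.values
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y differ in length")
    if np.var(y) == 0:
        raise ValueError("y has zero variance")
    if n_lv > min(n - 1, p):
        raise ValueError(f"n_lv must be <= min(n_rows - 1, n_columns) = {min(n - 1, p)}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if n_lv == 0:
        return PLSModel(x_mean, y_mean, np.zeros((p, 0)), np.zeros((p, 0)),
                        np.zeros(0), np.zeros(p), y_mean, 0)
    W, P, q, T = _nipals_decomposition(X - x_mean, y - y_mean, n_lv)
    a = W.shape[1]
    b = _coef_path(W, P, q, [a])[a]
    return PLSModel(x_mean, y_mean, W, P, q, b, y_mean, a, scores=T)


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """R2 (about the mean of y_true) and RMSE, in y units."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred differ in length")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R2 undefined: y_true is constant")
    ss_res = np.sum((y_true - y_pred) ** 2)
    return {"R2": float(1.0 - ss_res / ss_tot),
            "RMSE": float(np.sqrt(np.mean((y_true - y_pred) ** 2)))}


@dataclass
class PLSCVResult:
    """Pooled one-seed-out predictions and per-LV metrics."""

    predictions: pd.DataFrame      # seed_id, y_true, pred_lv1..pred_lvK
    metrics: pd.DataFrame          # n_lv, R2tr, RMSEC, R2cv, RMSECV
    chosen_n_lv: int
    fold_seeds: tuple = ()

    @property
    def y_pred(self) -> np.ndarray:
        """Held-out predictions at the chosen number of latent variables."""
        return self.predictions[f"pred_lv{self.chosen_n_lv}"].to_numpy()

    def metric(self, name: str, n_lv: int | None = None) -> float:
        n_lv = self.chosen_n_lv if n_lv is None else n_lv
        row = self.metrics.loc[self.metrics["n_lv"] == n_lv]
        return float(row[name].iloc[0])


def one_seed_out_cv(table: SpectraTable, y_key: str = "day",
                    max_lv: int = 12) -> PLSCVResult:
    """Leave-one-seed-out grouped cross-validation of PLS1.

    Every spectrum of the held-out seed (all days and positions) is
    excluded from its training fold; centering constants are recomputed
    per fold.  Metrics are computed per candidate LV count over the
    pooled held-out predictions, and the chosen LV count minimizes RMSECV
    (ties toward fewer LVs).
    """
    if "seed_id" not in table.meta.columns:
        raise ValueError("rows carry no seed_id; grouped CV impossible")
    X = table.values
    y = np.asarray(table.meta[y_key], float)
    if np.var(y) == 0:
        raise ValueError(f"{y_key} has zero variance")
    seeds = sorted(pd.unique(table.meta["seed_id"]))
    if len(seeds) < 2:
        raise ValueError("grouped CV needs at least 2 distinct seeds")
    seed_col = table.meta["seed_id"].to_numpy()

    n, p = X.shape
    k_max = max_lv
    for s in seeds:
        n_train = int(np.sum(seed_col != s))
        k_max = min(k_max, n_train - 1, p)
    if k_max < 1:
        raise ValueError("not enough data for even one latent variable")

    preds = np.full((n, k_max), np.nan)
    for s in seeds:
        test = seed_col == s
        if not test.any():
            warnings.warn(f"seed {s!r} has no rows; fold skipped", stacklevel=2)
            continue
        Xtr, ytr = X[~test], y[~test]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        W, P, q, _ = _nipals_decomposition(Xtr - xm, ytr - ym, k_max)
        path = _coef_path(W, P, q, range(1, W.shape[1] + 1))
        Xt = X[test] - xm
        for k in range(1, k_max + 1):
            b = path[min(k, W.shape[1])]  # deflation exhausted: reuse last
            preds[test, k - 1] = Xt @ b + ym

    # calibration on the full data
    xm, ym = X.mean(axis=0), y.mean()
    W, P, q, _ = _nipals_decomposition(X - xm, y - ym, k_max)
    cal_path = _coef_path(W, P, q, range(1, W.shape[1] + 1))

    rows = []
    for k in range(1, k_max + 1):
        b = cal_path[min(k, W.shape[1])]
        fit = (X - xm) @ b + ym
        cal = regression_metrics(y, fit)
        cv = regression_metrics(y, preds[:, k - 1])
        rows.append({"n_lv": k, "R2tr": cal["R2"], "RMSEC": cal["RMSE"],
                     "R2cv": cv["R2"], "RMSECV": cv["RMSE"]})
    metrics = pd.DataFrame(rows)
    chosen = select_n_lv_from_metrics(metrics)

    pred_df = pd.DataFrame({"seed_id": seed_col, "y_true": y})
    for k in range(1, k_max + 1):
        pred_df[f"pred_lv{k}"] = preds[:, k - 1]
    return PLSCVResult(pred_df, metrics, chosen, tuple(seeds))


def select_n_lv_from_metrics(metrics: pd.DataFrame) -> int:
    rmsecv = metrics["RMSECV"].to_numpy()
    return int(metrics["n_lv"].iloc[int(np.argmin(rmsecv))])


def select_n_lv(cv: PLSCVResult, max_lv: int = 12) -> int:
    """LV count minimizing RMSECV among 1..max_lv; ties go to fewer LVs."""
    sub = cv.metrics[cv.metrics["n_lv"] <= max_lv]
    return select_n_lv_from_metrics(sub)
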