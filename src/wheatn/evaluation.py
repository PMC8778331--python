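"""Accuracy metrics and the cross-validation harness.

Metrics (all on pooled out-of-fold predictions):

* RMSE = sqrt(mean((ŷ − y)²)), MAE = mean(|ŷ − y|)  — RMSE ≥ MAE always;
* NSE  = 1 − SS_res/SS_tot, the Nash–Sutcliffe efficiency (≤ 1, 0 for the
  mean predictor, penalizes bias);
* R²   = squared Pearson correlation of observations and predictions (the
  cross-validation R² reported alongside NSE; the two coincide only for an
  unbiased linear fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be equal-length 1-D vectors")
    if y.size == 0:
        raise ValueError("empty vectors")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("inputs must be finite")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean square error."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def mae(y, yhat) -> float:
    """Mean absolute error."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(yhat - y)))


def nse(y, yhat) -> float:
    """Nash–Sutcliffe modeling efficiency, 1 − SS_res/SS_tot."""
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("NSE undefined for constant observations")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def r2(y, yhat) -> float:
    """Squared Pearson correlation between observations and predictions."""
    y, yhat = _check_pair(y, yhat)
    if np.std(y) == 0:
        raise ValueError("R² undefined for constant observations")
    if np.std(yhat) == 0:
        return float("nan")
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


@dataclass
class CVResult:
    """Pooled out-of-fold predictions plus aggregate metrics for one model."""

    y_true: np.ndarray
    y_pred: np.ndarray
    fold: np.ndarray
    method: str = ""
    target: str = ""
    stage: str = ""
    feature_set: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def rmse(self) -> float:
        return rmse(self.y_true, self.y_pred)

    @property
    def mae(self) -> float:
        return mae(self.y_true, self.y_pred)

    @property
    def nse(self) -> float:
        return nse(self.y_true, self.y_pred)

    @property
    def r2(self) -> float:
        return r2(self.y_true, self.y_pred)

    def metrics(self) -> dict:
        return {"R2": self.r2, "RMSE": self.rmse, "MAE": self.mae, "NSE": self.nse}


def kfold_cv(
    estimator,
    X,
    y,
    k: int = 10,
    seed: int = 0,
    *,
    method: str = "",
    target: str = "",
    stage: str = "",
    feature_set: str = "",
) -> CVResult:
    """Seeded k-fold cross-validation with pooled out-of-fold metrics.

    Every sample is predicted exactly once by a model trained without it;
    fold sizes differ by at most one; ``k = n`` gives leave-one-out.
    ``estimator`` is a scikit-learn-style estimator (cloned per fold).
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError("need n >= k >= 2")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(n, dtype=float)
    fold_id = np.empty(n, dtype=int)
    for f, (tr, te) in enumerate(kf.split(Xdf)):
        m = clone(estimator).fit(Xdf.iloc[tr], y[tr])
        pred[te] = np.asarray(m.predict(Xdf.iloc[te]), dtype=float).ravel()
        fold_id[te] = f
    return CVResult(
        y_true=y, y_pred=pred, fold=fold_id,
        method=method, target=target, stage=stage, feature_set=feature_set,
    )


def results_frame(results: list[CVResult]) -> pd.DataFrame:
    """Flat per-model metric table from a list of CV results."""
    rows = []
    for r in results:
        rows.append(
            {
                "target": r.target,
                "stage": r.stage,
                "method": r.method,
                "feature_set": r.feature_set,
                **r.metrics(),
                **r.extra,
            }
        )
    return pd.DataFrame(rows)


def comparison_report(results: list[CVResult]) -> dict[str, pd.DataFrame]:
    """Method-comparison tables across targets and stage groupings.

    Returns one wide table per metric (R2, RMSE, MAE, NSE): rows are
    (target, stage), columns are (method, feature_set) cells; duplicate
    (target, stage, method, feature_set) keys are an error.
    """
    if not results:
        raise ValueError("no results to report")
    flat = results_frame(results)
    keys = flat[["target", "stage", "method", "feature_set"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (target, stage, method, feature_set) result keys")
    out = {}
    for metric in ("R2", "RMSE", "MAE", "NSE"):
        out[metric] = flat.pivot_table(
            index=["target", "stage"],
            columns=["method", "feature_set"],
            values=metric,
            aggfunc="first",
        )
    return out


def render_report(tables: dict[str, pd.DataFrame]) -> str:
    """Markdown rendering of the comparison tables."""
    parts = []
    for metric, tab in tables.items():
        parts.append(f"## {metric}\n")
        parts.append(tab.round(3).to_markdown())
        parts.append("")
    return "\n".join(parts)
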