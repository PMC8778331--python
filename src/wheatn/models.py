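"""Estimators for N-indicator retrieval: parametric, stepwise MLR and GPR-SBBR.

Three families, all scikit-learn-style estimators (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing underscore):

* :class:`ParametricRegressor` — the five classical single-index forms
  (linear, logarithmic, power, exponential, second-order polynomial), with
  power/exponential fitted by least squares in log space;
  :class:`BestIndexRegressor` additionally ranks candidate indices by
  absolute Pearson correlation and picks the form by validation R².
* :class:`StepwiseLinearRegressor` — forward-entry / backward-removal
  stepwise multiple linear regression on partial F tests
  (α_enter = 0.05, α_remove = 0.10).
* :class:`GPRegressor` — Gaussian process regression with the anisotropic
  squared-exponential (ARD) kernel K(xᵢ,xⱼ) = γ·exp(−Σ_b (x_ib − x_jb)²/2σ_b²)
  plus an additive noise term, hyperparameters set by multi-restart marginal-
  likelihood maximisation.  Features are standardized internally so the
  per-feature length scales σ_b are comparable: a large σ_b marks an
  uninformative feature.

:func:`sbbr` implements sequential backward band removal: retrain the GP,
drop the feature with the largest fitted length scale, record the 10-fold
cross-validated RMSE of every visited subset, and select the subset with the
minimum CV RMSE (ties toward fewer features).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

PARAMETRIC_FORMS = ("linear", "logarithmic", "power", "exponential", "poly2")


def se_kernel(x_i, x_j, gamma: float, sigma) -> float:
    """Anisotropic squared-exponential covariance between two feature vectors.

    ``K = γ · exp(−Σ_b (x_ib − x_jb)² / (2 σ_b²))``; symmetric, equal to γ at
    zero distance, and insensitive to feature b in the limit σ_b → ∞.
    """
    x_i = np.asarray(x_i, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float).ravel(), x_i.shape)
    if x_i.shape != x_j.shape:
        raise ValueError("feature vectors must have equal length")
    if gamma <= 0 or np.any(sigma <= 0):
        raise ValueError("kernel hyperparameters must be positive")
    return float(gamma * np.exp(-np.sum((x_i - x_j) ** 2 / (2.0 * sigma**2))))


# ---------------------------------------------------------------------------
# Parametric regression
# ---------------------------------------------------------------------------


def _as_1d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("parametric regression takes a single index column")
        X = X[:, 0]
    return X


class ParametricRegressor(BaseEstimator, RegressorMixin):
    """Single-index parametric regression in one of five classical forms.

    Forms and fitting:

    - ``linear``       y = a + b·x            (ordinary least squares)
    - ``poly2``        y = a + b·x + c·x²     (ordinary least squares)
    - ``logarithmic``  y = a + b·ln x         (OLS on ln x; needs x > 0)
    - ``power``        y = a·x^b              (OLS of ln y on ln x; x, y > 0)
    - ``exponential``  y = a·e^(b·x)          (OLS of ln y on x; y > 0)
    """

    def __init__(self, form: str = "linear"):
        self.form = form

    def fit(self, X, y):
        if self.form not in PARAMETRIC_FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {PARAMETRIC_FORMS}")
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise ValueError("inputs must be finite")
        if self.form in ("logarithmic", "power") and np.any(x <= 0):
            raise ValueError(f"form {self.form!r} requires strictly positive x")
        if self.form in ("power", "exponential") and np.any(y <= 0):
            raise ValueError(f"form {self.form!r} requires strictly positive y")

        if self.form == "linear":
            self.coef_ = np.polynomial.polynomial.polyfit(x, y, 1)
        elif self.form == "poly2":
            self.coef_ = np.polynomial.polynomial.polyfit(x, y, 2)
        elif self.form == "logarithmic":
            self.coef_ = np.polynomial.polynomial.polyfit(np.log(x), y, 1)
        elif self.form == "power":
            c = np.polynomial.polynomial.polyfit(np.log(x), np.log(y), 1)
            self.coef_ = np.array([math.exp(c[0]), c[1]])  # (a, b) in y = a x^b
        else:  # exponential
            c = np.polynomial.polynomial.polyfit(x, np.log(y), 1)
            self.coef_ = np.array([math.exp(c[0]), c[1]])  # (a, b) in y = a e^{bx}

        resid = y - self._evaluate(x)
        self.rmse_ = float(np.sqrt(np.mean(resid**2)))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
        self.n_features_in_ = 1
        return self

    def _evaluate(self, x: np.ndarray) -> np.ndarray:
        a = self.coef_
        if self.form == "linear":
            return a[0] + a[1] * x
        if self.form == "poly2":
            return a[0] + a[1] * x + a[2] * x**2
        if self.form == "logarithmic":
            with np.errstate(invalid="ignore", divide="ignore"):
                return a[0] + a[1] * np.log(x)
        if self.form == "power":
            with np.errstate(invalid="ignore"):
                return a[0] * np.sign(x) * np.abs(x) ** a[1] * (x > 0)
        return a[0] * np.exp(a[1] * x)

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self._evaluate(_as_1d(X))


def fit_parametric(x, y, form: str) -> ParametricRegressor:
    """Fit one parametric form to a single index; thin functional wrapper."""
    return ParametricRegressor(form=form).fit(np.asarray(x, dtype=float), y)


def holdout_split(n_or_records, fraction: float = 0.7, seed: int = 0, stage=None):
    """Seeded random train/validation partition with ⌈fraction·n⌉ training rows.

    When per-record ``stage`` labels are given and more than one stage is
    present, the draw is stratified: training rows are allocated across
    stages by largest remainder so the total still equals ⌈fraction·n⌉.
    Returns ``(train_idx, val_idx)`` as integer arrays.
    """
    n = n_or_records if isinstance(n_or_records, (int, np.integer)) else len(n_or_records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(math.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    if stage is not None:
        stage = np.asarray(stage)
        groups = pd.unique(stage)
        if len(groups) > 1:
            quotas = {g: fraction * np.sum(stage == g) for g in groups}
            base = {g: int(math.floor(q)) for g, q in quotas.items()}
            shortfall = n_train - sum(base.values())
            order = sorted(groups, key=lambda g: quotas[g] - base[g], reverse=True)
            for g in order[:shortfall]:
                base[g] += 1
            train_parts = []
            for g in groups:
                idx = np.flatnonzero(stage == g)
                train_parts.append(rng.permutation(idx)[: base[g]])
            train_idx = np.sort(np.concatenate(train_parts))
            val_idx = np.setdiff1d(np.arange(n), train_idx)
            return train_idx, val_idx
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def select_best_index(
    X: pd.DataFrame,
    y,
    forms=PARAMETRIC_FORMS,
    *,
    fraction: float = 0.7,
    seed: int = 0,
    stage=None,
):
    """Pick the single most correlated index and its best parametric form.

    Indices are ranked by |Pearson r| with the target on the training split
    (ties broken toward registry/column order, logged); all applicable forms
    are fitted to the top index on the training rows and the form with the
    highest validation R² wins.  Returns ``(index_name, fitted_model, info)``.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    train, val = holdout_split(len(y), fraction=fraction, seed=seed, stage=stage)

    best_name, best_r = None, -1.0
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)[train]
        if np.all(~np.isfinite(x)) or np.nanstd(x) == 0:
            continue
        ok = np.isfinite(x)
        if ok.sum() < 3:
            continue
        r = abs(np.corrcoef(x[ok], y[train][ok])[0, 1])
        if np.isfinite(r) and r > best_r + 1e-15:
            best_name, best_r = name, r
    if best_name is None:
        raise ValueError("no usable (non-constant) index column")
    logger.info("selected index %s with |r| = %.3f", best_name, best_r)

    x_tr = X[best_name].to_numpy(dtype=float)[train]
    x_va = X[best_name].to_numpy(dtype=float)[val]
    best_form, best_model, best_val_r2 = None, None, -np.inf
    for form in forms:
        try:
            m = ParametricRegressor(form=form).fit(x_tr, y[train])
        except ValueError:
            continue
        pred = m.predict(x_va)
        if not np.all(np.isfinite(pred)):
            continue
        resid = y[val] - pred
        ss_tot = np.sum((y[val] - y[val].mean()) ** 2)
        val_r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else -np.inf
        if val_r2 > best_val_r2:
            best_form, best_model, best_val_r2 = form, m, val_r2
    if best_model is None:
        raise ValueError("no parametric form applicable to the selected index")
    info = {"abs_r": best_r, "form": best_form, "val_r2": best_val_r2}
    return best_name, best_model, info


class BestIndexRegressor(BaseEstimator, RegressorMixin):
    """Parametric regression on the automatically selected best single index.

    At ``fit`` time the candidate index with the highest |Pearson r| against
    the target is chosen and all five forms are tried on an internal
    train/validation split; prediction uses the winning form refitted on all
    training data.  Usable inside cross-validation.
    """

    def __init__(self, forms=PARAMETRIC_FORMS, fraction: float = 0.7, seed: int = 0):
        self.forms = forms
        self.fraction = fraction
        self.seed = seed

    def fit(self, X, y):
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        name, model, info = select_best_index(
            Xdf, y, forms=self.forms, fraction=self.fraction, seed=self.seed
        )
        # refit the winning form on all rows for prediction
        self.index_ = name
        self.form_ = info["form"]
        try:
            self.model_ = ParametricRegressor(form=self.form_).fit(
                Xdf[name].to_numpy(dtype=float), y
            )
        except ValueError:  # full-data domain violation: keep split fit
            self.model_ = model
        self.columns_ = list(Xdf.columns)
        self.n_features_in_ = Xdf.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X, dtype=float), columns=self.columns_
        )
        pred = self.model_.predict(Xdf[self.index_].to_numpy(dtype=float))
        return np.nan_to_num(pred, nan=float(np.nanmean(pred)))


# ---------------------------------------------------------------------------
# Stepwise multivariable linear regression
# ---------------------------------------------------------------------------


class StepwiseLinearRegressor(BaseEstimator, RegressorMixin):
    """Forward-entry / backward-removal stepwise multiple linear regression.

    At each step the candidate whose partial F test (equivalently the t test
    of its coefficient) has the smallest p-value enters if p < ``alpha_enter``;
    entered features whose partial p-value exceeds ``alpha_remove`` are
    dropped.  With no qualifying feature the model is intercept-only.
    Perfectly collinear candidates (e.g. duplicated columns) never enter.
    """

    def __init__(self, alpha_enter: float = 0.05, alpha_remove: float = 0.10, max_iter: int = 100):
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove
        self.max_iter = max_iter

    def fit(self, X, y):
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if len(Xdf) != len(y):
            raise ValueError("X and y must have equal length")
        cols = list(Xdf.columns)
        selected: list = []

        def pvalues(feats):
            M = sm.add_constant(Xdf[feats].to_numpy(dtype=float), has_constant="add")
            if np.linalg.matrix_rank(M) < M.shape[1]:
                return None
            res = sm.OLS(y, M).fit()
            return dict(zip(feats, res.pvalues[1:]))

        ss_tot = float(np.sum((y - y.mean()) ** 2))

        def residual_ss(feats):
            M = sm.add_constant(Xdf[feats].to_numpy(dtype=float), has_constant="add")
            return float(sm.OLS(y, M).fit().ssr)

        for _ in range(self.max_iter):
            changed = False
            # perfect fit: further partial tests are numerically meaningless
            if selected and residual_ss(selected) <= 1e-10 * max(ss_tot, 1.0):
                break
            # forward step
            best_p, best_c = None, None
            for c in cols:
                if c in selected:
                    continue
                pv = pvalues(selected + [c])
                if pv is None:
                    continue
                p = pv[c]
                if np.isfinite(p) and (best_p is None or p < best_p):
                    best_p, best_c = p, c
            if best_c is not None and best_p < self.alpha_enter:
                selected.append(best_c)
                changed = True
            # backward step
            if selected:
                pv = pvalues(selected)
                if pv is not None:
                    worst = max(selected, key=lambda c: pv[c])
                    if pv[worst] > self.alpha_remove:
                        selected.remove(worst)
                        changed = True
            if not changed:
                break

        if selected:
            M = sm.add_constant(Xdf[selected].to_numpy(dtype=float), has_constant="add")
            res = sm.OLS(y, M).fit()
            self.intercept_ = float(res.params[0])
            self.coef_ = np.asarray(res.params[1:], dtype=float)
        else:
            self.intercept_ = float(np.mean(y))
            self.coef_ = np.empty(0)
        self.selected_features_ = list(selected)
        self.columns_ = cols
        self.n_features_in_ = len(cols)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X, dtype=float), columns=self.columns_
        )
        if not self.selected_features_:
            return np.full(len(Xdf), self.intercept_)
        M = Xdf[self.selected_features_].to_numpy(dtype=float)
        return self.intercept_ + M @ self.coef_


# ---------------------------------------------------------------------------
# Gaussian process regression with ARD squared-exponential kernel
# ---------------------------------------------------------------------------


class GPRegressor(BaseEstimator, RegressorMixin):
    """GP regression with the anisotropic SE kernel and fitted noise term.

    Features are standardized to zero mean / unit variance internally
    (zero-variance features get a unit scale), so the fitted per-feature
    length scales ``length_scales_`` are directly comparable across indices;
    the target is centred on its training mean.  Hyperparameters — signal
    variance γ, length scales σ_b and noise variance — maximize the log
    marginal likelihood with ``n_restarts`` seeded random restarts.

    Parameters
    ----------
    n_restarts : extra random optimizer restarts beyond the initial point.
    length_scale_bounds : bounds for σ_b on the standardized scale.
    random_state : seed for restart sampling; fits are deterministic given it.
    """

    def __init__(
        self,
        n_restarts: int = 5,
        length_scale_bounds: tuple = (1e-2, 1e3),
        random_state: int | None = 0,
    ):
        self.n_restarts = n_restarts
        self.length_scale_bounds = length_scale_bounds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("GP regression needs at least 2 training rows")
        self.x_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0  # zero-variance feature: leave centred at 0
        self.x_scale_ = scale
        Xs = (X - self.x_mean_) / self.x_scale_

        b = X.shape[1]
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e4))
            * RBF(np.ones(b), self.length_scale_bounds)
            + WhiteKernel(1e-2, (1e-10, 1e2))
        )
        self.gp_ = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=self.n_restarts,
            random_state=self.random_state,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=UserWarning)  # bound hits
            warnings.filterwarnings("ignore", category=RuntimeWarning)
            self.gp_.fit(Xs, y)

        k = self.gp_.kernel_
        self.signal_variance_ = float(k.k1.k1.constant_value)  # γ
        ls = np.atleast_1d(k.k1.k2.length_scale)
        self.length_scales_ = np.broadcast_to(ls, (b,)).astype(float).copy()  # σ_b
        self.noise_variance_ = float(k.k2.noise_level)
        self.log_marginal_likelihood_ = float(self.gp_.log_marginal_likelihood_value_)
        self.n_features_in_ = b
        return self

    def predict(self, X, return_std: bool = False):
        check_is_fitted(self, "gp_")
        X = check_array(np.asarray(X, dtype=float))
        Xs = (X - self.x_mean_) / self.x_scale_
        return self.gp_.predict(Xs, return_std=return_std)


def fit_gpr(X, y, *, n_restarts: int = 5, random_state: int | None = 0) -> GPRegressor:
    """Fit a GP with the ARD SE kernel; thin wrapper over :class:`GPRegressor`."""
    return GPRegressor(n_restarts=n_restarts, random_state=random_state).fit(X, y)


# ---------------------------------------------------------------------------
# Sequential backward band removal
# ---------------------------------------------------------------------------


@dataclass
class SBBRTrace:
    """Record of one sequential backward removal run.

    ``subsets[i]`` is the feature list evaluated at iteration i (sizes B,
    B−1, …, 1), with its cross-validated RMSE/R² at the same position;
    ``removal_order`` lists features in the order they were dropped, the
    final survivor last (a permutation of the starting features).
    """

    subsets: list
    cv_rmse: list
    cv_r2: list
    removal_order: list
    k_folds: int
    seed: int

    @property
    def selected(self) -> list:
        """Subset with minimum CV RMSE; ties broken toward fewer features."""
        best = min(range(len(self.subsets)), key=lambda i: (self.cv_rmse[i], len(self.subsets[i])))
        return list(self.subsets[best])

    @property
    def selected_cv_rmse(self) -> float:
        return min(self.cv_rmse)


def _cv_predictions(estimator, X: np.ndarray, y: np.ndarray, k: int, seed: int) -> np.ndarray:
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty_like(y, dtype=float)
    for tr, te in kf.split(X):
        m = clone(estimator).fit(X[tr], y[tr])
        pred[te] = m.predict(X[te])
    return pred


def sbbr(
    X,
    y,
    k_folds: int = 10,
    seed: int = 0,
    *,
    n_restarts: int = 2,
) -> SBBRTrace:
    """Sequential backward band removal with a GP relevance criterion.

    Starting from all features: cross-validate a GP on the current subset,
    then refit on all rows and drop the feature with the largest fitted
    length scale (least informative under the ARD kernel); repeat until one
    feature remains.  CV folds are drawn with a seed fixed per subset size so
    subsets are compared on identical partitions.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if Xdf.shape[1] < 1:
        raise ValueError("need at least one feature")
    if len(y) < k_folds:
        raise ValueError("need at least k_folds samples")

    current = list(Xdf.columns)
    subsets, rmses, r2s, removed = [], [], [], []
    while current:
        Xc = Xdf[current].to_numpy(dtype=float)
        est = GPRegressor(n_restarts=n_restarts, random_state=seed)
        pred = _cv_predictions(est, Xc, y, k_folds, seed + len(current))
        resid = y - pred
        subsets.append(list(current))
        rmses.append(float(np.sqrt(np.mean(resid**2))))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2s.append(1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan"))
        if len(current) == 1:
            removed.append(current[0])
            break
        full = GPRegressor(n_restarts=n_restarts, random_state=seed).fit(Xc, y)
        worst = int(np.argmax(full.length_scales_))
        removed.append(current[worst])
        current = [c for i, c in enumerate(current) if i != worst]
    return SBBRTrace(
        subsets=subsets, cv_rmse=rmses, cv_r2=r2s, removal_order=removed,
        k_folds=k_folds, seed=seed,
    )
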