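"""Partial least squares regression (PLS1, NIPALS) for yield prediction.

The model autoscales predictors (mean 0, SD 1), centers the response, and
extracts latent variables by the NIPALS PLS1 recursion.  The number of
latent variables is the single tuned hyperparameter, chosen as the argmin
of out-of-fold RMSE in 10-fold cross-validation, with ties broken toward
fewer components; autoscaling is re-estimated inside each training fold.

The surface follows the statsmodels convention: :class:`PLSYieldModel`
holds the data, ``fit``/``fit_cv`` return a :class:`PLSYieldResults`
carrying coefficients on the original predictor scale, the CV RMSE
profile and a ``summary()`` table.  The functions :func:`fit_pls`,
:func:`tune_pls` and :func:`predict` are thin wrappers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_N_FOLDS = 10
MAX_LATENT_CAP = 20
_RANK_TOL = 1e-12


@dataclass
class CVPlan:
    """Seeded k-fold assignment: uniform shuffle, then block partition
    (fold sizes differ by at most one)."""

    n_folds: int = DEFAULT_N_FOLDS
    seed: int = 1

    def folds(self, n: int) -> np.ndarray:
        if n < self.n_folds:
            raise ValueError(f"need at least n_folds={self.n_folds} rows, got {n}")
        order = np.random.default_rng(self.seed).permutation(n)
        fold_of = np.empty(n, dtype=int)
        for f, block in enumerate(np.array_split(order, self.n_folds)):
            fold_of[block] = f
        return fold_of


def default_max_latent(n_train: int, n_predictors: int) -> int:
    return max(1, min(MAX_LATENT_CAP, n_predictors, n_train // 2))


def _coef_path(X: np.ndarray, y: np.ndarray, max_latent: int):
    """NIPALS PLS1 on autoscaled X / centered y.

    Returns (coef_path, achieved) where ``coef_path[a - 1]`` are the
    regression coefficients (on the scaled predictors) using ``a`` latent
    variables.  Extraction stops early when X or the residual is exhausted
    (rank deficiency), so ``achieved <= max_latent``.
    """
    n, p = X.shape
    Xd = X.copy()
    yd = y.copy()
    y_scale = max(float(np.abs(y).max()), 1.0)
    R = np.zeros((p, 0))  # columns r_a with beta_a = beta_{a-1} + r_a q_a
    W = np.zeros((p, 0))
    P = np.zeros((p, 0))
    beta = np.zeros(p)
    path = []
    for _ in range(max_latent):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn < _RANK_TOL * max(1.0, np.linalg.norm(X)) * y_scale:
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt < _RANK_TOL:
            break
        p_load = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd -= np.outer(t, p_load)
        yd = yd - q * t
        if W.shape[1]:
            r = w - R @ (P.T @ w)
        else:
            r = w
        beta = beta + r * q
        R = np.column_stack([R, r])
        W = np.column_stack([W, w])
        P = np.column_stack([P, p_load])
        path.append(beta.copy())
    return path, len(path)


@dataclass
class PLSModel:
    """A fitted PLS1 yield model in audit-friendly form.

    ``coefficients`` are on the original predictor scale;
    ``intercept`` completes ``yhat = intercept + X @ coefficients``.
    """

    predictor_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    y_center: float
    coefficients: np.ndarray
    intercept: float
    n_latent: int
    cv_rmse: np.ndarray | None = None

    def predict(self, X_new) -> np.ndarray:
        X = _align_columns(X_new, self.predictor_names)
        return self.intercept + X @ self.coefficients

    def to_json(self) -> str:
        doc = {
            "predictor_names": list(self.predictor_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "y_center": self.y_center,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "n_latent": self.n_latent,
            "cv_rmse": None if self.cv_rmse is None else self.cv_rmse.tolist(),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, doc: str) -> "PLSModel":
        d = json.loads(doc)
        return cls(
            predictor_names=d["predictor_names"],
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            y_center=float(d["y_center"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            n_latent=int(d["n_latent"]),
            cv_rmse=None if d["cv_rmse"] is None else np.asarray(d["cv_rmse"], dtype=float),
        )


def _align_columns(X_new, names: list[str]) -> np.ndarray:
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in names if c not in X_new.columns]
        extra = [c for c in X_new.columns if c not in names]
        if missing or extra:
            raise ValueError(
                f"predictor columns mismatch: missing {missing}, extra {extra}"
            )
        return X_new[names].to_numpy(dtype=float)
    X = np.asarray(X_new, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(names):
        raise ValueError(
            f"expected {len(names)} predictor columns, got {X.shape[1]}"
        )
    return X


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


class PLSYieldModel:
    """PLS1 regression model of plot grain yield on spectral predictors.

    Parameters
    ----------
    endog : yield vector (dt/ha), length n.
    exog : predictor matrix (n x p); a DataFrame's column names become the
        model's predictor names.
    """

    def __init__(self, endog, exog):
        X, names = _as_matrix(exog)
        y = np.asarray(endog, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("endog and exog row counts differ")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values in endog/exog")
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"{int((~keep).sum())} zero-variance predictor(s) dropped",
                stacklevel=2,
            )
        self.exog = X[:, keep]
        self.endog = y
        self.predictor_names = [n for n, k in zip(names, keep) if k]
        self.nobs = y.size

    # -- internal ----------------------------------------------------------
    def _autoscale(self, X, y):
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)
        return (X - center) / scale, center, scale, y - y.mean(), float(y.mean())

    def _fit_model(self, n_latent: int, cv_rmse=None) -> PLSModel:
        Xs, center, scale, yc, y_mean = self._autoscale(self.exog, self.endog)
        path, achieved = _coef_path(Xs, yc, n_latent)
        if achieved == 0:
            beta_s = np.zeros(self.exog.shape[1])
            achieved_n = 0
        else:
            if achieved < n_latent:
                warnings.warn(
                    f"n_latent reduced from {n_latent} to {achieved} (rank deficiency)",
                    stacklevel=3,
                )
            beta_s = path[achieved - 1]
            achieved_n = achieved
        coef = beta_s / scale
        intercept = y_mean - float(center @ coef)
        return PLSModel(
            predictor_names=self.predictor_names,
            center=center,
            scale=scale,
            y_center=y_mean,
            coefficients=coef,
            intercept=intercept,
            n_latent=achieved_n,
            cv_rmse=cv_rmse,
        )

    # -- public ------------------------------------------------------------
    def fit(self, n_latent: int) -> "PLSYieldResults":
        """Fit with a fixed number of latent variables."""
        if n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        if self.nobs <= n_latent:
            raise ValueError("need n rows > n_latent")
        return PLSYieldResults(self, self._fit_model(n_latent))

    def fit_cv(
        self,
        max_latent: int | None = None,
        cv: CVPlan | None = None,
    ) -> "PLSYieldResults":
        """Choose ``n_latent`` by out-of-fold RMSE, then refit on all rows."""
        cv = cv or CVPlan()
        if self.nobs < 2 * cv.n_folds:
            raise ValueError(
                f"need at least 2 x n_folds = {2 * cv.n_folds} rows for CV tuning"
            )
        if max_latent is None:
            max_latent = default_max_latent(self.nobs, len(self.predictor_names))
        if max_latent < 1:
            raise ValueError("max_latent must be >= 1")
        fold_of = cv.folds(self.nobs)
        sse = np.zeros(max_latent)
        for f in range(cv.n_folds):
            hold = fold_of == f
            Xs, center, scale, yc, y_mean = self._autoscale(
                self.exog[~hold], self.endog[~hold]
            )
            path, achieved = _coef_path(Xs, yc, max_latent)
            Xh = (self.exog[hold] - center) / scale
            yh = self.endog[hold]
            for a in range(max_latent):
                beta = path[min(a, achieved - 1)] if achieved else np.zeros(Xs.shape[1])
                pred = y_mean + Xh @ beta
                sse[a] += float(np.sum((pred - yh) ** 2))
        cv_rmse = np.sqrt(sse / self.nobs)
        n_latent = int(np.argmin(cv_rmse)) + 1  # argmin takes the first = fewest
        return PLSYieldResults(self, self._fit_model(n_latent, cv_rmse=cv_rmse))


class PLSYieldResults:
    """Results wrapper: fitted coefficients, diagnostics and prediction."""

    def __init__(self, model: PLSYieldModel, fit: PLSModel):
        self.model = model
        self._fit = fit

    @property
    def pls_model(self) -> PLSModel:
        return self._fit

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.concatenate([[self._fit.intercept], self._fit.coefficients]),
            index=["intercept"] + list(self._fit.predictor_names),
        )

    @property
    def n_latent(self) -> int:
        return self._fit.n_latent

    @property
    def cv_rmse(self) -> np.ndarray | None:
        return self._fit.cv_rmse

    @property
    def fittedvalues(self) -> np.ndarray:
        return self._fit.intercept + self.model.exog @ self._fit.coefficients

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def rsquared(self) -> float:
        y = self.model.endog
        f = self.fittedvalues
        if np.std(f) == 0 or np.std(y) == 0:
            return np.nan
        return float(np.corrcoef(y, f)[0, 1] ** 2)

    def predict(self, X_new) -> np.ndarray:
        return self._fit.predict(X_new)

    def summary(self) -> str:
        f = self._fit
        lines = [
            "PLS1 yield regression (NIPALS, autoscaled predictors)",
            "=" * 56,
            f"n obs:            {self.model.nobs}",
            f"n predictors:     {len(f.predictor_names)}",
            f"latent variables: {f.n_latent}",
            f"train R^2:        {self.rsquared:.4f}",
            f"train RMSE:       {float(np.sqrt(np.mean(self.resid ** 2))):.4f}",
        ]
        if f.cv_rmse is not None:
            best = f.cv_rmse[f.n_latent - 1]
            lines.append(f"CV RMSE (chosen): {best:.4f} at a = {f.n_latent}")
            prof = ", ".join(f"{v:.3f}" for v in f.cv_rmse[:10])
            lines.append(f"CV RMSE profile:  {prof}" + (" ..." if len(f.cv_rmse) > 10 else ""))
        lines.append("-" * 56)
        coefs = self.params
        show = coefs if len(coefs) <= 12 else pd.concat([coefs.iloc[:1], coefs.iloc[1:].abs().nlargest(10)])
        for name, val in show.items():
            lines.append(f"{name:>16s}  {coefs[name]: .5f}")
        if len(coefs) > 12:
            lines.append(f"  ... ({len(coefs) - len(show)} further coefficients)")
        return "\n".join(lines)


# -- spec-style functional surface ----------------------------------------

def fit_pls(X, y, n_latent: int) -> PLSModel:
    """Fit PLS1 with a fixed latent-variable count; see :class:`PLSYieldModel`."""
    return PLSYieldModel(y, X).fit(n_latent).pls_model


def tune_pls(
    X, y, cv: CVPlan | None = None, max_latent: int | None = None
) -> PLSModel:
    """CV-tuned PLS1: argmin out-of-fold RMSE over 1..max_latent components."""
    return PLSYieldModel(y, X).fit_cv(max_latent=max_latent, cv=cv).pls_model


def predict(model: PLSModel, X_new) -> np.ndarray:
    """Predict yield for new plots from a fitted model."""
    return model.predict(X_new)
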